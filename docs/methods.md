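# Methods

## The analysis

`dosepaint` implements a threshold-based, multi-level dose-painting
analysis for co-registered PET uptake volumes, and the machinery to compare
the resulting tracer-specific prescription plans.

**Segmentation.** The high-risk sub-volume is the set of GTV voxels with
SUV at or above an absolute cut-off. The cut-off comes from one of three
rules: a percentage of the within-GTV SUV_max (the usual FDG rule, 40% by
default), an absolute SUV (used for hypoxia tracers with a calibrated
threshold, e.g. 1.4 for an early Cu-ATSM scan), or a tumor-to-muscle ratio
times the mean SUV of a muscle reference ROI (used when no absolute
calibration exists, e.g. late Cu-ATSM scans; default ratio 2.0 — a package
choice, since no published value exists for 24 h distribution times). The
muscle statistic is the mean, the simplest convention. The sub-volume is
partitioned into `n_levels` (default 5) equal-width bins in percent-of-max
uptake between the cut-off percentage SUV_c and 100. Bins are half-open
`[lower, upper)` with the top bin closed at 100, so a voxel exactly at the
cut-off belongs to DP1 and the max-uptake voxel always to DPn; this
guarantees an exact partition of the super-threshold set.

**Prescription.** Each level's dose follows the linear escalation

    dose(%) = 100 + (SUV_iso − SUV_c) / (100 − SUV_c) × (max_pct − 100)

with SUV_iso the bin midpoint, a 45 Gy base dose (4.5 Gy × 10 fractions)
and `max_pct` = 150 by default. For equal-width bins the bracket reduces to
`(2k − 1) / (2n)`, so the level percentages are independent of the cut-off:
105/115/125/135/145% of base for five levels, i.e. 47.25/51.75/56.25/
60.75/65.25 Gy at 45 Gy. Doses are carried at full precision; report tables
round to 0.1 Gy. The prescription map assigns level doses inside the
high-risk sub-volume, the base dose to the rest of the GTV, and zero
elsewhere — it represents the prescription, not a delivered-dose
calculation (beam/arc optimization is out of scope). An optional Gaussian
blur (`emulate_delivery`, width in mm) stands in for deliverability; it
uses edge-replicating boundaries so a constant field is exactly invariant,
and it conserves the mean dose over the GTV interior (GTV eroded by twice
the blur width) to within 1% for widths up to 3 mm on realistic phantom
sizes. The rim necessarily leaks dose outward; that is physical, not an
artifact.

**Degenerate levels.** A level substructure confined to at most one axial
slice (third voxel index, by convention) is not a usable optimization
volume. Such levels are dropped: recorded by 1-based index, their voxels
merged into the nearest lower surviving level, or reverted to the base-dose
GTV when none survives. Validity is judged on the original masks before any
merging. In clinical practice the top level is the one lost this way; the
phantom reproduces that behaviour at high cut-offs.

**Comparison.** Two plans over a common GTV are compared three ways:
a 2D joint dose histogram (shared 0.5 Gy bins — wide enough to avoid
empty-bin noise, narrow enough to resolve the six discrete prescription
doses — spanning one bin beyond the observed dose range, half-open with
the top bin closed); a quality volume histogram of the voxelwise ratio
dose_A/dose_B, evaluated DVH-style (fraction of voxels with ratio ≥ x) on a
fixed grid from 0 to 2 in steps of 0.001, with the QI fraction counting
voxels whose ratio lies in the closed band [0.95, 1.05]; and per-level Dice
coefficients, either on the per-level bins (default) or on cumulative
super-threshold unions of levels ≥ k. A level empty in both plans yields an
undefined Dice, reported as null and excluded from trend statistics — 0/0
must not fabricate agreement. The ratio direction puts the "covering" plan
in the numerator and the reference (hypoxia) plan in the denominator; both
orders are available by swapping arguments.

## The phantom

Real multi-tracer PET volumes for this analysis are not publicly deposited,
so the package ships a synthetic generator. Each case holds two SUV volumes
on one grid, an ellipsoidal GTV (axis ratio 1 : 1.2 : 0.8 — deliberately
aspherical so single-slice top levels actually occur at high cut-offs) and
a muscle slab. Heterogeneous uptake is a Gaussian random field: white noise
filtered with a Gaussian of physical width `smoothness_mm` (default 4 mm)
and standardized. The two tracers mix a shared and a private field,

    Z_i = sqrt(|rho|) · S + sqrt(1 − |rho|) · L_i   (i = a, b),

with the sign of the shared term flipped for tracer b when rho < 0, giving
population inter-tracer correlation exactly rho. Inside the GTV the latent
field passes through a softplus (monotone, strictly positive, preserves the
field's topology so thresholding behaves like real uptake) and is rescaled
linearly to run from the background SUV up to exactly `suv_max`; outside
the GTV the volume sits at the constant background (default 0.7), with 5%
CV noise on the muscle slab (one draw shared by both tracers) so
tumor-to-muscle cut-offs are well defined but nontrivial. Defaults emulate
the reference cohort averages: GTV 63.3 ccm, tracer-A SUV_max 12.5,
tracer-B SUV_max 2.8, on a 48³ grid of 2 mm isotropic voxels.

What the phantom does *not* model: scanner point-spread and partial-volume
effects, attenuation, scatter, reconstruction noise, pharmacokinetics, and
anatomical structure. Passing tests therefore demonstrate correctness of
the segmentation/prescription/comparison machinery and qualitative trends
(mismatch growing with dose level, agreement growing with inter-tracer
correlation), not distributional realism of PET data.

## Numerical and design choices

- Binning uses `searchsorted` over the interior bin edges; an independent
  per-voxel loop oracle checks equality in the tests.
- Grid equality tolerance is 1e-6 mm on spacing and origin (float header
  round-trip noise); shapes must match exactly. All internal coordinates
  are 0-based voxel indices; world coordinates exist only in NIfTI headers.
- Masks are stored as uint8 0/1 NIfTI volumes, scalar fields as float64, so
  write→read round trips are bit-exact.
- Empty-both Dice is null; empty GTVs, zero reference doses inside the GTV,
  and cut-offs at or above the GTV maximum raise errors (the last with a
  dedicated "empty sub-volume" warning at cut-off computation time).
- The trend tests (Dice vs level, Dice vs rho) use cumulative mode. With
  per-bin masks the inner levels are thin shells whose Dice is dominated by
  boundary jitter, which breaks monotonicity near rho = 1 even though the
  underlying fields agree almost everywhere; cumulative super-threshold
  regions are compact and make the trend statistic well behaved. Which mode
  the original analysis used is not stated; both are provided.
- Trend and correlation-recovery statistics average 24 fixed seeds on a 30³
  grid with a 30 ccm GTV — small enough to keep the whole suite around a
  few seconds, large enough that the seed-mean of the empirical correlation
  sits within 0.1 of the target rho.
- Cohort summaries round QI fractions to 2 d.p. and doses/volumes to 1 d.p.
  after averaging; full precision is retained in JSON reports. (Published
  tables of this kind sometimes round before averaging, which can shift the
  last digit — e.g. an arithmetic mean of 0.496 printing as 0.50 here.)
- Exact equal-bin level doses end in .25/.75 Gy, which are rounding
  ties at 0.1 Gy precision; reports use round-half-even via numpy, and the
  acceptance script reports unrounded values.

## Limitations

- Prescription maps stand in for optimized treatment plans; absolute QI
  fractions on phantoms are not comparable to values obtained from
  delivered-dose calculations, though the comparison machinery is
  identical.
- The tumor-to-muscle ratio default (2.0) is a convention, not a
  calibrated threshold.
- No resampling: all inputs must share one voxel grid; co-registration is
  assumed done upstream and only verified.
- Dice on small high-dose regions is intrinsically noisy; per-case values
  at the top level should be read with the region volumes alongside.
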