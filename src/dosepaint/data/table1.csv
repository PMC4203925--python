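dog,tumor_type,localization,gtv_ccm,fdg_subvol_ccm,cu3_subvol_ccm,cu24_subvol_ccm,suv_max_fdg,suv_max_cu3
1,Hemangiopericytoma,Lumbar region,128.7,13.0,85.8,61.6,7.9,2.3
2,Fibrosarcoma,Lat. cervical region,88.2,66.4,63.9,17.0,8.5,3.6
3,Squamous cell carcinoma,Nasal cavity,55.4,23.7,21.2,30.0,23.1,3.0
4,Adenocarcinoma,Nasopharynx,20.8,10.3,9.3,3.5,13.2,2.5
5,Undifferentiated soft tissue sarcoma,Mandible,23.2,11.2,6.2,0.6,9.7,2.6
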