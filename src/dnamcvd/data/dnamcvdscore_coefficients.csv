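feature,coefficient,original_marker,source
DNAmGlucose,0.0329,Blood glucose,this_study
DNAmHDL,-0.4473,Blood HDL cholesterol,this_study
DNAmSBP,0.1420,Systolic blood pressure,this_study
DNAmCRP,0.0276,Blood C-reactive protein,this_study
DNAmPAI1,0.1679,Blood plasminogen activator inhibitor 1,this_study
DNAmSKR3,0.0362,Serine/threonine-protein kinase receptor R3,gadd_2022
DNAmHGF,0.0371,Hepatocyte growth factor,gadd_2022
DNAmLeadPatella,0.0402,Lead level in patella bone,colicino_2021
DNAmGDF15,0.0947,Growth differentiation factor 15,lu_2019
DNAmPACKYRS,0.1192,Smoking pack-years,lu_2019
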