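# EPMA vs LA-ICPMS (100%-normalization, oxide mode) major-element comparison
# for a garnet/wadsleyite silicate sample.  LA-ICPMS columns are the mean and
# 1-sigma SD over a rectangular ROI of n pixels; deviation_printed is the
# (ICPMS/EPMA)-1 column as printed in the source comparison table.
# Values in oxide wt%; empty cells = not measured.
phase,species,n,epma_wt,icpms_mean_wt,icpms_sd_wt,deviation_printed
garnet,SiO2,150,54.36,58.00,3.76,0.067
garnet,TiO2,150,0.08,0.04,0.01,-0.468
garnet,Al2O3,150,5.64,4.88,0.67,-0.134
garnet,CaO,150,2.34,1.65,0.54,-0.296
garnet,MgO,150,33.98,32.01,3.46,-0.058
garnet,FeO,150,2.89,2.62,0.41,-0.094
garnet,MnO,150,0.09,0.09,0.15,-0.021
garnet,NiO,150,0.03,,,
garnet,Na2O,150,0.12,0.14,0.02,0.115
garnet,Cr2O3,150,0.34,0.36,0.05,0.071
wadsleyite,SiO2,147,40.91,42.60,3.12,0.041
wadsleyite,TiO2,147,0.02,0.01,0.00,-0.524
wadsleyite,Al2O3,147,0.32,0.27,0.05,-0.154
wadsleyite,CaO,147,0.03,0.05,0.07,0.533
wadsleyite,MgO,147,51.93,50.24,3.25,-0.033
wadsleyite,FeO,147,5.97,6.51,0.80,0.091
wadsleyite,MnO,147,0.06,0.08,0.01,0.206
wadsleyite,NiO,147,0.20,,,
wadsleyite,Na2O,147,0.07,0.09,0.02,0.358
wadsleyite,Cr2O3,147,0.08,0.10,0.01,0.250
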