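gene,age,rate
MLH1,40,1.51884
MSH2,40,1.139346
MSH6,40,0.853522
PMS2,40,0.517657
MLH1,45,1.243757
MSH2,45,1.158089
MSH6,45,0.923757
PMS2,45,0.595213
MLH1,50,1.005917
MSH2,50,1.162602
MSH6,50,0.987421
PMS2,50,0.675926
MLH1,55,0.804734
MSH2,55,1.154472
MSH6,55,1.044025
PMS2,55,0.759259
MLH1,60,0.651538
MSH2,60,1.159695
MSH6,60,1.078648
PMS2,60,0.834167
MLH1,65,0.52071
MSH2,65,1.186992
MSH6,65,1.096436
PMS2,65,0.898148
MLH1,70,0.408284
MSH2,70,1.239837
MSH6,70,1.102725
PMS2,70,0.925926
MLH1,75,0.307692
MSH2,75,1.304878
MSH6,75,1.098532
PMS2,75,0.953704
MLH1,80,0.230769
MSH2,80,1.378049
MSH6,80,1.08805
PMS2,80,0.953704
MLH1,85,0.172337
MSH2,85,1.449081
MSH6,85,1.073046
PMS2,85,0.949611
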