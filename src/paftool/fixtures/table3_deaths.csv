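exposure,site,sex,total,paf_percent,attributable_printed
smoking,lung,male,2055,90.7,1865
smoking,lung,female,1525,87.3,1332
smoking,larynx,male,148,85.7,127
smoking,larynx,female,23,82.2,19
smoking,oral_cavity_pharynx,male,140,63.9,89
smoking,oral_cavity_pharynx,female,66,59.1,39
smoking,esophagus,male,362,58.9,213
smoking,esophagus,female,306,56.8,174
smoking,bladder,male,417,57.9,241
smoking,bladder,female,201,50.7,102
smoking,liver,male,778,36.7,285
smoking,liver,female,666,18.6,124
smoking,stomach,male,2342,30.8,721
smoking,stomach,female,1136,16.8,191
smoking,cervix,female,725,25.4,184
smoking,kidney,male,636,29.2,185
smoking,kidney,female,342,8.7,30
smoking,pancreas,male,763,16.7,127
smoking,pancreas,female,816,21.6,176
smoking,myeloid_leukemia,male,406,29.4,119
smoking,myeloid_leukemia,female,402,4.5,18
smoking,colorectum,male,1538,16.1,247
smoking,colorectum,female,1562,16.5,258
high_bmi,corpus_uteri,female,295,44.8,132
high_bmi,kidney,male,636,26.7,170
high_bmi,kidney,female,342,29.4,100
high_bmi,gallbladder,male,560,22.1,124
high_bmi,gallbladder,female,1063,26.8,285
high_bmi,liver,male,778,20.5,159
high_bmi,liver,female,666,23.2,155
high_bmi,colorectum,male,1538,17.8,274
high_bmi,colorectum,female,1562,11.2,175
high_bmi,breast,female,1688,13.0,220
high_bmi,pancreas,male,763,13.4,102
high_bmi,pancreas,female,816,12.1,99
high_bmi,multiple_myeloma,male,328,11.5,38
high_bmi,multiple_myeloma,female,284,8.7,25
high_bmi,thyroid,male,49,17.1,8
high_bmi,thyroid,female,106,6.3,7
high_bmi,prostate,male,2270,8.6,195
high_bmi,ovary,female,469,7.5,35
high_bmi,stomach,male,2342,7.1,165
high_bmi,stomach,female,1136,5.5,63
high_bmi,esophagus,male,362,6.5,23
high_bmi,esophagus,female,306,6.1,19
alcohol,oral_cavity_pharynx,male,140,44.6,62
alcohol,oral_cavity_pharynx,female,66,11.1,7
alcohol,esophagus,male,362,39.7,144
alcohol,esophagus,female,306,16.8,51
alcohol,larynx,male,148,25.9,38
alcohol,larynx,female,23,7.9,2
alcohol,gallbladder,male,560,15.3,86
alcohol,gallbladder,female,1063,5.8,61
alcohol,liver,male,778,8.4,65
alcohol,liver,female,666,5.1,34
alcohol,colorectum,male,1538,12.1,186
alcohol,colorectum,female,1562,1.1,18
alcohol,breast,female,1688,4.2,72
alcohol,pancreas,male,763,4.2,32
alcohol,pancreas,female,816,0.7,5
physical_activity,colorectum,male,1538,13.6,210
physical_activity,colorectum,female,1562,16.7,261
physical_activity,breast,female,1688,11.2,190
fruit_veg,larynx,male,148,25.2,37
fruit_veg,larynx,female,23,23.2,5
fruit_veg,oral_cavity_pharynx,male,140,25.2,35
fruit_veg,oral_cavity_pharynx,female,66,23.2,15
fruit,lung,male,2055,14.3,294
fruit,lung,female,1525,13.6,207
passive_smoking,lung,male,2055,2.2,46
passive_smoking,lung,female,1525,1.6,24
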