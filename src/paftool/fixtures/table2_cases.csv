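exposure,site,sex,total,paf_percent,attributable_printed
smoking,lung,male,2163,90.7,1963
smoking,lung,female,1708,87.3,1492
smoking,larynx,male,225,85.7,193
smoking,larynx,female,28,82.2,23
smoking,oral_cavity_pharynx,male,299,63.9,191
smoking,oral_cavity_pharynx,female,219,59.1,129
smoking,esophagus,male,412,58.9,243
smoking,esophagus,female,372,56.8,211
smoking,bladder,male,964,57.9,558
smoking,bladder,female,382,50.7,194
smoking,liver,male,866,36.7,317
smoking,liver,female,709,18.6,132
smoking,stomach,male,3429,30.8,1056
smoking,stomach,female,1733,16.8,291
smoking,cervix,female,1546,25.4,392
smoking,kidney,male,1215,29.2,354
smoking,kidney,female,705,8.7,61
smoking,pancreas,male,794,16.7,133
smoking,pancreas,female,841,21.6,182
smoking,myeloid_leukemia,male,522,29.4,153
smoking,myeloid_leukemia,female,514,4.5,23
smoking,colorectum,male,2952,16.1,474
smoking,colorectum,female,2821,16.5,466
high_bmi,corpus_uteri,female,933,44.8,418
high_bmi,kidney,male,1215,26.7,324
high_bmi,kidney,female,705,29.4,207
high_bmi,gallbladder,male,851,22.1,188
high_bmi,gallbladder,female,1848,26.8,496
high_bmi,liver,male,866,20.5,177
high_bmi,liver,female,709,23.2,165
high_bmi,colorectum,male,2952,16.7,492
high_bmi,colorectum,female,2821,10.8,304
high_bmi,pancreas,male,794,13.4,107
high_bmi,pancreas,female,841,12.1,102
high_bmi,breast,female,5391,11.2,603
high_bmi,multiple_myeloma,male,434,11.5,50
high_bmi,multiple_myeloma,female,389,8.7,34
high_bmi,thyroid,male,173,17.1,29
high_bmi,thyroid,female,875,6.3,55
high_bmi,ovary,female,826,7.5,62
high_bmi,stomach,male,3429,7.1,242
high_bmi,stomach,female,1733,5.5,95
high_bmi,esophagus,male,412,6.5,27
high_bmi,esophagus,female,372,6.1,23
high_bmi,prostate,male,6574,3.0,195
alcohol,oral_cavity_pharynx,male,299,44.6,133
alcohol,oral_cavity_pharynx,female,219,11.1,24
alcohol,esophagus,male,412,39.7,163
alcohol,esophagus,female,372,16.8,63
alcohol,larynx,male,225,25.9,58
alcohol,larynx,female,28,7.9,2
alcohol,gallbladder,male,851,15.3,130
alcohol,gallbladder,female,1848,5.8,107
alcohol,liver,male,866,8.4,73
alcohol,liver,female,709,5.1,36
alcohol,colorectum,male,2952,12.1,356
alcohol,colorectum,female,2821,1.1,32
alcohol,breast,female,5391,4.2,229
alcohol,pancreas,male,794,4.2,34
alcohol,pancreas,female,841,0.7,6
physical_activity,colorectum,male,2952,11.4,336
physical_activity,colorectum,female,2821,15.2,428
physical_activity,breast,female,5391,9.6,520
fruit_veg,larynx,male,225,25.2,57
fruit_veg,larynx,female,28,23.2,7
fruit_veg,oral_cavity_pharynx,male,299,25.2,75
fruit_veg,oral_cavity_pharynx,female,219,23.2,51
fruit,lung,male,2163,14.3,310
fruit,lung,female,1708,13.6,232
passive_smoking,lung,male,2163,2.2,48
passive_smoking,lung,female,1708,1.6,27
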