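site,sex,cases,deaths
lung,male,2163,2055
lung,female,1708,1525
larynx,male,225,148
larynx,female,28,23
oral_cavity_pharynx,male,299,140
oral_cavity_pharynx,female,219,66
esophagus,male,412,362
esophagus,female,372,306
bladder,male,964,417
bladder,female,382,201
liver,male,866,778
liver,female,709,666
stomach,male,3429,2342
stomach,female,1733,1136
cervix,female,1546,725
kidney,male,1215,636
kidney,female,705,342
pancreas,male,794,763
pancreas,female,841,816
myeloid_leukemia,male,522,406
myeloid_leukemia,female,514,402
colorectum,male,2952,1538
colorectum,female,2821,1562
corpus_uteri,female,933,295
gallbladder,male,851,560
gallbladder,female,1848,1063
breast,female,5391,1688
multiple_myeloma,male,434,328
multiple_myeloma,female,389,284
thyroid,male,173,49
thyroid,female,875,106
ovary,female,826,469
prostate,male,6574,2270
all_sites,both,50320,28010
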