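exposure,site,sexes,subtype
alcohol,oral_cavity_pharynx,both,
alcohol,esophagus,both,squamous_cell
alcohol,colorectum,both,
alcohol,liver,both,
alcohol,gallbladder,both,
alcohol,pancreas,both,
alcohol,larynx,both,
alcohol,breast,female,
high_bmi,esophagus,both,adenocarcinoma
high_bmi,stomach,both,cardia
high_bmi,colorectum,both,
high_bmi,liver,both,
high_bmi,gallbladder,both,
high_bmi,pancreas,both,
high_bmi,breast,female,postmenopausal
high_bmi,corpus_uteri,female,
high_bmi,ovary,female,
high_bmi,kidney,both,
high_bmi,thyroid,both,
high_bmi,multiple_myeloma,both,
high_bmi,prostate,male,advanced
fruit_veg,oral_cavity_pharynx,both,
fruit_veg,larynx,both,
fruit,lung,both,
physical_activity,colorectum,both,
physical_activity,breast,female,postmenopausal
passive_smoking,lung,both,
smoking,oral_cavity_pharynx,both,
smoking,esophagus,both,
smoking,stomach,both,
smoking,colorectum,both,
smoking,liver,both,
smoking,pancreas,both,
smoking,nasal_cavity_paranasal_sinus,both,
smoking,larynx,both,
smoking,lung,both,
smoking,cervix,female,
smoking,kidney,both,
smoking,bladder,both,
smoking,myeloid_leukemia,both,
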