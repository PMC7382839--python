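site,sex,subtype,fraction,rule
stomach,male,cardia,0.32,fixed
stomach,female,cardia,0.22,fixed
stomach,male,non_cardia,0.68,fixed
stomach,female,non_cardia,0.78,fixed
esophagus,male,adenocarcinoma,0.15,fixed
esophagus,female,adenocarcinoma,0.14,fixed
esophagus,male,squamous_cell,0.85,fixed
esophagus,female,squamous_cell,0.86,fixed
prostate,male,advanced,,cases_equal_deaths
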