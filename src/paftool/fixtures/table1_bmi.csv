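exposure,sex,mean,sd,cf_mean,cf_sd
high_bmi,male,28.42,6.0,22,1
high_bmi,female,29.62,5.6,22,1
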