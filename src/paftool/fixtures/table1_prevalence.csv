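exposure,sex,level,proportion,is_tmrel
alcohol,male,abstainer,0.205,1
alcohol,male,light,0.315,0
alcohol,male,moderate,0.391,0
alcohol,male,heavy,0.088,0
alcohol,female,abstainer,0.441,1
alcohol,female,light,0.414,0
alcohol,female,moderate,0.138,0
alcohol,female,heavy,0.007,0
fruit_veg,male,>=400 g/day,0.116,1
fruit_veg,male,300-399 g/day,0.091,0
fruit_veg,male,200-299 g/day,0.181,0
fruit_veg,male,100-199 g/day,0.380,0
fruit_veg,male,0-99 g/day,0.232,0
fruit_veg,female,>=400 g/day,0.147,1
fruit_veg,female,300-399 g/day,0.119,0
fruit_veg,female,200-299 g/day,0.198,0
fruit_veg,female,100-199 g/day,0.369,0
fruit_veg,female,0-99 g/day,0.166,0
fruit,male,>=250 g/day,0.062,1
fruit,male,200-249 g/day,0.061,0
fruit,male,150-199 g/day,0.112,0
fruit,male,100-149 g/day,0.077,0
fruit,male,50-99 g/day,0.275,0
fruit,male,0-49 g/day,0.412,0
fruit,female,>=250 g/day,0.065,1
fruit,female,200-249 g/day,0.079,0
fruit,female,150-199 g/day,0.154,0
fruit,female,100-149 g/day,0.061,0
fruit,female,50-99 g/day,0.305,0
fruit,female,0-49 g/day,0.336,0
physical_activity,male,>=8000 MET-min/week,0.006,1
physical_activity,male,4000-7999 MET-min/week,0.051,0
physical_activity,male,600-3999 MET-min/week,0.236,0
physical_activity,male,<600 MET-min/week,0.707,0
physical_activity,female,>=8000 MET-min/week,0.002,1
physical_activity,female,4000-7999 MET-min/week,0.018,0
physical_activity,female,600-3999 MET-min/week,0.137,0
physical_activity,female,<600 MET-min/week,0.843,0
passive_smoking,male,no,0.827,1
passive_smoking,male,yes,0.173,0
passive_smoking,female,no,0.870,1
passive_smoking,female,yes,0.130,0
smoking,male,never,0.377,1
smoking,male,former,0.289,0
smoking,male,current,0.334,0
smoking,female,never,0.526,1
smoking,female,former,0.216,0
smoking,female,current,0.258,0
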