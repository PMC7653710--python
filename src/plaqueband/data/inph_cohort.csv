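subject_id,group,gender,age_years,weight_kg,height_cm,bmi_printed,homa_ir,t2d,hypertension,abeta_positive,apoe
S01,BMI<25,female,67,70,170,24.2,0.6,no,no,yes,3/4
S02,BMI<25,male,79,65,168,23.0,2.7,no,no,yes,3/4
S03,BMI<25,male,75,56,159,22.2,0.7,no,yes,yes,4/4
S04,BMI<25,female,71,60,158,24.0,1.9,no,no,yes,3/3
S05,BMI>30,female,71,87,160,34.0,4.9,no,no,yes,3/4
S06,BMI>30,male,81,102,171,34.9,7.0,no,no,yes,3/3
S07,BMI>30,male,69,80,160,31.3,3.4,no,yes,yes,3/3
S08,BMI>30+T2D,male,72,98,170,33.9,14.1,yes,yes,yes,3/3
S09,BMI>30+T2D,male,73,90,173,30.1,4.7,yes,yes,yes,3/4
S10,BMI>30+T2D,male,73,92,162,35.1,4.5,yes,yes,yes,3/3
S11,BMI>30+T2D,female,75,92,155,38.3,16.8,yes,yes,yes,3/4
S12,BMI>30+T2D,male,67,82,165,30.1,5.9,yes,yes,yes,3/4
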