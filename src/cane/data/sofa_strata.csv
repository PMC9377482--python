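organ,variable,stratum_min,stratum_max,subscore
respiration,pf_ratio,400,,0
respiration,pf_ratio,300,400,1
respiration,pf_ratio,200,300,2
respiration,pf_ratio,100,200,3
respiration,pf_ratio,0,100,4
coagulation,platelets,150,,0
coagulation,platelets,100,150,1
coagulation,platelets,50,100,2
coagulation,platelets,20,50,3
coagulation,platelets,0,20,4
liver,total_bilirubin,0,1.2,0
liver,total_bilirubin,1.2,2.0,1
liver,total_bilirubin,2.0,6.0,2
liver,total_bilirubin,6.0,12.0,3
liver,total_bilirubin,12.0,,4
cardiovascular,map,70,,0
cardiovascular,map,0,70,1
cns,gcs,15,,0
cns,gcs,13,15,1
cns,gcs,10,13,2
cns,gcs,6,10,3
cns,gcs,3,6,4
renal,creatinine,0,1.2,0
renal,creatinine,1.2,2.0,1
renal,creatinine,2.0,3.5,2
renal,creatinine,3.5,5.0,3
renal,creatinine,5.0,,4
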