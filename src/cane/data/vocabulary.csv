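source_system,source_code,feature_name,omop_concept_id,canonical_unit
http://loinc.org,9269-2,gcs,3032652,{score}
http://loinc.org,8480-6,sbp,3004249,mm[Hg]
http://loinc.org,8462-4,dbp,3012888,mm[Hg]
http://loinc.org,9279-1,resp_rate,3024171,/min
http://loinc.org,8867-4,heart_rate,3027018,/min
http://loinc.org,8310-5,body_temperature,3020891,Cel
http://loinc.org,2703-1,pao2,3027315,mm[Hg]
http://loinc.org,19994-3,fio2,3020716,1
http://loinc.org,777-3,platelets,3024929,10*3/uL
http://loinc.org,2160-0,creatinine,3016723,mg/dL
http://loinc.org,1975-2,total_bilirubin,3024128,mg/dL
http://loinc.org,2524-7,lactate,3047181,mmol/L
http://loinc.org,2708-6,spo2,3016502,%
http://loinc.org,67775-7,mental_status_avpu,40493026,{coded}
http://loinc.org,8661-1,chief_complaint,3000062,{coded}
http://loinc.org,11368-8,onset_to_visit,40757210,h
http://snomed.info/sct,417746004,trauma,442562,{coded}
http://snomed.info/sct,30088009,blood_culture_panel,4107893,{order}
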