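marker,source,variant,code
aaa_screen,clinical,narrow,AAASCR001
aaa_screen,clinical,narrow,AAASCR002
aaa_screen,clinical,narrow,AAASCR003
aaa_screen,clinical,broad,AAAUSS101
aaa_screen,clinical,broad,AAAUSS102
breast_screen,clinical,narrow,BRSCR001
breast_screen,clinical,narrow,BRSCR002
breast_screen,clinical,narrow,BRSCR003
breast_screen,clinical,broad,MAMMO101
breast_screen,clinical,broad,MAMMO102
cervical_screen,clinical,narrow,CXSCR001
cervical_screen,clinical,narrow,CXSCR002
cervical_screen,clinical,narrow,CXSCR003
cervical_screen,clinical,broad,SMEAR101
cervical_screen,clinical,broad,SMEAR102
bowel_screen,clinical,narrow,BWSCR001
bowel_screen,clinical,narrow,BWSCR002
bowel_screen,clinical,narrow,FIT00001
nhs_health_check,clinical,narrow,NHSHC001
nhs_health_check,clinical,narrow,NHSHC002
influenza_vaccination,clinical,narrow,FLUVAC001
influenza_vaccination,clinical,narrow,FLUVAC002
influenza_vaccination,prescription,narrow,FLURX0001
influenza_vaccination,prescription,narrow,FLURX0002
pneumococcal_vaccination,clinical,narrow,PNEUVAC01
pneumococcal_vaccination,clinical,narrow,PNEUVAC02
pneumococcal_vaccination,prescription,narrow,PNEURX001
psa_test,clinical,narrow,PSATST001
psa_test,clinical,narrow,PSATST002
bone_density_scan,clinical,narrow,DEXA00001
bone_density_scan,clinical,narrow,DEXA00002
dna_primary_care,clinical,narrow,DNAPC0001
dna_primary_care,clinical,narrow,DNAPC0002
low_value_procedure,hes_procedure,narrow,OPLV00001
low_value_procedure,hes_procedure,narrow,OPLV00002
low_value_prescription,prescription,narrow,GLUCOS001
acs_hospital_visit,hes_diagnosis,narrow,ACSJ18001
acs_hospital_visit,hes_diagnosis,narrow,ACSI50001
acs_hospital_visit,hes_diagnosis,narrow,ACSE11001
blood_pressure,clinical,narrow,BPMEAS001
blood_pressure,clinical,narrow,BPMEAS002
blood_pressure,clinical,narrow,BPMEAS003
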