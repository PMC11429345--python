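marker,stratum,reference_pct
aaa_screen,overall,76.1
breast_screen,overall,71.1
cervical_screen,overall,76.2
bowel_screen,overall,60.5
nhs_health_check,overall,40.0
influenza_vaccination,overall,72.4
pneumococcal_vaccination,overall,69.0
psa_test,overall,53.0
blood_pressure,overall,84.6
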