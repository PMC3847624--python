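intervention_id,baseline_2010_percent,mics_2006_percent,dhs_2003_percent
act_malaria,26,2,0
ors_diarrhea,23,17,12
antibiotics_pneumonia,33,24,18
zinc_diarrhea,4,1,0
breastfeeding,33,26,19
itn_irs,64,33,10
labor_delivery,71,62,55
iptp_itn,38,22,10
vitamin_a,89,95,70
immediate_assessment,56,48,42
clean_birth,60,52,45
syphilis_detection,23,18,14
anc4,34,28,22
sba,54,46,38
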