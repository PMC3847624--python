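intervention_id,target_percent,program
act_malaria,70,1
ors_diarrhea,60,1
antibiotics_pneumonia,60,1
zinc_diarrhea,60,1
breastfeeding,38,1
itn_irs,70,1
labor_delivery,79,1
iptp_itn,70,1
vitamin_a,90,1
immediate_assessment,58,1
clean_birth,64,1
syphilis_detection,64,1
anc4,80,1
sba,60,1
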