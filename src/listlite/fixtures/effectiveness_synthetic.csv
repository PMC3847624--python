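intervention_id,cause,effectiveness,affected_fraction
act_malaria,malaria,0.55,1.00
ors_diarrhea,diarrhea,0.93,0.80
antibiotics_pneumonia,pneumonia,0.70,0.80
zinc_diarrhea,diarrhea,0.23,1.00
itn_irs,malaria,0.55,0.77
iptp_itn,neonatal,0.35,0.10
breastfeeding,diarrhea,0.45,0.30
breastfeeding,pneumonia,0.30,0.25
vitamin_a,diarrhea,0.30,0.30
vitamin_a,other,0.15,0.20
anc4,neonatal,0.15,0.30
sba,neonatal,0.40,0.45
labor_delivery,neonatal,0.30,0.30
immediate_assessment,neonatal,0.20,0.35
clean_birth,neonatal,0.25,0.30
syphilis_detection,neonatal,0.50,0.05
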