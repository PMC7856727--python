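condition_id,label
asthma,Asthma
behavioural_psychological_symptoms_of_dementia,Behavioural and psychological symptoms of dementia
benign_prostatic_hyperplasia,Benign prostatic hyperplasia
blood_clotting_disorders,Blood clotting disorders
breast_cancer,Breast cancer
cardiac_arrhythmia,Cardiac arrhythmia
chronic_constipation,Chronic constipation
chronic_kidney_disease,Chronic kidney disease
chronic_obstructive_pulmonary_disease,Chronic obstructive pulmonary disease
delirium,Delirium
dementia_cognitive_impairment,Dementia/ Cognitive impairment
depression,Depression
diabetes,Diabetes
diabetic_hypoglycemia,Diabetic hypoglycemia
epilepsy_seizures,Epilepsy/Seizures
falls,Falls
glaucoma,Glaucoma
gout,Gout
heart_block,Heart block
heart_failure,Heart failure
hypercalcaemia,Hypercalcaemia
hyperkalaemia,Hyperkalaemia
hypertension,Hypertension
hypokalaemia,Hypokalaemia
hyponatraemia,Hyponatraemia
lewy_body_disease,Lewy body disease
lower_urinary_tract_symptoms,Lower urinary tract symptoms
osteoarthritis,Osteoarthritis
osteoporosis,Osteoporosis
parkinson_disease,Parkinson disease
peptic_ulcer_disease,Peptic ulcer disease
postural_hypotension,Postural hypotension
prostate_adenoma,Prostate adenoma
raynaud_disease,Raynaud disease
respiratory_failure,Respiratory failure
severe_active_liver_diseases,Severe active liver diseases
sleep_apnea_syndrome,Sleep apnea syndrome
syncope,Syncope
transplanted_organ_and_tissue_status,Transplanted organ and tissue status
urinary_incontinence,Urinary incontinence
urinary_retention,Urinary retention
venous_thromboembolism,Venous thromboembolism
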