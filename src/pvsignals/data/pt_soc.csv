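pt,soc
Headache,Nervous system disorders
Migraine,Nervous system disorders
Dizziness,Nervous system disorders
Aseptic meningitis,Nervous system disorders
Tremor,Nervous system disorders
Chronic inflammatory demyelinating polyradiculoneuropathy,Nervous system disorders
Pyrexia,General disorders and administration site conditions
Chills,General disorders and administration site conditions
Asthenia,General disorders and administration site conditions
Fatigue,General disorders and administration site conditions
Illness,General disorders and administration site conditions
Malaise,General disorders and administration site conditions
No adverse event,General disorders and administration site conditions
Infusion site pain,General disorders and administration site conditions
Infusion site erythema,General disorders and administration site conditions
Infusion site swelling,General disorders and administration site conditions
Infusion site extravasation,General disorders and administration site conditions
Chest pain,General disorders and administration site conditions
Oedema peripheral,General disorders and administration site conditions
Sinusitis,Infections and infestations
Pneumonia,Infections and infestations
Bronchitis,Infections and infestations
Upper respiratory tract infection,Infections and infestations
Urinary tract infection,Infections and infestations
Influenza,Infections and infestations
Covid-19,Infections and infestations
Infection,Infections and infestations
Ear infection,Infections and infestations
Nasopharyngitis,Infections and infestations
Gastroenteritis,Infections and infestations
Urticaria,Skin and subcutaneous tissue disorders
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Erythema,Skin and subcutaneous tissue disorders
Hyperhidrosis,Skin and subcutaneous tissue disorders
Infusion related reaction,Injury poisoning and procedural complications
Fall,Injury poisoning and procedural complications
Contusion,Injury poisoning and procedural complications
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Abdominal pain,Gastrointestinal disorders
Constipation,Gastrointestinal disorders
Hypersensitivity,Immune system disorders
Anaphylactic reaction,Immune system disorders
Serum sickness,Immune system disorders
Drug hypersensitivity,Immune system disorders
Hemolytic anaemia,Blood and lymphatic system disorders
Anaemia,Blood and lymphatic system disorders
Neutropenia,Blood and lymphatic system disorders
Haemorrhage,Vascular disorders
Hypertension,Vascular disorders
Hypotension,Vascular disorders
Deep vein thrombosis,Vascular disorders
Flushing,Vascular disorders
Dyspnoea,Respiratory thoracic and mediastinal disorders
Cough,Respiratory thoracic and mediastinal disorders
Pulmonary embolism,Respiratory thoracic and mediastinal disorders
Weight decreased,Investigations
Weight increased,Investigations
Blood pressure increased,Investigations
Arthralgia,Musculoskeletal and connective tissue disorders
Myalgia,Musculoskeletal and connective tissue disorders
Back pain,Musculoskeletal and connective tissue disorders
Acute kidney injury,Renal and urinary disorders
Renal impairment,Renal and urinary disorders
Tachycardia,Cardiac disorders
Palpitations,Cardiac disorders
Insomnia,Psychiatric disorders
Anxiety,Psychiatric disorders
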