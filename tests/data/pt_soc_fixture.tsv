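pt	soc
Injection-site vasculitis	General disorders and administration-site conditions
Injection-site phlebitis	General disorders and administration-site conditions
Infusion-site phlebitis	General disorders and administration-site conditions
Infusion-site irritation	General disorders and administration-site conditions
Infusion-site urticaria	General disorders and administration-site conditions
Infusion-site rash	General disorders and administration-site conditions
Infusion-site reaction	General disorders and administration-site conditions
Infusion-site pain	General disorders and administration-site conditions
Infusion-site discomfort	General disorders and administration-site conditions
Infusion-site induration	General disorders and administration-site conditions
Injection-site atrophy	General disorders and administration-site conditions
Injection-site induration	General disorders and administration-site conditions
Infusion-site extravasation	General disorders and administration-site conditions
Infusion-site pruritus	General disorders and administration-site conditions
Disease progression	General disorders and administration-site conditions
Drug interaction	General disorders and administration-site conditions
Death	General disorders and administration-site conditions
Vein discoloration	Vascular disorders
Phlebitis	Vascular disorders
Flushing	Vascular disorders
Testicular germ cell cancer metastatic	Benign, malignant, and unspecified neoplasms (including cysts and polyps)
Seminoma	Benign, malignant, and unspecified neoplasms (including cysts and polyps)
Recurrent cancer	Benign, malignant, and unspecified neoplasms (including cysts and polyps)
Computerized tomogram thorax abnormal	Investigations
Pulse pressure decreased	Investigations
Hiccups	Respiratory, thoracic, and mediastinal disorders
Dyspnoea	Respiratory, thoracic, and mediastinal disorders
Joint deposit	Musculoskeletal and connective tissue disorders
Radiation esophagitis	Injury, poisoning, and procedural complications
Infusion-related hypersensitivity reaction	Immune system disorders
Seizure-like phenomena	Nervous system disorders
Serotonin syndrome	Nervous system disorders
Encephalopathy	Nervous system disorders
Injection-site cellulitis	Infections and infestations
Septic shock	Infections and infestations
Neutropenic colitis	Gastrointestinal disorders
Colitis	Gastrointestinal disorders
Stomatitis	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Leukopenia	Blood and lymphatic system disorders
Neutropenia	Blood and lymphatic system disorders
Febrile neutropenia	Blood and lymphatic system disorders
Hyponatremia	Metabolism and nutrition disorders
Dehydration	Metabolism and nutrition disorders
Bradycardia	Cardiac disorders
Tachycardia	Cardiac disorders
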