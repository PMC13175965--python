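pt	soc
Hypophysitis	Endocrine disorders
Adrenal insufficiency	Endocrine disorders
Hypothyroidism	Endocrine disorders
Hyperthyroidism	Endocrine disorders
Thyroiditis	Endocrine disorders
Hypopituitarism	Endocrine disorders
Fulminant type 1 diabetes mellitus	Endocrine disorders
Immune-mediated hepatitis	Hepatobiliary disorders
Autoimmune hepatitis	Hepatobiliary disorders
Hepatitis	Hepatobiliary disorders
Cholangitis	Hepatobiliary disorders
Hepatic failure	Hepatobiliary disorders
Hyperbilirubinaemia	Hepatobiliary disorders
Myocarditis	Cardiac disorders
Immune-mediated myocarditis	Cardiac disorders
Pericarditis	Cardiac disorders
Cardiac failure	Cardiac disorders
Atrial fibrillation	Cardiac disorders
Myocardial infarction	Cardiac disorders
Pneumonitis	Respiratory, thoracic and mediastinal disorders
Immune-mediated lung disease	Respiratory, thoracic and mediastinal disorders
Interstitial lung disease	Respiratory, thoracic and mediastinal disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Cough	Respiratory, thoracic and mediastinal disorders
Pleural effusion	Respiratory, thoracic and mediastinal disorders
Colitis	Gastrointestinal disorders
Immune-mediated enterocolitis	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Pancreatitis	Gastrointestinal disorders
Myasthenia gravis	Nervous system disorders
Encephalitis	Nervous system disorders
Guillain-Barre syndrome	Nervous system disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Neuropathy peripheral	Nervous system disorders
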