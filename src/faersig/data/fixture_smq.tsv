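smq	pt	scope
Hypothyroidism (SMQ)	Hypothyroidism	narrow
Hypothyroidism (SMQ)	Thyroiditis	narrow
Hypothyroidism (SMQ)	Hypopituitarism	broad
Noninfectious hepatitis (SMQ)	Immune-mediated hepatitis	narrow
Noninfectious hepatitis (SMQ)	Autoimmune hepatitis	narrow
Noninfectious hepatitis (SMQ)	Hepatitis	narrow
Noninfectious hepatitis (SMQ)	Hyperbilirubinaemia	broad
Noninfectious myocarditis/pericarditis (SMQ)	Myocarditis	narrow
Noninfectious myocarditis/pericarditis (SMQ)	Immune-mediated myocarditis	narrow
Noninfectious myocarditis/pericarditis (SMQ)	Pericarditis	narrow
Noninfectious myocarditis/pericarditis (SMQ)	Cardiac failure	broad
Interstitial lung disease (SMQ)	Interstitial lung disease	narrow
Interstitial lung disease (SMQ)	Pneumonitis	narrow
Interstitial lung disease (SMQ)	Immune-mediated lung disease	narrow
Interstitial lung disease (SMQ)	Cough	broad
Interstitial lung disease (SMQ)	Dyspnoea	broad
Gastrointestinal nonspecific inflammation (SMQ)	Colitis	narrow
Gastrointestinal nonspecific inflammation (SMQ)	Immune-mediated enterocolitis	narrow
Gastrointestinal nonspecific inflammation (SMQ)	Diarrhoea	broad
Noninfectious encephalitis (SMQ)	Encephalitis	narrow
Noninfectious encephalitis (SMQ)	Headache	broad
Guillain-Barre syndrome (SMQ)	Guillain-Barre syndrome	narrow
Guillain-Barre syndrome (SMQ)	Myasthenia gravis	broad
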