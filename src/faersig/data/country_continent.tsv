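country	continent
US	North America
CA	North America
MX	North America
JP	Asia
CN	Asia
KR	Asia
IN	Asia
TW	Asia
SG	Asia
IL	Asia
GB	Europe
DE	Europe
FR	Europe
IT	Europe
ES	Europe
NL	Europe
SE	Europe
DK	Europe
CH	Europe
AT	Europe
BE	Europe
PL	Europe
BR	South America
AR	South America
CL	South America
CO	South America
AU	Oceania
NZ	Oceania
ZA	Africa
EG	Africa
NG	Africa
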