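USA	North America	High income
CHN	Asia	Upper middle income
JPN	Asia	High income
DEU	Europe	High income
GBR	Europe	High income
FRA	Europe	High income
CHE	Europe	High income
BRA	South America	Upper middle income
IND	Asia	Lower middle income
MWI	Africa	Low income
ZAF	Africa	Upper middle income
LUX	Europe	High income
ATA	Antarctica	Not classified
TUR	Asia	Upper middle income
NGA	Africa	Lower middle income
KEN	Africa	Lower middle income
AUS	Oceania	High income
CAN	North America	High income
MEX	North America	Upper middle income
ITA	Europe	High income
ESP	Europe	High income
KOR	Asia	High income
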