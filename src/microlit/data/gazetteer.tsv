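United States	USA	ci
United States of America	USA	ci
USA	USA	cs
U.S.A.	USA	cs
Boston	USA	ci
New York	USA	ci
China	CHN	ci
Shanghai	CHN	ci
Beijing	CHN	ci
Japan	JPN	ci
Tokyo	JPN	ci
Yokohama	JPN	ci
Germany	DEU	ci
Berlin	DEU	ci
United Kingdom	GBR	ci
London	GBR	ci
France	FRA	ci
Paris	FRA	cs
Switzerland	CHE	ci
Brazil	BRA	ci
Sao Paulo	BRA	ci
São Paulo	BRA	ci
India	IND	ci
New Delhi	IND	ci
Malawi	MWI	ci
Blantyre	MWI	ci
South Africa	ZAF	ci
Luxembourg	LUX	ci
Antarctica	ATA	ci
Turkey	TUR	cs
Türkiye	TUR	ci
Nigeria	NGA	ci
Kenya	KEN	ci
Australia	AUS	ci
Canada	CAN	ci
Mexico	MEX	ci
Italy	ITA	ci
Spain	ESP	ci
South Korea	KOR	ci
Republic of Korea	KOR	ci
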