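country,region
Ethiopia,Africa
Niger,Africa
Kenya,Africa
Malawi,Africa
Nigeria,Africa
Chad,Africa
Mali,Africa
Somalia,Africa
Sudan,Africa
South Sudan,Africa
Uganda,Africa
Zambia,Africa
Zimbabwe,Africa
Mozambique,Africa
Madagascar,Africa
Burkina Faso,Africa
Senegal,Africa
Bangladesh,South-East Asia
Nepal,South-East Asia
Myanmar,South-East Asia
India,South-East Asia
Indonesia,South-East Asia
Sri Lanka,South-East Asia
Timor-Leste,South-East Asia
Yemen,Middle East
Afghanistan,Middle East
Iraq,Middle East
Syria,Middle East
Jordan,Middle East
Pakistan,Middle East
Haiti,Americas
Guatemala,Americas
Honduras,Americas
Nicaragua,Americas
Bolivia,Americas
Peru,Americas
Albania,Eastern Europe
Tajikistan,Eastern Europe
Kyrgyzstan,Eastern Europe
Uzbekistan,Eastern Europe
Armenia,Eastern Europe
Moldova,Eastern Europe
Cambodia,Western Pacific
Laos,Western Pacific
Vietnam,Western Pacific
Philippines,Western Pacific
Mongolia,Western Pacific
Papua New Guinea,Western Pacific
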