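# Default hazard registry for the five-industry demonstration dataset.
# RfC values (ug/m3) follow the toxicological reference concentrations used
# for the four focal chemicals; OELs (mg/m3), acute-toxicity data and risk
# phrases marked "placeholder" in notes are GBZ 2.1-2019 / ACGIH-style
# defaults the user must confirm before regulatory use.
name,cas,rfc,iur,oel_china_twa,oel_acgih_twa,carcinogenicity,ld50_oral,lc50_inhal,risk_phrases,physical_form,dustiness_band,volatility_band,hr_override,notes
Silicious dust,14808-60-7,,,1.0,0.025,IARC-1,,,R49;R48/20,solid,high,,,OELs placeholder (GBZ 2.1 total silica dust / ACGIH respirable quartz)
Other dust,,,,8.0,,none,,,,solid,low,,2,OEL and HR placeholder (particles not otherwise regulated)
Iron dust,,,,4.0,,none,,,,solid,low,,2,OEL and HR placeholder (iron oxide dust)
Welding fume,,,,4.0,5.0,IARC-2B,,,R37,solid,high,,,OELs and phrases placeholder
Manganese and inorganic compounds,7439-96-5,0.05,,0.15,0.1,none,9000,,R20/22,solid,medium,,4,OELs placeholder; HR override = expert judgment (neurotoxicant)
Nitrogen oxides,10102-44-0,,,5.0,5.6,none,,115,R23,gas,,,,OELs and LC50 placeholder (as NO2)
Grinding wheel dust,,,,8.0,,none,,,,solid,medium,,2,OEL and HR placeholder
Benzene,71-43-2,30,,6.0,1.6,IARC-1,930,,R45;R46;R11;R48/23,liquid,,medium,,OELs placeholder
Xylene,1330-20-7,100,,50.0,434.0,IARC-3,3500,,R20/21;R38,liquid,,medium,,OELs placeholder
Ethyl acetate,141-78-6,3500,,200.0,1440.0,none,5620,,R11;R36;R66;R67,liquid,,medium,,OELs placeholder
Iron-ore dust,,,,4.0,,none,,,,solid,medium,,2,OEL and HR placeholder
Talc dust,14807-96-6,,,3.0,2.0,none,,,,solid,medium,,2,OELs and HR placeholder
Gasoline,86290-81-5,,,300.0,890.0,IARC-2B,14000,,R12;R45;R65;R38,liquid,,high,,OELs placeholder (solvent gasoline)
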