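# Five-industry exposure structure: per-location record count, mean and
# min-max concentration (mg/m3).  Row counts follow the published location
# counts, adjusted so each industry total matches the published per-industry
# record counts (148 / 97 / 989 / 85 / 200, total 1519): ship-repair
# manganese 208->210, equipment talc polishing 15->14, and the 20 ferrous
# casting locations split 10/10 between the two hazards measured there.
industry,location,hazard,n,mean,min,max
Mining of soil and sand,Rig operator,Silicious dust,19,2.275,0.186,21.6
Mining of soil and sand,Excavator driver,Silicious dust,26,0.892,0.143,2.986
Mining of soil and sand,Transport driver,Silicious dust,25,1.107,0.200,3.429
Mining of soil and sand,Stope inspector,Silicious dust,11,0.989,0.333,2.186
Mining of soil and sand,Discharge,Silicious dust,15,2.216,0.357,10.729
Mining of soil and sand,Crushing inspector,Silicious dust,26,1.218,0.186,4.714
Mining of soil and sand,Forklift driver,Silicious dust,15,0.901,0.171,4.233
Mining of soil and sand,Sprinkler driver,Silicious dust,11,0.617,0.143,0.943
Ferrous casting,Molding,Silicious dust,43,1.372,0.200,7.200
Ferrous casting,Smelting,Other dust,6,0.158,0.050,0.363
Ferrous casting,Casting,Silicious dust,10,0.761,0.020,1.660
Ferrous casting,Casting,Iron dust,10,0.136,0.030,0.363
Ferrous casting,Sand stripping,Silicious dust,23,1.237,0.150,7.500
Ferrous casting,Shot blasting,Silicious dust,5,5.900,0.500,13.60
Ship repair,Electrowelding,Welding fume,208,1.355,0.050,7.575
Ship repair,Electrowelding,Manganese and inorganic compounds,210,0.956,0.003,28.98
Ship repair,Electrowelding,Nitrogen oxides,208,0.013,0.002,0.038
Ship repair,Polishing,Grinding wheel dust,176,0.618,0.025,5.378
Ship repair,Spraying,Benzene,44,0.037,0.008,0.200
Ship repair,Spraying,Xylene,44,1.149,0.001,12.89
Ship repair,Spraying,Ethyl acetate,44,0.002,0.0003,0.031
Ship repair,Sanding,Iron-ore dust,55,1.549,0.060,5.483
Equipment repair,Electrowelding,Welding fume,12,0.071,0.025,0.225
Equipment repair,Electrowelding,Manganese and inorganic compounds,12,0.027,0.007,0.073
Equipment repair,Polishing,Grinding wheel dust,11,0.032,0.014,0.074
Equipment repair,Paint mixing,Benzene,3,0.05,0.05,0.05
Equipment repair,Paint mixing,Xylene,3,0.023,0.010,0.030
Equipment repair,Paint mixing,Ethyl acetate,3,0.0007,0.0007,0.0007
Equipment repair,Spraying,Benzene,9,0.068,0.008,0.1
Equipment repair,Spraying,Xylene,9,0.0468,0.001,0.16
Equipment repair,Spraying,Ethyl acetate,9,0.001,0.0004,0.005
Equipment repair,Polishing,Talc dust,14,0.127,0.025,0.525
Petrol station,Oiling,Gasoline,100,0.044,0.0003,0.491
Petrol station,Oil discharge,Gasoline,100,0.006,0.0003,0.096
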