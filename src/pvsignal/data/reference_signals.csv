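drug,n_reports,atc_class,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,ebgm05,ic,ic_025
mirabegron,3,Urogenital System and Sex Hormone Drugs,80.255,25.750,250.135,79.730,232.663,79.533,30.722,6.313,4.640
raloxifene,26,Urogenital System and Sex Hormone Drugs,67.511,45.723,99.681,67.147,1657.496,65.708,47.426,6.038,4.370
tadalafil,14,Urogenital System and Sex Hormone Drugs,36.190,21.350,61.343,36.085,472.024,35.674,22.940,5.157,3.488
sildenafil,47,Urogenital System and Sex Hormone Drugs,25.685,19.181,34.394,25.634,1068.974,24.665,19.319,4.624,2.956
vardenafil,3,Urogenital System and Sex Hormone Drugs,21.859,7.033,67.944,21.822,59.458,21.769,8.428,4.444,2.775
drospirenone,11,Urogenital System and Sex Hormone Drugs,10.883,6.009,19.711,10.874,97.726,10.873,6.560,3.431,1.763
estradiol,6,Urogenital System and Sex Hormone Drugs,7.302,3.273,16.291,7.298,32.451,7.267,3.713,2.861,1.193
bimatoprost,4,Sensory Organ Drugs,26.757,10.015,71.487,26.700,98.626,26.614,11.695,4.734,3.065
brimonidine,3,Sensory Organ Drugs,25.307,8.140,78.671,25.256,69.716,25.195,9.753,4.655,2.985
verteporfin,4,Sensory Organ Drugs,19.716,7.382,52.662,19.686,70.715,19.623,8.625,4.294,2.626
aripiprazole,5,Nervous System Drugs,7.608,3.160,18.317,7.604,28.558,7.576,3.632,2.921,1.253
celecoxib,4,Musculoskeletal System Drugs,19.620,7.346,52.404,19.590,70.333,19.528,8.583,4.287,2.618
rofecoxib,47,Musculoskeletal System Drugs,3.734,2.789,4.999,3.733,90.354,3.626,2.840,1.858,0.190
fingolimod,6,Antitumor and Immunomodulating Drugs,29.746,13.324,66.411,29.675,165.433,29.531,15.081,4.884,3.215
sorafenib,4,Antitumor and Immunomodulating Drugs,19.485,7.295,52.044,19.455,69.798,19.394,8.524,4.278,2.609
anastrozole,7,Antitumor and Immunomodulating Drugs,15.592,7.413,32.793,15.573,94.908,15.487,8.314,3.953,2.285
upadacitinib,8,Antitumor and Immunomodulating Drugs,10.534,5.254,21.120,10.526,68.513,10.462,5.846,3.387,1.719
encorafenib,3,Antitumor and Immunomodulating Drugs,9.469,3.048,29.416,9.463,22.650,9.441,3.657,3.239,1.570
ponatinib,7,Antitumor and Immunomodulating Drugs,8.959,4.260,18.838,8.953,49.166,8.906,4.782,3.155,1.487
peginterferon beta-1a,3,Antitumor and Immunomodulating Drugs,8.365,2.693,25.985,8.360,19.393,8.342,3.231,3.060,1.392
letrozole,4,Antitumor and Immunomodulating Drugs,6.498,2.434,17.347,6.495,18.536,6.477,2.848,2.695,1.027
vemurafenib,10,Antitumor and Immunomodulating Drugs,6.128,3.288,11.421,6.125,42.532,6.083,3.613,2.605,0.937
dabrafenib,4,Antitumor and Immunomodulating Drugs,4.838,1.812,12.914,4.836,12.133,4.824,2.121,2.270,0.602
tacrolimus,7,Antitumor and Immunomodulating Drugs,4.401,2.093,9.254,4.400,18.286,4.380,2.352,2.131,0.463
hydroxychloroquine,3,Antiparasitic Drugs,10.005,3.221,31.080,9.997,24.233,9.975,3.864,3.318,1.650
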