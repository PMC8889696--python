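# population_units: thousands
# Ancestry-mixture weights and first-cousin-or-closer consanguinity rates per
# country. The source weight vectors are not published: weights here are
# SYNTHETIC back-derivations solving w.f = sqrt(published baseline prevalence)
# as two-group mixtures, and consanguinity rates invert the published
# baseline->adjusted pairs through the inbreeding adjustment (F=1/16). Four
# Latin American countries publish carrier frequencies above the largest group
# frequency (0.001404); no convex mixture reaches them (see note column).
country,population,w_nfe,w_afr,w_amr,w_asian,consanguinity,note
Argentina,45914,0.0,0.0,1.0,0.0,0.001994,published carrier frequency exceeds max group frequency; clamped to AMR
Australia,25700,0.641908,0.0,0.0,0.358092,0.001932,
Austria,8801,0.769467,0.0,0.0,0.230533,0.004896,
Bahrain,1744,0.278395,0.0,0.0,0.721605,0.067942,
Belgium,11669,0.813394,0.0,0.0,0.186606,0.01013,
Brazil,215278,0.10879,0.0,0.89121,0.0,0.012981,
Canada,37924,0.628099,0.0,0.0,0.371901,0.015055,
Chile,18605,0.0,0.0,1.0,0.0,0.00703,published carrier frequency exceeds max group frequency; clamped to AMR
Colombia,50576,0.0,0.0,1.0,0.0,0.011047,published carrier frequency exceeds max group frequency; clamped to AMR
Croatia,4092,0.798669,0.0,0.0,0.201331,0.001024,
Czech Republic,10634,0.888324,0.0,0.0,0.111676,0.001945,
Denmark,5819,0.784027,0.0,0.0,0.215973,0.011883,
Finland,5599,0.769467,0.0,0.0,0.230533,0.001013,
France,65955,0.587082,0.0,0.0,0.412918,0.008048,
Germany,82591,0.828204,0.0,0.0,0.171796,0.00708,
Ireland,4926,0.784027,0.0,0.0,0.215973,0.005093,
Israel,8842,0.740589,0.0,0.0,0.259411,0.11471,
Italy,59038,0.754988,0.0,0.0,0.245012,0.005037,
Japan,126109,0.0,0.0,0.409091,0.590909,0.039066,
South Korea,51667,0.0,0.0,0.430912,0.569088,0.0,
Kuwait,4361,0.352617,0.0,0.0,0.647383,0.171243,
Mexico,135384,0.0,0.0,1.0,0.0,0.003011,published carrier frequency exceeds max group frequency; clamped to AMR
Netherlands,17230,0.754988,0.0,0.0,0.245012,0.002015,
New Zealand,4876,0.726267,0.0,0.0,0.273733,0.001993,
Norway,5500,0.813394,0.0,0.0,0.186606,0.000858,
Poland,37847,0.798669,0.0,0.0,0.201331,0.004951,
Portugal,10183,0.754988,0.0,0.0,0.245012,0.01511,
Qatar,2840,0.182107,0.0,0.0,0.817893,0.222378,
Russia,143637,0.798669,0.0,0.0,0.201331,0.007,
Saudi Arabia,35263,0.697853,0.0,0.0,0.302147,0.224785,
Spain,46450,0.683758,0.0,0.0,0.316242,0.041028,
Sweden,10188,0.843101,0.0,0.0,0.156899,0.00608,
Switzerland,8731,0.828204,0.0,0.0,0.171796,0.006044,
Taiwan,23873,0.0,0.0,0.430912,0.569088,0.018063,
Turkey,84515,0.784027,0.0,0.0,0.215973,0.09218,
United Arab Emirates,9937,0.205906,0.0,0.0,0.794094,0.159455,
United Kingdom,67699,0.754988,0.0,0.0,0.245012,0.004029,
United States,333783,0.449174,0.0,0.550826,0.0,0.002068,
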