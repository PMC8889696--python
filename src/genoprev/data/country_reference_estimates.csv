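# Published per-country estimates (carrier frequency, baseline and
# consanguinity-adjusted birth prevalence per million live births with 95% CI,
# 2021 population in thousands, estimated living cases, population prevalence
# per million). Values transcribed at printed precision.
country,carrier_frequency,baseline_per_million,adjusted_per_million,adjusted_ci_low,adjusted_ci_high,population_thousands,cases,population_prevalence_per_million
Argentina,0.0017,2.85,3.06,2.11,4.56,45914,70,1.53
Australia,0.001,0.99,1.11,0.87,1.55,25700,14,0.56
Austria,0.0009,0.9,1.19,0.98,1.53,8801,5,0.6
Bahrain,0.0011,1.27,6.05,4.78,8.23,1744,5,3.02
Belgium,0.0009,0.87,1.46,1.23,1.84,11669,9,0.73
Brazil,0.0013,1.81,2.9,2.19,4.02,215278,312,1.45
Canada,0.001,1.0,1.94,1.55,2.62,37924,37,0.97
Chile,0.0016,2.62,3.33,2.37,4.82,18605,31,1.67
Colombia,0.0016,2.64,3.76,2.7,5.41,50576,95,1.88
Croatia,0.0009,0.88,0.94,0.76,1.23,4092,2,0.47
Czech Republic,0.0009,0.82,0.93,0.76,1.25,10634,5,0.47
Denmark,0.0009,0.89,1.59,1.35,1.97,5819,5,0.8
Finland,0.0009,0.9,0.96,0.77,1.27,5599,3,0.48
France,0.001,1.03,1.54,1.24,2.04,65955,51,0.77
Germany,0.0009,0.86,1.27,1.06,1.62,82591,52,0.64
Ireland,0.0009,0.89,1.19,0.97,1.55,4926,3,0.59
Israel,0.001,0.92,7.79,6.8,9.36,8842,34,3.9
Italy,0.001,0.91,1.21,0.99,1.56,59038,36,0.61
Japan,0.0013,1.69,4.86,3.46,7.43,126109,306,2.43
South Korea,0.0013,1.7,1.7,1.02,3.15,51667,44,0.85
Kuwait,0.0011,1.21,12.97,10.58,16.92,4361,28,6.49
Mexico,0.0016,2.55,2.85,1.99,4.2,135384,193,1.43
Netherlands,0.001,0.91,1.03,0.82,1.38,17230,9,0.51
New Zealand,0.001,0.93,1.05,0.82,1.49,4876,3,0.52
Norway,0.0009,0.87,0.92,0.75,1.22,5500,3,0.46
Poland,0.0009,0.88,1.17,0.97,1.5,37847,22,0.59
Portugal,0.001,0.91,1.81,1.53,2.24,10183,9,0.9
Qatar,0.0012,1.35,17.48,13.95,23.28,2840,25,8.74
Russia,0.0009,0.88,1.29,1.08,1.63,143637,93,0.65
Saudi Arabia,0.001,0.95,14.63,12.79,17.48,35263,258,7.32
Spain,0.001,0.96,3.47,2.98,4.22,46450,81,1.73
Sweden,0.0009,0.85,1.2,1.0,1.54,10188,6,0.6
Switzerland,0.0009,0.86,1.21,1.01,1.56,8731,5,0.6
Taiwan,0.0013,1.7,3.17,2.15,5.14,23873,38,1.58
Turkey,0.0009,0.89,6.32,5.59,7.39,84515,267,3.16
United Arab Emirates,0.0012,1.33,12.81,10.09,17.44,9937,64,6.4
United Kingdom,0.001,0.91,1.15,0.92,1.55,67699,39,0.58
United States,0.0012,1.35,1.5,1.09,2.2,333783,250,0.75
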