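group,min_dlp,n_crosses,mean_linkage,min_linkage,max_linkage,n_optimal_linkage,mean_independent,min_independent,max_independent,n_optimal_independent
ER-I,18.9,903,36.6,12.6,62.3,9,36.3,10.4,60.6,16
ER-II,17.2,5253,34.3,9.4,62.4,79,33.9,10.3,60.3,85
ER-III,30.2,2485,42.1,20.2,65.5,140,41.4,16.8,65.5,191
ER-IV,19.8,3160,39.1,5.1,71.1,106,39.1,8.9,71.3,83
ER-V,25.0,561,35.3,20.4,55.8,23,35.1,20.5,56.5,30
ER-VI,20.3,741,33.0,5.7,59.1,70,32.4,9.5,59.9,73
Within,17.2,13103,37.1,5.1,71.1,180,36.7,8.9,71.3,171
Between,17.2,55162,37.0,3.0,71.7,695,36.6,6.7,70.6,659
All,17.2,68265,37.0,3.0,71.7,875,36.6,6.7,71.3,830
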