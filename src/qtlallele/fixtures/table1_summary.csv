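group,bin_15,bin_20,bin_25,bin_30,bin_35,bin_40,bin_45,bin_50,bin_55,bin_60,bin_65,bin_70,bin_75,bin_80,n,mean,min,max,f_value,h2,gcv,cv
All,1,6,28,30,45,62,47,50,44,27,18,7,4,1,370,44.5,17.2,79.9,6.2,77.3,24.1,19.1
ER-I,0,1,2,5,4,7,6,6,7,3,0,0,2,0,43,44.6,18.9,74.9,3.7,63.3,21.7,24.7
ER-II,1,1,11,11,14,18,12,12,14,7,0,2,0,0,103,42.0,17.2,69.5,5.3,72.1,22.9,20.3
ER-III,0,0,0,3,8,16,8,8,10,6,10,2,0,0,71,49.3,30.2,70.3,5.9,75.9,19.7,16.2
ER-IV,0,2,6,4,9,9,10,13,10,5,7,2,2,1,80,46.9,19.8,79.9,9.3,83.3,13.6,16.3
ER-V,0,0,3,2,6,8,4,8,0,3,0,0,0,0,34,41.7,25.0,62.1,5.7,77.5,20.1,16.6
ER-VI,0,2,6,5,4,4,7,3,3,3,1,1,0,0,39,40.2,20.3,67.5,6.6,80.1,28.4,21.4
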