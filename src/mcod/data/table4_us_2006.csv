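sex,age_band,uc_deaths,uc_rate,mc_deaths,mc_rate
male,0-14,0,0.0,0,0.0
female,0-14,1,0.0,2,0.0
total,0-14,1,0.0,2,0.0
male,15-24,0,0.0,0,0.0
female,15-24,1,0.0,0,0.0
total,15-24,1,0.0,0,0.0
male,25-34,0,0.0,3,0.0
female,25-34,0,0.0,0,0.0
total,25-34,0,0.0,0,0.0
male,35-44,4,0.0,4,0.0
female,35-44,1,0.0,4,0.0
total,35-44,5,0.0,0,0.0
male,45-54,36,0.2,67,0.3
female,45-54,16,0.1,30,0.1
total,45-54,52,0.1,97,0.2
male,55-64,251,1.7,450,3.0
female,55-64,130,0.8,239,1.5
total,55-64,381,1.2,689,2.2
male,65-74,1512,17.4,2677,30.9
female,65-74,783,7.6,1359,13.3
total,65-74,2295,12.1,4036,21.3
male,75-84,5517,104.1,9665,182.4
female,75-84,3544,45.7,6147,79.3
total,75-84,9061,69.5,15812,121.2
male,85+,3894,230.7,6860,406.3
female,85+,3741,103.7,6809,188.7
total,85+,7635,144.1,13669,258.1
male,total,11214,7.6,19726,13.4
female,total,8217,5.4,14590,9.6
total,total,19431,6.5,34316,11.5
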