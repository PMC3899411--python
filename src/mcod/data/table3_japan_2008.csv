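sex,age_band,uc_deaths,uc_rate,mc_deaths,mc_rate
male,0-14,0,0.0,0,0.0
female,0-14,0,0.0,0,0.0
total,0-14,0,0.0,0,0.0
male,15-24,0,0.0,0,0.0
female,15-24,0,0.0,0,0.0
total,15-24,0,0.0,0,0.0
male,25-34,0,0.0,0,0.0
female,25-34,0,0.0,0,0.0
total,25-34,0,0.0,0,0.0
male,35-44,2,0.0,2,0.0
female,35-44,1,0.0,2,0.0
total,35-44,3,0.0,4,0.0
male,45-54,6,0.1,9,0.1
female,45-54,7,0.1,10,0.1
total,45-54,13,0.1,19,0.1
male,55-64,53,0.6,83,0.9
female,55-64,32,0.3,45,0.5
total,55-64,85,0.5,128,0.7
male,65-74,381,5.4,623,8.8
female,65-74,297,3.7,407,5.1
total,65-74,678,4.5,1030,6.9
male,75-84,1187,29.4,2023,50.1
female,75-84,1214,21.2,1769,30.9
total,75-84,2401,24.6,3792,38.8
male,85+,495,52.4,911,96.5
female,85+,914,36.4,1549,61.8
total,85+,1409,40.8,2461,71.3
male,total,2124,3.4,3652,5.9
female,total,2465,3.8,3782,5.8
total,total,4589,3.6,7434,5.8
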