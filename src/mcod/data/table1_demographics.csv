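characteristic,level,all_value,all_pct_or_sd,sampled_value,sampled_pct_or_sd
sex,men,2124,46.3,208,43.6
sex,women,2465,53.7,269,56.4
age_mean,men,79.5,7.2,80.1,7.2
age_mean,women,82.0,7.3,82.7,6.9
age_mean,both,80.9,7.4,81.6,7.1
marital_status,married,2380,51.9,239,50.1
marital_status,single,184,4.0,21,4.4
marital_status,bereaved,1865,40.6,200,41.9
marital_status,separated,158,3.4,17,3.6
marital_status,unknown,2,0.0,0,0.0
occupation,farming,349,7.6,48,10.1
occupation,self_employed,242,5.3,31,6.5
occupation,employed,570,12.5,60,12.5
occupation,other,302,6.6,29,6.1
occupation,unemployed,2718,59.2,266,55.8
occupation,unknown,408,8.9,43,9.0
place_of_death,hospital,3496,76.2,363,76.1
place_of_death,clinic,156,3.4,11,2.3
place_of_death,healthcare_facility_for_the_aged,103,2.2,15,3.1
place_of_death,nursing_home,325,7.1,33,6.9
place_of_death,home,466,10.2,48,10.1
place_of_death,other,43,0.9,7,1.5
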