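# Synthetic approximation of Singapore female breast-cancer incidence
# (2013-2017-era registry scale) and non-breast-cancer mortality
# (2016-era), per 100,000 person-years, in 5-year age intervals, overall
# and by major ethnic group.  Hand-written stand-in for the restricted
# registry tables; not an official extract.
age_low,age_high,incidence_per_100k_py,mortality_per_100k_py,population
30,35,26,30,overall
35,40,62,45,overall
40,45,112,70,overall
45,50,162,110,overall
50,55,192,170,overall
55,60,204,270,overall
60,65,214,430,overall
65,70,204,720,overall
70,75,192,1250,overall
75,80,182,2300,overall
30,35,27,28,Chinese
35,40,64,42,Chinese
40,45,116,66,Chinese
45,50,168,104,Chinese
50,55,198,160,Chinese
55,60,210,255,Chinese
60,65,220,410,Chinese
65,70,210,690,Chinese
70,75,198,1200,Chinese
75,80,188,2200,Chinese
30,35,24,38,Malay
35,40,56,58,Malay
40,45,100,92,Malay
45,50,146,145,Malay
50,55,174,225,Malay
55,60,186,355,Malay
60,65,194,560,Malay
65,70,184,930,Malay
70,75,172,1600,Malay
75,80,162,2900,Malay
30,35,22,34,Indian
35,40,52,52,Indian
40,45,94,82,Indian
45,50,138,130,Indian
50,55,164,200,Indian
55,60,176,320,Indian
60,65,184,500,Indian
65,70,176,840,Indian
70,75,164,1450,Indian
75,80,156,2650,Indian
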