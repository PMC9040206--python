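# Synthetic approximation of US white-female breast-cancer incidence and
# competing (non-breast-cancer) mortality, 5-year age intervals, per
# 100,000 person-years.  Values are rounded approximations of recent
# SEER-era registry rates, bundled as a reference fixture for the
# average-woman 5-year-risk screening threshold; they are not an official
# SEER extract.
age_low,age_high,incidence_per_100k_py,mortality_per_100k_py,population
30,35,28,70,us_white
35,40,62,95,us_white
40,45,126,140,us_white
45,50,192,210,us_white
50,55,250,310,us_white
55,60,280,480,us_white
60,65,340,740,us_white
65,70,400,1100,us_white
70,75,430,1700,us_white
75,80,445,2800,us_white
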