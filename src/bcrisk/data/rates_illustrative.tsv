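# Illustrative (synthetic) age-band breast-cancer incidence and competing
# (non-breast-cancer) mortality rates, per 100,000 person-years, shaped to
# resemble a Southeast-Asian female population. These are NOT official
# registry values; swap in a calibrated table for real use.
age_start	age_end	incidence_per_100k	mortality_per_100k
20	25	2	60
25	30	6	70
30	35	15	90
35	40	30	120
40	45	55	180
45	50	80	280
50	55	100	450
55	60	115	700
60	65	125	1100
65	70	130	1800
70	75	135	2900
75	80	140	4800
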