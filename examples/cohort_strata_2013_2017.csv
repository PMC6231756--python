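year,category,percent
2013,LARGE_METRO,48.86
2013,SMALL_METRO,33.16
2013,NONMETRO,17.98
2014,LARGE_METRO,50.63
2014,SMALL_METRO,32.53
2014,NONMETRO,16.83
2015,LARGE_METRO,48.86
2015,SMALL_METRO,33.05
2015,NONMETRO,18.08
2016,LARGE_METRO,43.85
2016,SMALL_METRO,36.7
2016,NONMETRO,19.45
2017,LARGE_METRO,42.65
2017,SMALL_METRO,36.24
2017,NONMETRO,21.11
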