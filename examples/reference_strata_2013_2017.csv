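year,category,percent
2013,LARGE_METRO,48.14
2013,SMALL_METRO,31.63
2013,NONMETRO,20.23
2014,LARGE_METRO,50.07
2014,SMALL_METRO,31.0
2014,NONMETRO,18.93
2015,LARGE_METRO,50.29
2015,SMALL_METRO,32.93
2015,NONMETRO,16.78
2016,LARGE_METRO,49.21
2016,SMALL_METRO,31.99
2016,NONMETRO,18.8
2017,LARGE_METRO,48.18
2017,SMALL_METRO,33.65
2017,NONMETRO,18.17
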