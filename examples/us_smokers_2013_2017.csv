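year,category,smokers_thousands
2013,LARGE_METRO,26849
2013,SMALL_METRO,17643
2013,NONMETRO,11286
2014,LARGE_METRO,27656
2014,SMALL_METRO,17125
2014,NONMETRO,10459
2015,LARGE_METRO,26124
2015,SMALL_METRO,17108
2015,NONMETRO,8719
2016,LARGE_METRO,25259
2016,SMALL_METRO,16421
2016,NONMETRO,9653
2017,LARGE_METRO,23458
2017,SMALL_METRO,16385
2017,NONMETRO,8849
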