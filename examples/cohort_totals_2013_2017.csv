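year,n
2013,33484
2014,18255
2015,5491
2016,1820
2017,8832
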