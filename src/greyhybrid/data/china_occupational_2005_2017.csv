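year,count,regions
2005,12212,30
2006,11805,29
2007,14296,30
2008,13744,30
2009,18128,30
2010,27240,30
2011,29879,30
2012,27420,30
2013,26393,30
2014,29972,30
2015,27389,31
2016,29838,31
2017,25114,31
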