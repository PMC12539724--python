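year,government_acres,total_acres
2013,9617,677272
2014,18758,440666
2015,30364,615086
2016,23889,561533
2017,24386,406832
2018,94465,880185
2019,201361,904624
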