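study_id,n_cases,prevalence_pos
Griewank 2013,38,0.31
Griewank 2014,362,0.43
Populo 2014,116,0.22
Egberts 2016,96,0.49
Nagore 2016,300,0.42
Ofner 2017,40,0.55
Roh 2017,88,0.17
Zehir 2017,164,0.75
de Unamuno Bustos 2018,170,0.31
Tan 2019,133,0.32
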