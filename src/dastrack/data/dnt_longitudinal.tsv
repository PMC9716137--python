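label	ordinal	dnt_percent	treatment
2017-05	1	7.4	false
2017-08	2	7.8	false
2017-11	3	1.9	true
2018-05	4	1.4	true
2018-12	5	1.76	true
2021-03	6	0.89	true
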