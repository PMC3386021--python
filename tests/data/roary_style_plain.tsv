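gene	iso1	iso2	iso3
group_0001	1	1	1
group_0002	1	0	1
group_0003	0	1	0
group_0004	1	1	1
group_0005	1	0	0
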