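chr1	45000000	46200000
chr1	52000000	53100000
chr1	60000000	60900000
chr21	100000	1300000
chr34	20000000	20900000
chr34	25000000	25700000
chr7	100000	5600000
chr8	30500000	31600000
chr8	41000000	41800000
chr9	12000000	13000000
chr9	30000000	30600000
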