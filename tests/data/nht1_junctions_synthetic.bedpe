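chr21	1299999	1300000	chr1	45000000	45000001	junction_00	34	+	-
chr1	46199999	46200000	chr8	31599999	31600000	junction_01	12	+	+
chr8	30500000	30500001	chr9	12000000	12000001	junction_02	27	-	-
chr9	12999999	13000000	chr1	53099999	53100000	junction_03	9	+	+
chr1	52000000	52000001	chr34	20000000	20000001	junction_04	18	-	-
chr34	20899999	20900000	chr8	41799999	41800000	junction_05	41	+	+
chr8	41000000	41000001	chr34	25000000	25000001	junction_06	15	-	-
chr34	25699999	25700000	chr9	30599999	30600000	junction_07	22	+	+
chr9	30000000	30000001	chr1	60000000	60000001	junction_08	11	-	-
chr1	60899999	60900000	chr7	5599999	5600000	junction_09	30	+	+
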