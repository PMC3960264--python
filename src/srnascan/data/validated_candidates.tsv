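name	location	start	end	strand	class
SYPCC_Igr_01	pSYSA	68081	68925	+	I_intergenic
SYPCC_Igr_02	chromosome	2530895	2530962	+	I_intergenic
SYPCC_Igr_03	pSYSG	15392	15481	+	I_intergenic
SYPCC_Igr_04	chromosome	496101	496321	+	I_intergenic
SYPCC_Igr_05	chromsome	1104709	1104929	+	I_intergenic
SYPCC_Igr_06	chromosome	3019919	3020058	-	I_intergenic
SYPCC_Igr_07	pSYSM	66503	66574	+	I_intergenic
SYPCC_Igr_08	chromosome	3039292	3039406	+	I_intergenic
SYPCC_Igr_09	chromosome	3305423	3305514	+	I_intergenic
SYPCC_anti_01	chromosome	407802	407923	+	II_antisense
SYPCC_anti_02	chromosome	1909216	1909443	-	II_antisense
SYPCC_anti_03	chromosome	2724266	2724365	-	II_antisense
SYPCC_anti_04	chromosome	279064	29161	-	II_antisense
SYPCC_anti_05	chromosome	346136	346282	+	II_antisense
SYPCC_anti_06	chromosome	2478723	2478824	-	II_antisense
SYPCC_anti_07	chromosome	940674	940896	+	II_antisense
SYPCC_anti_08	chromosome	1665302	1665520	+	II_antisense
SYPCC_anti_09	chromosome	2219904	2220106	-	II_antisense
SYPCC_anti_10	chromosome	1020080	1020302	-	II_antisense
SYPCC_anti_11	pSYSX	91564	91738	-	II_antisense
SYPCC_Ir_01	chromosome	1832226	1832339	+	III_leader
SYPCC_Ir_02	chromosome	2730512	2730591	+	III_leader
SYPCC_Ir_03	chromosome	3433172	3433275	+	III_leader
SYPCC_Ir_04	chromosome	901005	901125	+	III_leader
SYPCC_Ir_05	chromosome	458917	459162	+	III_leader
SYPCC_Ir_06	chromosome	3168882	3169030	+	III_leader
SYPCC_Ir_07	chromosome	102301	102387	-	III_leader
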