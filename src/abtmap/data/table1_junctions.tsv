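family	member	affected	translocation	junction_interval	junction_length_bp	read_pairs	breakpoint_interval	disrupted_genes	indel	microhomology	repeats
1	proband	yes	t(1;7)(p36.1;q22)	chr1:18163342–18163563	222	12	chr1:18163344–18163348	—	3bp-AGT del.	T	SINE-MIR-MIRb
1	proband	yes	t(1;7)(p36.1;q22)	chr7:99019714–99019855	142	12	chr7:99019710–99019714	PTCD1 & ATP5J2-PTCD1	3bp-AGA del.	CC	LINE-L1-L1M5
1	mother	no	t(1;7)(p36.1;q22)	chr1:18163366–18163436	71	17	chr1:18163344–18163348	—	3bp-AGT del.	T	SINE-MIR-MIRb
1	mother	no	t(1;7)(p36.1;q22)	chr7:99019342–99019746	405	17	chr7:99019710–99019714	PTCD1 & ATP5J2-PTCD1	3bp-AGA del.	CC	LINE-L1-L1M5
2	proband	yes	t(7;8)(q32;q24.13)	chr7:122515289–122515690	402	17	chr7:122515671–122515672	CADPS2	—	C	—
2	proband	yes	t(7;8)(q32;q24.13)	chr8:119865523–119866376	854	17	chr8:119866044–119866050	—	5bp-GTAAA del.	TAA	—
2	sibling	no	t(7;8)(q32;q24.13)	chr7:122514386–122515726	1341	20	chr7:122515671–122515672	CADPS2	—	C	—
2	sibling	no	t(7;8)(q32;q24.13)	chr8:119866031–119866086	56	20	chr8:119866044–119866050	—	5bp-GTAAA del.	TAA	—
3	proband	yes	t(4;10)(q35;q11.2)	chr4:189742584–189742790	207	15	chr4:189742651–189742656	—	4bp-ATCG del.	T	LINE-L2-L2a
3	proband	yes	t(4;10)(q35;q11.2)	chr10:43139092–43140045	954	15	chr10:43139266–43139272	—	5bp-CTGGC del.	—	SINE-Alu-AluSc
3	sibling	no	t(4;10)(q35;q11.2)	chr4:189742123–189743225	1103	26	chr4:189742651–189742656	—	4bp-ATCG del.	T	LINE-L2-L2a
3	sibling	no	t(4;10)(q35;q11.2)	chr10:43139186–43139369	184	26	chr10:43139266–43139272	—	5bp-CTGGC del.	—	SINE-Alu-AluSc
3	mother	no	t(4;10)(q35;q11.2)	chr4:189742483–189743387	905	25	chr4:189742651–189742656	—	4bp-ATCG del.	T	LINE-L2-L2a
3	mother	no	t(4;10)(q35;q11.2)	chr10:43139065–43140359	1295	25	chr10:43139266–43139272	—	5bp-CTGGC del.	—	SINE-Alu-AluSc
4	proband	yes	t(1;20)(p35.3;q13.3)	chr1:24738004–24738807	804	13	chr1:24738180–24738181	STPG1	—	C	SINE-Alu-AluJr4
4	proband	yes	t(1;20)(p35.3;q13.3)	chr20:56177192–56177656	465	13	chr20:56177612–56177613	—	2bp-GA dupl.	—	—
4	mother	no	t(1;20)(p35.3;q13.3)	chr1:24738108–24738220	113	15	chr1:24738180–24738181	STPG1	—	C	SINE-Alu-AluJr4
4	mother	no	t(1;20)(p35.3;q13.3)	chr20:56177454–56178424	971	15	chr20:56177612–56177613	—	2bp-GA dupl.	—	—
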