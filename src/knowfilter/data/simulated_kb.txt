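# simulated knowledge database (synthetic) for exploring knowfilter
build	simB1
source	light
source	paint
source	spectrum
gene	A	A	1 1000 2000
gene	B	B	2 1000 2000
gene	C	C	1 3000 4000
gene	D	D	2 3000 4000
gene	E	E	2 5000 6000
gene	F	F	1 5000 6000
gene	G	G	2 7000 8000
gene	H	H	2 9000 10000
gene	I	I	2 9500 10500
gene	J	J	3 1000 2000
gene	K	K	3 3000 4000
gene	L	L	3 5000 6000
gene	M	M	3 7000 8000;3 9000 9500
alias	DE	symbol	D,E
alias	Galt	symbol	G
alias	GH	symbol	G,H
alias	Jalt	symbol	J
alias	JK	symbol	J,K
alias	Lalt	symbol	L
alias	LM	symbol	L,M
alias	101	numeric	A
alias	103	numeric	C
alias	104	numeric	D
alias	p1	protein	D,E
alias	p2	protein	H,I
alias	p3	protein	I,J
snp	11	1	1100
snp	12	1	1500
snp	13	1	2500
snp	15	1	3200
snp	16	1	3900
snp	21	2	1500
snp	22	2	3500
snp	23	2	5500
snp	24	2	9800
snp	25	2	7500
snp	26	2	9200
snp	27	2	10200
snp	28	2	12000
snp	29	2	3600
snp	30	2	6500
snp	30	3	2500
snp	31	3	1500
snp	32	3	3500
snp	33	3	5500
snp	34	3	7500
snp	35	3	9200
snp	36	3	12000
merge	90	24
group	light	red	red
member	red	F:symbol
member	red	B:symbol
group	light	green	green
member	green	B:symbol
member	green	E:symbol
group	light	blue	blue
member	blue	A:symbol
member	blue	C:symbol
group	paint	gray_white	gray|white
member	gray_white	A:symbol
member	gray_white	C:symbol
member	gray_white	D:symbol
group	paint	cyan	cyan
member	cyan	A:symbol
member	cyan	C:symbol
member	cyan	D:symbol,DE:symbol
group	paint	magenta	magenta
member	magenta	G:symbol,Galt:symbol,GH:symbol
group	paint	yellow	yellow
member	yellow	J:symbol,Jalt:symbol,JK:symbol
group	spectrum	gray_black	gray|black
member	gray_black	L:symbol,Lalt:symbol,LM:symbol
group	spectrum	orange	orange
member	orange	H:symbol
member	orange	I:symbol
group	spectrum	indigo	indigo
member	indigo	p1:protein,D:symbol
member	indigo	K:symbol
group	spectrum	violet	violet
member	violet	p2:protein,p3:protein
member	violet	M:symbol
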