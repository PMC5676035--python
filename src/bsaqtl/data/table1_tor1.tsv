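strain	58	133	216	396	547	1117	1640	2414
BTC.1D	D	S	E	N	N	S	F	K
ER18	G	N	*	K	S	P	V	R
S288c	D	S	E	N	N	S	F	K
AWRI796		P	F	T	Y			K
BC 187	D	S	E	K	S	S	F	K
BY4741	D	S	E	N	N	S	F	K
BY4742	D	S	E	N	N	S	F	K
CBS7960			E	K	S	S	V	R
CEN.PK	D	S	E	K	S	S	V	R
D273-10B	G	N	E	K	S	S	V	R
DBVP6044	G	N	E	K	S	S	V	R
EC1118	D	S	E	K	S	S	V	K
EC9-8	G	N	E	K	S	S		
FL100	D	S	E	N	N	S	F	K
FY1679	D	S	E	N	N	S	F	K
FostersB	P	P	F	T	Y			X
FostersO			E	K	S			
JAY291	D	S	E	K	S	S	V	R
JK9-3d	D	S	E	K	S	S	V	R
K11	G	N	E	K	S	P	V	R
Kyokai7	G	N	E	K	S	P	V	R
L1528	D	S	E	K	S	S	F	K
LalvinQA23					Y			
RM11-1a	D	S	E	K	S	S	F	K
RedStar	G	N	E	K	S	S	F	R
SEY6210	D	S	E	K	S	S	V	R
SK1	G	N	E	K	S	S	V	R
UC5	G	N	E	K	S	P	V	R
VL3	D	S	E	K	S	S		
Vin13	D	S	E	K	S			
W303	D	S	E	N	N	S	F	K
X2180-1A	D	S	E	N	N	S	F	K
Y55	G	N	E	K	S	S	V	R
YJM269	G	N	E	K	S	S	V	R
YJM339	G	N	E	K	S	P	V	R
YJM789	G	N	E	K	S	P	V	R
YJM499	D	S	E	K	S	S	V	R
YPS128	G	N	E	K	S	S	V	R
YPS163	G	N	E	K	S	S	V	R
YS9	P	P	F	T	Y			R
ZTW1	G	N	E	K	S	S	V	R
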