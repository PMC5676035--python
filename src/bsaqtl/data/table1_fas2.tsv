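strain	57	565	1136	1624	1800
BTC.1D	T	N	T	I	N
ER18	A	S	A	V	S
S288c	A	S	A	V	S
AWRI796		N	A	V	N
BC 187	T	N	A	V	N
BY4741	A	S	A	V	S
BY4742	A	S	A	V	S
CBS7960	A	S	A	V	S
CEN.PK	A	S	A	V	N
D273-10B	A	S	A	V	N
DBVP6044	A	N	A	V	N
EC1118	A	N	A	V	N
EC9-8	T	N	A	V	N
FL100	A	S	A	V	S
FY1679	X	N	A	V	N
FostersB	A	N	A	V	N
FostersO	A	N	A	V	N
JAY291	A	S	A	V	S
JK9-3d	A	S	A	V	S
K11	A	S	A	V	S
Kyokai7	T	N	A	V	N
L1528	A	N	A	V	N
LalvinQA23	A	S	A	V	N
RM11-1a	T	N	A	V	N
RedStar	T	N	A	V	N
SEY6210	A	S	A	V	S
SK1	A	S	A	V	N
UC5	A	S	A	V	S
VL3	A	S	A	V	S
Vin13	A	S	A	V	S
W303	T	N	A	V	N
X2180-1A	X	N	A		
Y55	A	S	A	V	S
YJM269	A	S	A	V	S
YJM339	T	N	A	V	N
YJM789	A	S	A	V	S
YJM499	T	N	A	V	N
YPS128	A	S	A	V	S
YPS163	A	S	A	V	N
YS9	A	S	A	V	N
ZTW1	T	N	A	V	N
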