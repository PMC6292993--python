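aa	gc_class	recruit_order	cost	mol_weight
A	2	2	11.7	89.09
C	1	16	24.7	121.16
D	1	3	12.7	133.10
E	1	7	15.3	147.13
F	0	17	52.0	165.19
G	2	1	11.7	75.07
H	1	14	38.3	155.15
I	0	11	32.3	131.17
K	0	15	30.3	146.19
L	1	8	27.3	131.17
M	0	19	34.3	149.21
N	0	13	14.7	132.12
P	2	5	20.3	115.13
Q	1	12	16.3	146.15
R	2	10	27.3	174.20
S	1	6	11.7	105.09
T	1	9	18.7	119.12
V	1	4	23.3	117.15
W	1	20	74.3	204.23
Y	0	18	50.0	181.19
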