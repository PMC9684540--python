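# Toy pair-motif table: two interacting residue types with a pseudo-CB
# distance window (angstroms) and an orientation class.  Hydrophobic-pair
# biased; a table harvested from crystal structures can be dropped in with
# the same columns.
# resA	resB	dmin	dmax	orientation
L	I	4.0	7.5	any
L	L	4.0	7.5	any
L	V	4.0	7.0	any
I	I	4.2	7.5	any
I	V	4.0	7.0	any
V	V	3.8	6.5	any
L	F	4.5	8.0	any
I	F	4.5	8.0	any
V	F	4.2	7.5	any
F	F	4.8	8.5	any
L	M	4.2	7.8	any
I	M	4.2	7.8	any
M	M	4.5	8.0	any
F	M	4.5	8.2	any
A	L	3.8	6.5	any
A	I	3.8	6.5	any
A	V	3.6	6.0	any
A	F	4.0	7.0	any
W	L	4.8	8.5	any
W	I	4.8	8.5	any
W	V	4.6	8.0	any
F	W	5.0	9.0	any
K	E	4.5	8.0	salt
R	E	4.5	8.0	salt
K	D	4.2	7.5	salt
R	D	4.2	7.5	salt
N	Q	4.0	7.0	polar
S	T	3.5	6.0	polar
Y	L	4.6	8.2	any
Y	I	4.6	8.2	any
Y	V	4.4	7.8	any
Y	F	4.8	8.6	any
M	A	4.0	7.0	any
W	M	5.0	8.8	any
L	T	3.8	6.8	any
I	T	3.8	6.8	any
V	T	3.6	6.4	any
A	A	3.4	5.8	any
W	W	5.2	9.5	any
Y	Y	5.0	9.0	any
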