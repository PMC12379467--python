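# Elemental composition of amino acid residues (free amino acid minus water).
# Columns: residue one-letter code, then atom counts per element.
residue	C	H	N	O	S
A	3	5	1	1	0
C	3	5	1	1	1
D	4	5	1	3	0
E	5	7	1	3	0
F	9	9	1	1	0
G	2	3	1	1	0
H	6	7	3	1	0
I	6	11	1	1	0
K	6	12	2	1	0
L	6	11	1	1	0
M	5	9	1	1	1
N	4	6	2	2	0
P	5	7	1	1	0
Q	5	8	2	2	0
R	6	12	4	1	0
S	3	5	1	2	0
T	4	7	1	2	0
V	5	9	1	1	0
W	11	10	2	1	0
Y	9	9	1	2	0
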