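# residue biochemical features: Kyte-Doolittle hydrophobicity (H),
# side-chain pKa (K; 0.0 for non-ionizable side chains), monoisotopic residue mass in Da (M).
# X carries the per-feature mean over the 20 standard amino acids.
letter	H	K	M
A	1.8	0.0	71.03711
C	2.5	8.18	103.00919
D	-3.5	3.65	115.02694
E	-3.5	4.25	129.04259
F	2.8	0.0	147.06841
G	-0.4	0.0	57.02146
H	-3.2	6.0	137.05891
I	4.5	0.0	113.08406
K	-3.9	10.53	128.09496
L	3.8	0.0	113.08406
M	1.9	0.0	131.04049
N	-3.5	0.0	114.04293
P	-1.6	0.0	97.05276
Q	-3.5	0.0	128.05858
R	-4.5	12.48	156.10111
S	-0.8	0.0	87.03203
T	-0.7	0.0	101.04768
V	4.2	0.0	99.06841
W	-0.9	0.0	186.07931
Y	-1.3	10.07	163.06333
X	-0.49	2.758	118.80572
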