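# Amino-acid biosynthetic costs in high-energy phosphate bond equivalents (~P),
# Akashi & Gojobori (2002) PNAS 99:3695-3700, averaged E. coli / B. subtilis values.
amino_acid	cost
A	11.7
R	27.3
N	14.7
D	12.7
C	24.7
Q	16.3
E	15.3
G	11.7
H	38.3
I	32.3
L	27.3
K	30.3
M	34.3
F	52.0
P	20.3
S	11.7
T	18.7
W	74.3
Y	50.0
V	23.3
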