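# Physicochemical classes of the 20 canonical amino acids, encoded from the
# IMGT amino-acid aide-mémoire (IMGT classes page, accessed 2023 version).
# volume_class: 1=very small, 2=small, 3=medium, 4=large, 5=very large.
aa	volume_class	hydropathy	polarity	charge
A	1	hydrophobic	nonpolar	uncharged
G	1	neutral	nonpolar	uncharged
S	1	neutral	polar	uncharged
C	2	hydrophobic	nonpolar	uncharged
D	2	hydrophilic	polar	negative
N	2	hydrophilic	polar	uncharged
P	2	neutral	nonpolar	uncharged
T	2	neutral	polar	uncharged
E	3	hydrophilic	polar	negative
H	3	neutral	polar	positive
Q	3	hydrophilic	polar	uncharged
V	3	hydrophobic	nonpolar	uncharged
I	4	hydrophobic	nonpolar	uncharged
K	4	hydrophilic	polar	positive
L	4	hydrophobic	nonpolar	uncharged
M	4	hydrophobic	nonpolar	uncharged
R	4	hydrophilic	polar	positive
F	5	hydrophobic	nonpolar	uncharged
W	5	hydrophobic	nonpolar	uncharged
Y	5	neutral	polar	uncharged
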