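# Nuclear tRNA gene copies of Saccharomyces cerevisiae, per anticodon.
# Assembled from the standard S. cerevisiae tRNA gene set (GtRNAdb-style
# copy numbers); elongator Met only (initiator tRNA excluded). The t6A_37
# flag marks tRNAs decoding ANN codons (anticodon position 36 = U).
# Columns: amino_acid, anticodon (RNA), gene_copies
amino_acid	anticodon	gene_copies
A	AGC	11
A	UGC	5
R	ACG	6
R	CCG	1
R	CCU	1
R	UCU	11
N	GUU	10
D	GUC	16
C	GCA	4
Q	CUG	1
Q	UUG	9
E	CUC	2
E	UUC	14
G	CCC	2
G	GCC	16
G	UCC	3
H	GUG	7
I	AAU	13
I	UAU	2
L	CAA	10
L	GAG	1
L	UAA	7
L	UAG	3
K	CUU	14
K	UUU	7
M	CAU	5
F	GAA	10
P	AGG	10
P	UGG	2
S	AGA	11
S	CGA	1
S	GCU	4
S	UGA	3
T	AGU	11
T	CGU	1
T	UGU	4
W	CCA	6
Y	GUA	8
V	AAC	14
V	CAC	2
V	UAC	2
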