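# Pharmacophore atom-typing rules.
# Columns: class <TAB> SMARTS <TAB> priority
# An atom receives a class if it is the FIRST atom of any match of that
# class's patterns (lowest priority number tried first; within a class,
# later patterns cannot remove a label already granted). Labels are
# multi-label across classes. Atoms matching no rule get "Neutral".
# Edit or replace this file (classes=... in FeatureConfig) to change typing.
Donor	[#7;+0;!H0]	1
Donor	[#8;+0;!H0]	2
Donor	[#16;+0;!H0]	3
Acceptor	[#8;+0]	1
Acceptor	[nX2;+0]	2
Acceptor	[NX3;+0;!$([NX3][CX3]=[OX1])]	3
Acceptor	[NX1;+0]	4
Acceptor	[NX2;+0]	5
PositiveIonizable	[+1,+2,+3]	1
PositiveIonizable	[NX3;H2;+0;!$([NX3][CX3]=[OX1]);!$([NX3]a)]	2
NegativeIonizable	[-1,-2,-3]	1
NegativeIonizable	[OX2H1][CX3]=[OX1]	2
NegativeIonizable	[OX2H1][SX4](=[OX1])=[OX1]	3
Aromatic	[a]	1
Sulfur	[#16]	1
Hydrophobe	[#6]	1
Hydrophobe	[F,Cl,Br,I]	2
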