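# Bjellqvist pK set (Bjellqvist et al. 1993, Electrophoresis 14:1023-1031),
# the table behind the ExPASy Compute pI/Mw server. One generic pK per
# ionisable group; sign: +1 groups are protonated-positive below their pK,
# -1 groups deprotonate to negative above their pK.
# group	pk	sign
Nterm	7.50	+1
Cterm	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.00	-1
Y	10.00	-1
H	5.98	+1
K	10.00	+1
R	12.00	+1
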