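# Dinucleotide bend/deformability propensity on a coarse 0-1 scale encoding
# the standard flexibility ordering pyrimidine-purine >> purine-purine ~
# pyrimidine-pyrimidine > purine-pyrimidine (TA most bendable, GC stiffest).
# A coarse package-authored scale; replaceable and re-calibratable as data.
dinucleotide	value
AA	0.50
AC	0.35
AG	0.45
AT	0.55
CA	0.90
CC	0.30
CG	0.70
CT	0.45
GA	0.45
GC	0.25
GG	0.30
GT	0.35
TA	1.00
TC	0.45
TG	0.90
TT	0.50
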