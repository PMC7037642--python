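key	sequence
CETP:18bp	gggcggacatacatatac
SOD1:26bp	aggcgcggaggtctggcctataaagt
APOA1:6bp	gacata
MLH1:21bp	ggatacaacaaaggggacttc
DHFR:35bp	ctcgcctgcacaaatggggacgaggggggcggggc
COMT:15bp	ccgccacggcctgcg
ATM:15bp	gggcggggatgagga
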