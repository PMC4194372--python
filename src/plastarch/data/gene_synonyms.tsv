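# Synonym -> canonical gene symbol (matched case-insensitively).
# synonym	canonical
rrn16	rrs
rrn23	rrl
rrn5	rrf
rrn4.5	rrf
16S rRNA	rrs
23S rRNA	rrl
5S rRNA	rrf
rrnS	rrs
rrnL	rrl
ycf9	psbZ
psbM1	psbM
rpoC	rpoC1
trnfM-cau	trnMf-cau
trnM-cau	trnMe-cau
rps12A	rps12a
rps12B	rps12b
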