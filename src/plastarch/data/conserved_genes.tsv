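# Conserved chloroplast gene catalog (controlled vocabulary).
# Union of the ~75-gene green-algal core, the ndh set, and genes with
# sporadic distributions across prasinophyte/streptophyte plastomes.
# name	category
accD	protein
atpA	protein
atpB	protein
atpE	protein
atpF	protein
atpH	protein
atpI	protein
ccsA	protein
cemA	protein
chlB	protein
chlI	protein
chlL	protein
chlN	protein
chlP	protein
clpP	protein
cysA	protein
cysT	protein
ftsH	protein
ftsI	protein
ftsW	protein
infA	protein
minD	protein
ndhA	protein
ndhB	protein
ndhC	protein
ndhD	protein
ndhE	protein
ndhF	protein
ndhG	protein
ndhH	protein
ndhI	protein
ndhJ	protein
ndhK	protein
odpB	protein
petA	protein
petB	protein
petD	protein
petG	protein
petL	protein
psaA	protein
psaB	protein
psaC	protein
psaI	protein
psaJ	protein
psaM	protein
psbA	protein
psbB	protein
psbC	protein
psbD	protein
psbE	protein
psbF	protein
psbH	protein
psbI	protein
psbJ	protein
psbK	protein
psbL	protein
psbM	protein
psbN	protein
psbT	protein
psbZ	protein
rbcL	protein
rbcR	protein
rne	protein
rnpB	other
rpl2	protein
rpl5	protein
rpl12	protein
rpl14	protein
rpl16	protein
rpl19	protein
rpl20	protein
rpl21	protein
rpl22	protein
rpl23	protein
rpl32	protein
rpl36	protein
rpoA	protein
rpoB	protein
rpoC1	protein
rpoC2	protein
rps2	protein
rps3	protein
rps4	protein
rps7	protein
rps8	protein
rps9	protein
rps11	protein
rps12	protein
rps14	protein
rps15	protein
rps16	protein
rps18	protein
rps19	protein
tilS	protein
tufA	protein
ycf1	protein
ycf3	protein
ycf4	protein
ycf12	protein
ycf20	protein
ycf47	protein
ycf65	protein
ycf66	protein
rrf	rRNA
rrl	rRNA
rrs	rRNA
trnA-ugc	tRNA
trnC-gca	tRNA
trnD-guc	tRNA
trnE-uuc	tRNA
trnF-gaa	tRNA
trnG-gcc	tRNA
trnG-ucc	tRNA
trnH-gug	tRNA
trnI-cau	tRNA
trnI-gau	tRNA
trnK-uuu	tRNA
trnL-caa	tRNA
trnL-uaa	tRNA
trnL-uag	tRNA
trnMe-cau	tRNA
trnMf-cau	tRNA
trnN-guu	tRNA
trnP-ugg	tRNA
trnQ-uug	tRNA
trnR-acg	tRNA
trnR-ccg	tRNA
trnR-ucu	tRNA
trnS-gcu	tRNA
trnS-gga	tRNA
trnS-uga	tRNA
trnT-ggu	tRNA
trnT-ugu	tRNA
trnV-gac	tRNA
trnV-uac	tRNA
trnW-cca	tRNA
trnY-gua	tRNA
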