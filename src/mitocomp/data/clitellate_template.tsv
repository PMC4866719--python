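label	kind
cox1	CDS
trnN	tRNA
trnY	tRNA
trnG	tRNA
cox2	CDS
trnD	tRNA
atp8	CDS
trnC	tRNA
cox3	CDS
atp6	CDS
trnR	tRNA
pCR	control_region
trnH	tRNA
nad5	CDS
trnF	tRNA
trnE	tRNA
trnP	tRNA
trnT	tRNA
nad4L	CDS
nad4	CDS
trnW	tRNA
trnA	tRNA
trnS2	tRNA
nad6	CDS
cob	CDS
trnS1	tRNA
nad1	CDS
trnI	tRNA
trnK	tRNA
nad3	CDS
trnQ	tRNA
trnL2	tRNA
nad2	CDS
trnM	tRNA
rrnS	rRNA
trnV	tRNA
rrnL	rRNA
trnL1	tRNA
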