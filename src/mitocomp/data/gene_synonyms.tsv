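synonym	canonical
co1	cox1
coi	cox1
cox1	cox1
coxi	cox1
co2	cox2
coii	cox2
cox2	cox2
coxii	cox2
co3	cox3
coiii	cox3
cox3	cox3
coxiii	cox3
cytb	cob
cytochrome b	cob
cob	cob
atp6	atp6
atpase6	atp6
atpase 6	atp6
atp8	atp8
atpase8	atp8
atpase 8	atp8
nd1	nad1
nad1	nad1
nd2	nad2
nad2	nad2
nd3	nad3
nad3	nad3
nd4	nad4
nad4	nad4
nd4l	nad4L
nad4l	nad4L
nd5	nad5
nad5	nad5
nd6	nad6
nad6	nad6
12s	rrnS
12s rrna	rrnS
rrns	rrnS
srrna	rrnS
s-rrna	rrnS
small subunit ribosomal rna	rrnS
16s	rrnL
16s rrna	rrnL
rrnl	rrnL
lrrna	rrnL
l-rrna	rrnL
large subunit ribosomal rna	rrnL
d-loop	pCR
control region	pCR
putative control region	pCR
pcr	pCR
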