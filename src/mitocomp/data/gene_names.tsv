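raw_label	canonical_name
atp6	atp6
ATPase6	atp6
ATP synthase F0 subunit 6	atp6
ATP synthase subunit 6	atp6
ATP6 gene	atp6
atp8	atp8
ATPase8	atp8
ATP synthase F0 subunit 8	atp8
ATP synthase subunit 8	atp8
cob	cob
cytb	cob
cyb	cob
cytochrome b	cob
CytB protein	cob
cox1	cox1
COI	cox1
CO1	cox1
COX-I	cox1
cytochrome c oxidase subunit 1	cox1
cytochrome c oxidase subunit I	cox1
cytochrome oxidase subunit 1	cox1
cox2	cox2
COII	cox2
CO2	cox2
COX-II	cox2
cytochrome c oxidase subunit 2	cox2
cytochrome c oxidase subunit II	cox2
cox3	cox3
COIII	cox3
CO3	cox3
COX-III	cox3
cytochrome c oxidase subunit 3	cox3
cytochrome c oxidase subunit III	cox3
nad1	nad1
ND1	nad1
NADH1	nad1
NADH dehydrogenase subunit 1	nad1
nad2	nad2
ND2	nad2
NADH2	nad2
NADH dehydrogenase subunit 2	nad2
nad3	nad3
ND3	nad3
NADH3	nad3
NADH dehydrogenase subunit 3	nad3
nad4	nad4
ND4	nad4
NADH4	nad4
NADH dehydrogenase subunit 4	nad4
nad5	nad5
ND5	nad5
NADH5	nad5
NADH dehydrogenase subunit 5	nad5
nad6	nad6
ND6	nad6
NADH6	nad6
NADH dehydrogenase subunit 6	nad6
nad4l	nad4l
ND4L	nad4l
NADH4L	nad4l
NADH dehydrogenase subunit 4L	nad4l
trnA	trnA
tRNA-Ala	trnA
trnA(tRNA-Ala)	trnA
trnR	trnR
tRNA-Arg	trnR
trnR(tRNA-Arg)	trnR
trnN	trnN
tRNA-Asn	trnN
trnN(tRNA-Asn)	trnN
trnD	trnD
tRNA-Asp	trnD
trnD(tRNA-Asp)	trnD
trnC	trnC
tRNA-Cys	trnC
trnC(tRNA-Cys)	trnC
trnE	trnE
tRNA-Glu	trnE
trnE(tRNA-Glu)	trnE
trnQ	trnQ
tRNA-Gln	trnQ
trnQ(tRNA-Gln)	trnQ
trnG	trnG
tRNA-Gly	trnG
trnG(tRNA-Gly)	trnG
trnH	trnH
tRNA-His	trnH
trnH(tRNA-His)	trnH
trnI	trnI
tRNA-Ile	trnI
trnI(tRNA-Ile)	trnI
trnK	trnK
tRNA-Lys	trnK
trnK(tRNA-Lys)	trnK
trnM	trnM
tRNA-Met	trnM
trnM(tRNA-Met)	trnM
trnF	trnF
tRNA-Phe	trnF
trnF(tRNA-Phe)	trnF
trnP	trnP
tRNA-Pro	trnP
trnP(tRNA-Pro)	trnP
trnT	trnT
tRNA-Thr	trnT
trnT(tRNA-Thr)	trnT
trnW	trnW
tRNA-Trp	trnW
trnW(tRNA-Trp)	trnW
trnY	trnY
tRNA-Tyr	trnY
trnY(tRNA-Tyr)	trnY
trnV	trnV
tRNA-Val	trnV
trnV(tRNA-Val)	trnV
trnL1	trnL1
tRNA-L1	trnL1
tRNA-Leu1	trnL1
tRNA-Leu(CUN)	trnL1
trnL(CUN)	trnL1
tRNA-Leu(tag)	trnL1
trnL-tag	trnL1
trnL2	trnL2
tRNA-L2	trnL2
tRNA-Leu2	trnL2
tRNA-Leu(UUR)	trnL2
trnL(UUR)	trnL2
tRNA-Leu(taa)	trnL2
trnL-taa	trnL2
trnS1	trnS1
tRNA-S1	trnS1
tRNA-Ser1	trnS1
tRNA-Ser(AGN)	trnS1
trnS(AGN)	trnS1
tRNA-Ser(AGY)	trnS1
trnS(AGY)	trnS1
tRNA-Ser(tct)	trnS1
trnS-tct	trnS1
tRNA-Ser(gct)	trnS1
trnS-gct	trnS1
trnS2	trnS2
tRNA-S2	trnS2
tRNA-Ser2	trnS2
tRNA-Ser(UCN)	trnS2
trnS(UCN)	trnS2
tRNA-Ser(tga)	trnS2
trnS-tga	trnS2
rrnL	rrnL
16S	rrnL
l-rRNA	rrnL
16S ribosomal RNA	rrnL
large subunit ribosomal RNA	rrnL
16S rRNA	rrnL
rrn16	rrnL
rrnS	rrnS
12S	rrnS
s-rRNA	rrnS
12S ribosomal RNA	rrnS
small subunit ribosomal RNA	rrnS
12S rRNA	rrnS
rrn12	rrnS
control region	control_region
D-loop	control_region
AT-rich region	control_region
CR	control_region
putative control region	control_region
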