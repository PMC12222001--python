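canonical_name	kind	strand
trnI	tRNA	J
trnQ	tRNA	N
trnM	tRNA	J
nad2	PCG	J
trnW	tRNA	J
trnC	tRNA	N
trnY	tRNA	N
cox1	PCG	J
trnL2	tRNA	J
cox2	PCG	J
trnK	tRNA	J
trnD	tRNA	J
atp8	PCG	J
atp6	PCG	J
cox3	PCG	J
trnG	tRNA	J
nad3	PCG	J
trnA	tRNA	J
trnR	tRNA	J
trnN	tRNA	J
trnS1	tRNA	J
trnE	tRNA	J
trnF	tRNA	N
nad5	PCG	N
trnH	tRNA	N
nad4	PCG	N
nad4l	PCG	N
trnT	tRNA	J
trnP	tRNA	N
nad6	PCG	J
cob	PCG	J
trnS2	tRNA	J
nad1	PCG	N
trnL1	tRNA	N
rrnL	rRNA	N
trnV	tRNA	N
rrnS	rRNA	N
control_region	CR	J
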