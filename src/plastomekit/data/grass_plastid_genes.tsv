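name	region	kind	strand	length
psbA	LSC	CDS	+	1062
matK	LSC	CDS	+	1536
rps16	LSC	CDS	-	261
trnQ-UUG	LSC	tRNA	-	72
atpA	LSC	CDS	-	1524
atpF	LSC	CDS	-	555
atpH	LSC	CDS	-	246
atpI	LSC	CDS	-	744
rps2	LSC	CDS	-	711
rpoC2	LSC	CDS	-	4140
rpoC1	LSC	CDS	-	2052
rpoB	LSC	CDS	-	3213
petN	LSC	CDS	+	90
trnD-GUC	LSC	tRNA	-	74
psbM	LSC	CDS	-	105
psbD	LSC	CDS	+	1062
psbC	LSC	CDS	+	1422
rps14	LSC	CDS	-	303
psaB	LSC	CDS	-	2205
psaA	LSC	CDS	-	2253
ycf3	LSC	CDS	-	507
rps4	LSC	CDS	-	606
trnL-UAA	LSC	tRNA	+	85
ndhJ	LSC	CDS	-	477
ndhK	LSC	CDS	-	678
ndhC	LSC	CDS	-	363
trnV-UAC	LSC	tRNA	-	74
atpB	LSC	CDS	-	1497
atpE	LSC	CDS	-	411
rbcL	LSC	CDS	+	1434
psaI	LSC	CDS	+	111
ycf4	LSC	CDS	+	555
cemA	LSC	CDS	+	690
petA	LSC	CDS	+	963
psbJ	LSC	CDS	-	123
psbL	LSC	CDS	-	117
psbF	LSC	CDS	-	120
psbE	LSC	CDS	-	252
rpl33	LSC	CDS	+	201
rps18	LSC	CDS	+	306
rpl20	LSC	CDS	-	354
clpP	LSC	CDS	-	591
psbB	LSC	CDS	+	1527
psbH	LSC	CDS	+	222
petB	LSC	CDS	+	648
petD	LSC	CDS	+	483
rpoA	LSC	CDS	-	1014
rps11	LSC	CDS	-	417
rps8	LSC	CDS	-	405
rpl14	LSC	CDS	-	369
rpl16	LSC	CDS	-	408
rps3	LSC	CDS	-	657
rpl22	LSC	CDS	-	465
rps19	LSC	CDS	-	279
rpl2	IR	CDS	-	1488
rpl23	IR	CDS	-	282
ndhB	IR	CDS	-	1533
trnL-CAA	IR	tRNA	-	81
rps7	IR	CDS	-	468
trnV-GAC	IR	tRNA	+	72
rrn16	IR	rRNA	+	1491
trnI-GAU	IR	tRNA	+	72
trnA-UGC	IR	tRNA	+	73
rrn23	IR	rRNA	+	2810
rrn4.5	IR	rRNA	+	97
rrn5	IR	rRNA	+	121
trnR-ACG	IR	tRNA	+	74
trnN-GUU	IR	tRNA	-	72
ndhF	SSC	CDS	-	2220
rpl32	SSC	CDS	+	174
trnL-UAG	SSC	tRNA	+	80
ccsA	SSC	CDS	+	966
ndhD	SSC	CDS	-	1503
psaC	SSC	CDS	-	246
ndhE	SSC	CDS	-	306
ndhG	SSC	CDS	-	531
ndhI	SSC	CDS	-	543
ndhA	SSC	CDS	-	1092
ndhH	SSC	CDS	-	1182
rps15	SSC	CDS	-	273
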