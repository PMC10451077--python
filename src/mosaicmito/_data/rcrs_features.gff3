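##gff-version 3
##sequence-region chrM 1 16569
chrM	mosaicmito	control_region	1	576	.	+	.	ID=MT-CR1;Name=MT-CR1;oxphos_complex=none
chrM	mosaicmito	tRNA	577	647	.	+	.	ID=MT-TF;Name=MT-TF;oxphos_complex=none
chrM	mosaicmito	rRNA	648	1601	.	+	.	ID=MT-RNR1;Name=MT-RNR1;oxphos_complex=none
chrM	mosaicmito	tRNA	1602	1670	.	+	.	ID=MT-TV;Name=MT-TV;oxphos_complex=none
chrM	mosaicmito	rRNA	1671	3229	.	+	.	ID=MT-RNR2;Name=MT-RNR2;oxphos_complex=none
chrM	mosaicmito	tRNA	3230	3304	.	+	.	ID=MT-TL1;Name=MT-TL1;oxphos_complex=none
chrM	mosaicmito	protein_coding	3307	4262	.	+	.	ID=MT-ND1;Name=MT-ND1;oxphos_complex=I
chrM	mosaicmito	tRNA	4263	4331	.	+	.	ID=MT-TI;Name=MT-TI;oxphos_complex=none
chrM	mosaicmito	tRNA	4329	4400	.	-	.	ID=MT-TQ;Name=MT-TQ;oxphos_complex=none
chrM	mosaicmito	tRNA	4402	4469	.	+	.	ID=MT-TM;Name=MT-TM;oxphos_complex=none
chrM	mosaicmito	protein_coding	4470	5511	.	+	.	ID=MT-ND2;Name=MT-ND2;oxphos_complex=I
chrM	mosaicmito	tRNA	5512	5579	.	+	.	ID=MT-TW;Name=MT-TW;oxphos_complex=none
chrM	mosaicmito	tRNA	5587	5655	.	-	.	ID=MT-TA;Name=MT-TA;oxphos_complex=none
chrM	mosaicmito	tRNA	5657	5729	.	-	.	ID=MT-TN;Name=MT-TN;oxphos_complex=none
chrM	mosaicmito	tRNA	5761	5826	.	-	.	ID=MT-TC;Name=MT-TC;oxphos_complex=none
chrM	mosaicmito	tRNA	5826	5891	.	-	.	ID=MT-TY;Name=MT-TY;oxphos_complex=none
chrM	mosaicmito	protein_coding	5904	7445	.	+	.	ID=MT-CO1;Name=MT-CO1;oxphos_complex=IV
chrM	mosaicmito	tRNA	7446	7514	.	-	.	ID=MT-TS1;Name=MT-TS1;oxphos_complex=none
chrM	mosaicmito	tRNA	7518	7585	.	+	.	ID=MT-TD;Name=MT-TD;oxphos_complex=none
chrM	mosaicmito	protein_coding	7586	8269	.	+	.	ID=MT-CO2;Name=MT-CO2;oxphos_complex=IV
chrM	mosaicmito	tRNA	8295	8364	.	+	.	ID=MT-TK;Name=MT-TK;oxphos_complex=none
chrM	mosaicmito	protein_coding	8366	8572	.	+	.	ID=MT-ATP8;Name=MT-ATP8;oxphos_complex=V
chrM	mosaicmito	protein_coding	8527	9207	.	+	.	ID=MT-ATP6;Name=MT-ATP6;oxphos_complex=V
chrM	mosaicmito	protein_coding	9207	9990	.	+	.	ID=MT-CO3;Name=MT-CO3;oxphos_complex=IV
chrM	mosaicmito	tRNA	9991	10058	.	+	.	ID=MT-TG;Name=MT-TG;oxphos_complex=none
chrM	mosaicmito	protein_coding	10059	10404	.	+	.	ID=MT-ND3;Name=MT-ND3;oxphos_complex=I
chrM	mosaicmito	tRNA	10405	10469	.	+	.	ID=MT-TR;Name=MT-TR;oxphos_complex=none
chrM	mosaicmito	protein_coding	10470	10766	.	+	.	ID=MT-ND4L;Name=MT-ND4L;oxphos_complex=I
chrM	mosaicmito	protein_coding	10760	12137	.	+	.	ID=MT-ND4;Name=MT-ND4;oxphos_complex=I
chrM	mosaicmito	tRNA	12138	12206	.	+	.	ID=MT-TH;Name=MT-TH;oxphos_complex=none
chrM	mosaicmito	tRNA	12207	12265	.	+	.	ID=MT-TS2;Name=MT-TS2;oxphos_complex=none
chrM	mosaicmito	tRNA	12266	12336	.	+	.	ID=MT-TL2;Name=MT-TL2;oxphos_complex=none
chrM	mosaicmito	protein_coding	12337	14148	.	+	.	ID=MT-ND5;Name=MT-ND5;oxphos_complex=I
chrM	mosaicmito	protein_coding	14149	14673	.	-	.	ID=MT-ND6;Name=MT-ND6;oxphos_complex=I
chrM	mosaicmito	tRNA	14674	14742	.	-	.	ID=MT-TE;Name=MT-TE;oxphos_complex=none
chrM	mosaicmito	protein_coding	14747	15887	.	+	.	ID=MT-CYB;Name=MT-CYB;oxphos_complex=III
chrM	mosaicmito	tRNA	15888	15953	.	+	.	ID=MT-TT;Name=MT-TT;oxphos_complex=none
chrM	mosaicmito	tRNA	15956	16023	.	-	.	ID=MT-TP;Name=MT-TP;oxphos_complex=none
chrM	mosaicmito	control_region	16024	16569	.	+	.	ID=MT-CR2;Name=MT-CR2;oxphos_complex=none
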