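family	name	mature_seq	length_nt	homolog	reads	gma	ath	ptc	osa
MIR156	ame-miR156-1	ugacagaagagagugagcac	20	gma-miR156u	13342	++	+	+	+
MIR156	ame-miR156-2	ugacagaagagagagagcac	20	gma-miR156b	10	++	+	+	+
MIR156	ame-miR156-3	uugacagaagauagagagcac	21	gma-miR156d	45036	++	++	++	+
MIR156	ame-miR156-4	ugacagaagauagagagcac	20	gma-miR156d	603	+	+	+	+
MIR159	ame-miR159-1	uuuggauugaagggagcucua	21	gma-miR159a-3p	40206	++	++	++	+
MIR159	ame-miR159-2	uuuggauugaagggagcu	18	gma-miR159a-3p	135	++	++	++	++
MIR159	ame-miR159-3	uuuggacugaagggagcuccu	21	csi-miR159d	88	+	+	+	+
MIR159	ame-miR159-4	uuggacugaaggggccucuu	20	gma-miR319f	48	++	+	+	+
MIR159	ame-miR159-5	uuggacugaagggagcuccc	20	ath-miR319a	1459	++	++	++	+
MIR159	ame-miR159-6	uggacugaagggagcuccuuc	21	gma-miR319q	437	++	+	+	+
MIR160	ame-miR160-1	ugccuggcucccugaaugcca	21	mtr-miR160c	261	+	+	++	++
MIR160	ame-miR160-2	ugccuggcucccuguaugcca	21	gma-miR160a-5p	2374	++	++	++	++
MIR160	ame-miR160-3	gcguaugaggagccaagcaua	21	gma-miR160a-3p	127	++	+	+	+
MIR162	ame-miR162-1	ucgauaaaccucugcauccag	21	ath-miR162a-3p	961	++	++	++	++
MIR162	ame-miR162-2	ggaggcagcgguucaucgauc	21	csi-miR162-5p	60	+	+	+	+
MIR164	ame-miR164-1	uggagaagcagggcacgugca	21	ath-miR164a	1584	++	++	++	++
MIR164	ame-miR164-2	caugugccccucuuccccauc	21	zma-miR164c-3p	41		+	+
MIR166	ame-miR166-1	ucggaccaggcuucauucccc	21	gma-miR166d	71955	++	+	+	+
MIR166	ame-miR166-2	ucggaccaggcuucauucccg	21	gma-miR166j-3p	8165	++
MIR166	ame-miR166-3	ucucggaccaggcuucauucc	21	gma-miR166k	7665	++	+	+	+
MIR166	ame-miR166-4	ggaauguugucuggcucgagg	21	gma-miR166a-5p	276	++	+		+
MIR166	ame-miR166-5	ggaauguuguuuggcucgagg	21	gma-miR166h-5p	162	++	+		+
MIR167_1	ame-miR167-1	ugaagcugccagcaugaucuga	22	gma-miR167g	6608	++	+	+	+
MIR167_1	ame-miR167-2	ugaagcugccagcaugaucug	21	gma-miR167c	3720	++	++	++	++
MIR167_1	ame-miR167-3	ugaagcugccagcaugaucua	21	gma-miR167a	2600	++	++	++	++
MIR167_1	ame-miR167-4	gucaugcugugacagccucacu	22	cas-miR167b	210				+
MIR167_1	ame-miR167-5	agaucauguggcaguuucacc	21	ahy-miR167-3p	68			++	+
MIR168	ame-miR168-1	cccgccuugcaucaacugaau	21	aly-miR168a-3p	478		++	++	+
MIR168	ame-miR168-2	ucgcuuggugcaggucggga	20	gma-miR168a	30	++	++	++	+
MIR169_2	ame-miR169-1	cagccaaggaugacuugccgg	21	gma-miR169a	105	++	++	++	++
MIR169_2	ame-miR169-2	ugagccagggaugacuugccgg	22	gma-miR169d	12	+	+	+	+
MIR169_2	ame-miR169-3	ugagccaaggaugacuugccgg	22	gma-miR169d	47	++	+	+	+
MIR169_2	ame-miR169-4	ugcagccaaggaugacuugcc	21	gma-miR169b	39	+	+	+	+
MIR169_2	ame-miR169-5	ggcaaguuggccuuggcuau	20	zma-miR169r-3p	4		+	+	+
MIR171	ame-miR171-1	ugauugagccgugccaauauc	21	gma-miR171e	1419	++	+	++	++
MIR171	ame-miR171-2	uugagccgcgccaauaucacu	21	gma-miR171k-3p	439	++	+	+	+
MIR171	ame-miR171-3	uugagccgugccaauaucac	20	gma-miR171i-3p	87	+	+	+	+
MIR171	ame-miR171-4	uugagccgcgucaauaucuca	21	gma-miR171m	1713	++	+	+	+
MIR171	ame-miR171-5	agguauuggcgcgccucaauu	21	osa-miR171i-5p	5	+	+	+	+
MIR171	ame-miR171-6	cgauguuggugagguucaauc	21	gma-miR171k-5p	40	++	+	+	+
MIR172	ame-miR172-1	agaaucuugaugaugcugcau	21	gma-miR172a	1122	++	++	++	++
MIR172	ame-miR172-2	ggagcaucaucaagauucaca	21	aly-miR172c-5p	5	+	+	++	+
MIR172	ame-miR172-3	agaaucuugaugaugcugcag	21	ath-miR172c	133	+	++	+	+
MIR172	ame-miR172-4	gcagcaucaucaagauucaca	21	csi-miR172b-5p	6	++	+	+	+
MIR390	ame-miR390-1	aagcucaggagggauagcgcc	21	gma-miR390a-5p	350	++	++	++	++
MIR390	ame-miR390-2	cgcuauccauccugaguuuca	21	gma-miR390a-3p	11	++	++	+	+
MIR394	ame-miR394-1	uuggcauucuguccaccucc	20	gma-miR394c-5p	546	++	++	++	++
MIR396	ame-miR396-1	uuccacagcuuucuugaacuu	21	gma-miR396b-5p	6105	++	++	++	++
MIR396	ame-miR396-2	guucaauaaagcugugggaag	21	gma-miR396i-3p	1717	++	++	+	++
MIR396	ame-miR396-3	cucaagaaagcugugggaga	20	gma-miR396b-3p	1313	+	+	+	+
MIR396	ame-miR396-4	cuuccacagcuuucuugaacug	22	gma-miR396a-5p	523	+	+	+	+
MIR397	ame-miR397-1	ucauugagugcagcguugaug	21	gma-miR397a	579	++	++	++	++
MIR398	ame-miR398-1	uguguucucaggucaccccuu	21	gma-miR398a	3826	++	++	++	++
MIR398	ame-miR398-2	gggucguccugagaccacaug	21	bra-miR398-5p	13	+		+	+
MIR398	ame-miR398-3	uguguucucaggucgccccug	21	gma-miR398c	666	++	+	++	++
MIR398	ame-miR398-4	ggagugaaucugagaacacaag	22	gma-miR398b-5p	440	+		+
MIR408	ame-miR408-1	augcacugccucuucccuggc	21	gma-miR408a-3p	3496	++	++	++	+
MIR477	ame-miR477-1	ucccucaaaggcuuccaguau	21	ppt-miR477c	31	+		+
MIR530	ame-miR530-1	ucugcauuugcaccugcacuu	21	stu-miR530	49	+		+	+
MIR858	ame-miR858-1	cucguugucuguucgaccuug	21	csi-miR858-3p	15		+
MIR1514	ame-miR1514-1	uuuucauuuuuaaaauaggca	21	gma-miR408a-3p	10	+
MIR2111	ame-miR2111-1	uaaucugcauccugagguuu	20	gma-miR2111b	197	++	+	+
MIR2111	ame-miR2111-2	uaaucugcauccugagguu	19	gma-miR2111b	14	+	+	+
MIR2111	ame-miR2111-3	uaaucugcauccugaggugu	20	gma-miR2111b	95	+	+	+
MIR2111	ame-miR2111-4	guccuugggaugcagauuacc	21	gma-miR2111a	82	+	+	+
MIR2118	ame-miR2118-1	uuaccgauuccacccaugccuc	22	mtr-miR2118	850		+	+	+
MIR4415	ame-miR4415-1	uugauucucaucacaacuugg	21	gma-miR4415a-3p	1879	+
MIR4415	ame-miR4415-2	auguugugaugggaaucaaug	21	gma-miR4415b-5p	50	+
MIR5083	ame-miR5083-1	agacuacaauuaucugaucaau	22	osa-miR5083	15				+
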