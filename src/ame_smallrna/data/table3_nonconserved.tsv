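name	mature_seq	length_nt	reads
ame-miRN-1	guucaagucccuccuuccgc	20	31
ame-miRN-2	uccguuguagucuaguugguc	21	2043
ame-miRN-3	gucgauauguccgagugguuaag	23	1399
ame-miRN-4	caauuuagucccugaaauugu	21	26
ame-miRN-5	gggcauuuggucuagugguaug	22	696
ame-miRN-6	gaagcggaugggggccggcg	20	402
ame-miRN-7	guauuguaaguggcagagug	20	307
ame-miRN-8	acaaaucuuugaaaacaggaa	21	8
ame-miRN-9	ccuguuuucaaauauuuguac	21	2
ame-miRN-10	uauaguuuguuugaugguag	20	78
ame-miRN-11	ugaaucucaguggaucguggc	21	69
ame-miRN-12	gcuuccauagcauagugguag	21	21
ame-miRN-13	uucuaauuucuccucccuuuc	21	7
ame-miRN-14	uuuuugguucauuaaauaacu	21	6
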