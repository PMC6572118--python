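homolog_id	family
gma-miR156u	MIR156
gma-miR156b	MIR156
gma-miR156d	MIR156
gma-miR159a-3p	MIR159
csi-miR159d	MIR159
gma-miR319f	MIR159
ath-miR319a	MIR159
gma-miR319q	MIR159
mtr-miR160c	MIR160
gma-miR160a-5p	MIR160
gma-miR160a-3p	MIR160
ath-miR162a-3p	MIR162
csi-miR162-5p	MIR162
ath-miR164a	MIR164
zma-miR164c-3p	MIR164
gma-miR166d	MIR166
gma-miR166j-3p	MIR166
gma-miR166k	MIR166
gma-miR166a-5p	MIR166
gma-miR166h-5p	MIR166
gma-miR167g	MIR167_1
gma-miR167c	MIR167_1
gma-miR167a	MIR167_1
cas-miR167b	MIR167_1
ahy-miR167-3p	MIR167_1
aly-miR168a-3p	MIR168
gma-miR168a	MIR168
gma-miR169a	MIR169_2
gma-miR169d	MIR169_2
gma-miR169b	MIR169_2
zma-miR169r-3p	MIR169_2
gma-miR171e	MIR171
gma-miR171k-3p	MIR171
gma-miR171i-3p	MIR171
gma-miR171m	MIR171
osa-miR171i-5p	MIR171
gma-miR171k-5p	MIR171
gma-miR172a	MIR172
aly-miR172c-5p	MIR172
ath-miR172c	MIR172
csi-miR172b-5p	MIR172
gma-miR390a-5p	MIR390
gma-miR390a-3p	MIR390
gma-miR394c-5p	MIR394
gma-miR396b-5p	MIR396
gma-miR396i-3p	MIR396
gma-miR396b-3p	MIR396
gma-miR396a-5p	MIR396
gma-miR397a	MIR397
gma-miR398a	MIR398
bra-miR398-5p	MIR398
gma-miR398c	MIR398
gma-miR398b-5p	MIR398
gma-miR408a-3p	MIR408
ppt-miR477c	MIR477
stu-miR530	MIR530
csi-miR858-3p	MIR858
gma-miR2111b	MIR2111
gma-miR2111a	MIR2111
mtr-miR2118	MIR2118
gma-miR4415a-3p	MIR4415
gma-miR4415b-5p	MIR4415
osa-miR5083	MIR5083
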