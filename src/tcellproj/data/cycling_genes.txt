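# Cell-cycle genes excluded from variable-gene selection (mouse symbols).
# Editable: one symbol per line, '#' comments. S-phase and G2/M programs.
Mcm2
Mcm3
Mcm4
Mcm5
Mcm6
Mcm7
Pcna
Rrm1
Rrm2
Cdc6
Cdc20
Cdc45
Cdca2
Cdca3
Cdca8
Cdk1
Ccnb1
Ccnb2
Ccne2
Aurka
Aurkb
Birc5
Bub1
Bub1b
Top2a
Mki67
Tyms
Tk1
Ung
Gins2
Hells
Dut
Tipin
Prim1
Uhrf1
Hmgb2
Tubb5
Tpx2
Ube2c
Plk1
Kif11
Kif23
Kif2c
Cenpa
Cenpe
Cenpf
Nusap1
Anln
Ckap2
Ckap5
Ect2
Smc4
Dlgap5
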