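# Compact human->mouse ortholog symbol table (default shipped with tcellproj).
# Curated subset covering T-cell and common immune genes; for genome-wide
# analyses supply a full BioMart ortholog export via read_ortholog_table().
# columns: human_symbol<TAB>mouse_symbol
CD2	Cd2
CD3D	Cd3d
CD3E	Cd3e
CD3G	Cd3g
CD4	Cd4
CD8A	Cd8a
CD8B	Cd8b1
CD19	Cd19
SPI1	Spi1
FCER1G	Fcer1g
CSF1R	Csf1r
PDCD1	Pdcd1
PDCD1LG2	Pdcd1lg2
CD274	Cd274
CTLA4	Ctla4
LAG3	Lag3
HAVCR2	Havcr2
TIGIT	Tigit
ENTPD1	Entpd1
TOX	Tox
TOX2	Tox2
TCF7	Tcf7
LEF1	Lef1
SELL	Sell
CCR7	Ccr7
IL7R	Il7r
CXCR3	Cxcr3
CXCR5	Cxcr5
CX3CR1	Cx3cr1
XCL1	Xcl1
GZMA	Gzma
GZMB	Gzmb
GZMK	Gzmk
GZMM	Gzmm
PRF1	Prf1
IFNG	Ifng
IFNGR1	Ifngr1
TNF	Tnf
TNFRSF9	Tnfrsf9
TNFRSF4	Tnfrsf4
TNFSF4	Tnfsf4
CD40LG	Cd40lg
FOXP3	Foxp3
IL2RA	Il2ra
IKZF2	Ikzf2
KLRG1	Klrg1
KLRC1	Klrc1
KLRD1	Klrd1
NKG7	Nkg7
FASLG	Fasl
SLAMF6	Slamf6
ICOS	Icos
CD28	Cd28
CD27	Cd27
CD69	Cd69
CD44	Cd44
ITGAE	Itgae
ITGA4	Itga4
ITGB1	Itgb1
S1PR1	S1pr1
KLF2	Klf2
BACH2	Bach2
ID2	Id2
ID3	Id3
TBX21	Tbx21
EOMES	Eomes
GATA3	Gata3
RORC	Rorc
RORA	Rora
BCL6	Bcl6
PRDM1	Prdm1
BATF	Batf
IRF4	Irf4
NR4A1	Nr4a1
NR4A2	Nr4a2
NR4A3	Nr4a3
EGR1	Egr1
EGR2	Egr2
NFKBIA	Nfkbia
JUN	Jun
JUNB	Junb
FOS	Fos
FOSB	Fosb
DUSP1	Dusp1
DUSP2	Dusp2
ZEB2	Zeb2
RUNX3	Runx3
MKI67	Mki67
TOP2A	Top2a
PCNA	Pcna
CCNB1	Ccnb1
CDK1	Cdk1
BIRC5	Birc5
STMN1	Stmn1
TUBB	Tubb5
HMGB2	Hmgb2
LDHA	Ldha
TPI1	Tpi1
PGK1	Pgk1
SLC2A1	Slc2a1
HIF1A	Hif1a
MTOR	Mtor
MYC	Myc
IL2	Il2
IL10	Il10
IL21	Il21
CCL3	Ccl3
CCL4	Ccl4
CCL5	Ccl5
CXCL10	Cxcl10
CXCL13	Cxcl13
ANXA1	Anxa1
ANXA2	Anxa2
LGALS1	Lgals1
LGALS3	Lgals3
S100A4	S100a4
S100A6	S100a6
VIM	Vim
ACTB	Actb
B2M	B2m
PTPRC	Ptprc
LCK	Lck
ZAP70	Zap70
LAT	Lat
CD5	Cd5
CD6	Cd6
THY1	Thy1
TRAC	Trac
TRBC1	Trbc1
IFIT1	Ifit1
IFIT3	Ifit3
ISG15	Isg15
STAT1	Stat1
STAT3	Stat3
STAT4	Stat4
STAT5A	Stat5a
FOXO1	Foxo1
TNFAIP3	Tnfaip3
ZC3H12A	Zc3h12a
MIR155HG	Mir155hg
PTPN2	Ptpn2
PTPN6	Ptpn6
PTPN11	Ptpn11
IL2RB	Il2rb
IL2RG	Il2rg
IL15RA	Il15ra
IL18R1	Il18r1
IL18RAP	Il18rap
CD38	Cd38
CD101	Cd101
CD160	Cd160
CD200	Cd200
CD200R1	Cd200r1
VSIR	Vsir
BTLA	Btla
CD226	Cd226
CRTAM	Crtam
SH2D1A	Sh2d1a
TBC1D4	Tbc1d4
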