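# Reconstructed immune-regulator panel (78 genes, 7 categories).
# User-replaceable fixture.
feature	category
HLA-A	antigen_presentation
HLA-B	antigen_presentation
HLA-C	antigen_presentation
HLA-DPA1	antigen_presentation
HLA-DPB1	antigen_presentation
HLA-DQA1	antigen_presentation
HLA-DQB1	antigen_presentation
HLA-DRA	antigen_presentation
HLA-DRB1	antigen_presentation
HLA-E	antigen_presentation
HLA-F	antigen_presentation
HLA-G	antigen_presentation
B2M	antigen_presentation
TAP1	antigen_presentation
TAP2	antigen_presentation
TAPBP	antigen_presentation
MICA	antigen_presentation
MICB	antigen_presentation
ICAM1	cell_adhesion
ITGB2	cell_adhesion
SELP	cell_adhesion
PDCD1	co_inhibitor
CTLA4	co_inhibitor
LAG3	co_inhibitor
HAVCR2	co_inhibitor
TIGIT	co_inhibitor
BTLA	co_inhibitor
CD274	co_inhibitor
PDCD1LG2	co_inhibitor
VTCN1	co_inhibitor
CD160	co_inhibitor
CD244	co_inhibitor
ADORA2A	co_inhibitor
IDO1	co_inhibitor
VSIR	co_inhibitor
KIR2DL1	co_inhibitor
KIR2DL3	co_inhibitor
CD28	co_stimulator
ICOS	co_stimulator
CD40LG	co_stimulator
CD27	co_stimulator
TNFRSF4	co_stimulator
TNFRSF9	co_stimulator
TNFRSF14	co_stimulator
TNFRSF18	co_stimulator
CD226	co_stimulator
TMIGD2	co_stimulator
CD80	co_stimulator
CD86	co_stimulator
ICOSLG	co_stimulator
CD40	co_stimulator
CD70	co_stimulator
TNFSF4	co_stimulator
TNFSF9	co_stimulator
TNFSF14	co_stimulator
IL2	ligand
IL4	ligand
IL10	ligand
IL12A	ligand
IL13	ligand
IL1B	ligand
IFNG	ligand
TNF	ligand
TGFB1	ligand
CXCL9	ligand
CXCL10	ligand
CCL5	ligand
VEGFA	ligand
VEGFB	ligand
IL2RA	receptor
IL10RA	receptor
IL4R	receptor
TGFBR1	receptor
IFNGR1	receptor
TNFRSF1A	receptor
ENTPD1	other
NT5E	other
HMGB1	other
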