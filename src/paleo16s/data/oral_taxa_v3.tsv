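# Literature-derived 16S rRNA V3 (U341F/534R) primer-inclusive amplicon
# lengths for oral microbiome taxa of interest, with HOMD rank abundances
# (fraction of the human oral microbiome; empty when the HOMD assay could
# not measure the taxon, e.g. archaea, which HOMD primers do not amplify).
taxon	domain	group	v3_length_bp	homd_abundance
Actinomyces naeslundii	Bacteria	oral_commensal	190	0.0023
Anaerolineae G-1 sp.	Bacteria	oral_commensal	169
Atopobium parvulum	Bacteria	oral_commensal	173	0.0030
Campylobacter gracilis	Bacteria	oral_commensal	169	0.0104
Corynebacterium matruchotii	Bacteria	oral_commensal	189	0.0049
Eubacterium saphenum	Bacteria	oral_commensal	171	0.0037
Fusobacterium nucleatum	Bacteria	oral_commensal	172	0.0135
Methanobrevibacter oralis	Archaea	oral_commensal	151
Mogibacterium timidum	Bacteria	oral_commensal	171	0.0027
Neisseria mucosa	Bacteria	oral_commensal	193	0.0033
Oribacterium sinus	Bacteria	oral_commensal	168	0.0014
Parvimonas micra	Bacteria	oral_commensal	168	0.0068
Prevotella melaninogenica	Bacteria	oral_commensal	188	0.0022
Rothia dentocariosa	Bacteria	oral_commensal	173	0.0060
Streptococcus mitis	Bacteria	oral_commensal	194	0.0566
TM7 spp.	Bacteria	oral_commensal	168	0.0024
Veillonella parvula	Bacteria	oral_commensal	194	0.0663
Lactobacillus salivarius	Bacteria	caries_pathogen	193	0.0009
Streptococcus mutans	Bacteria	caries_pathogen	194	0.0431
Aggregatibacter actinomycetemcomitans	Bacteria	periodontal_pathogen	193	0.0003
Filifactor alocis	Bacteria	periodontal_pathogen	171	0.0031
Porphyromonas gingivalis	Bacteria	periodontal_pathogen	188	0.0026
Tannerella forsythia	Bacteria	periodontal_pathogen	188	0.0025
Treponema denticola	Bacteria	periodontal_pathogen	194	0.0022
Bordetella pertussis	Bacteria	respiratory_pathogen	193
Corynebacterium diphtheriae	Bacteria	respiratory_pathogen	173
Haemophilus influenzae	Bacteria	respiratory_pathogen	193	0.0029
Streptococcus pneumoniae	Bacteria	respiratory_pathogen	194	0.0018
Streptococcus pyogenes	Bacteria	respiratory_pathogen	194
Neisseria meningitidis	Bacteria	systemic_pathogen	193	0.0017
Mycobacterium tuberculosis	Bacteria	systemic_pathogen	185
Mycobacterium leprae	Bacteria	systemic_pathogen	185
Treponema pallidum	Bacteria	systemic_pathogen	194
Streptophyta (plant chloroplast)	Chloroplast	dietary	170
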