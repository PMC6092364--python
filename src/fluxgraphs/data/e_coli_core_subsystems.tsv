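# Pathway (subsystem) annotation for the E. coli core metabolic model,
# transcribed from the public BiGG annotation of e_coli_core (11 pathways,
# 95 reactions). The bundled SBML distribution of the model carries no
# subsystem notes, so the grouping is shipped here as a plain-text table.
reaction	subsystem
ACALD	Pyruvate Metabolism
ACALDt	Transport, Extracellular
ACKr	Pyruvate Metabolism
ACONTa	Citric Acid Cycle
ACONTb	Citric Acid Cycle
ACt2r	Transport, Extracellular
ADK1	Oxidative Phosphorylation
AKGDH	Citric Acid Cycle
AKGt2r	Transport, Extracellular
ALCD2x	Pyruvate Metabolism
ATPM	Oxidative Phosphorylation
ATPS4r	Oxidative Phosphorylation
Biomass_Ecoli_core	Biomass and maintenance functions
CO2t	Transport, Extracellular
CS	Citric Acid Cycle
CYTBD	Oxidative Phosphorylation
D_LACt2	Transport, Extracellular
ENO	Glycolysis/Gluconeogenesis
ETOHt2r	Transport, Extracellular
EX_ac_e	Exchange
EX_acald_e	Exchange
EX_akg_e	Exchange
EX_co2_e	Exchange
EX_etoh_e	Exchange
EX_for_e	Exchange
EX_fru_e	Exchange
EX_fum_e	Exchange
EX_glc__D_e	Exchange
EX_gln__L_e	Exchange
EX_glu__L_e	Exchange
EX_h2o_e	Exchange
EX_h_e	Exchange
EX_lac__D_e	Exchange
EX_mal__L_e	Exchange
EX_nh4_e	Exchange
EX_o2_e	Exchange
EX_pi_e	Exchange
EX_pyr_e	Exchange
EX_succ_e	Exchange
FBA	Glycolysis/Gluconeogenesis
FBP	Glycolysis/Gluconeogenesis
FORt2	Transport, Extracellular
FORti	Transport, Extracellular
FRD7	Oxidative Phosphorylation
FRUpts2	Transport, Extracellular
FUM	Citric Acid Cycle
FUMt2_2	Transport, Extracellular
G6PDH2r	Pentose Phosphate Pathway
GAPD	Glycolysis/Gluconeogenesis
GLCpts	Transport, Extracellular
GLNS	Glutamate Metabolism
GLNabc	Transport, Extracellular
GLUDy	Glutamate Metabolism
GLUN	Glutamate Metabolism
GLUSy	Glutamate Metabolism
GLUt2r	Transport, Extracellular
GND	Pentose Phosphate Pathway
H2Ot	Transport, Extracellular
ICDHyr	Citric Acid Cycle
ICL	Anaplerotic Reactions
LDH_D	Pyruvate Metabolism
MALS	Anaplerotic Reactions
MALt2_2	Transport, Extracellular
MDH	Citric Acid Cycle
ME1	Anaplerotic Reactions
ME2	Anaplerotic Reactions
NADH16	Oxidative Phosphorylation
NADTRHD	Oxidative Phosphorylation
NH4t	Inorganic Ion Transport and Metabolism
O2t	Transport, Extracellular
PDH	Glycolysis/Gluconeogenesis
PFK	Glycolysis/Gluconeogenesis
PFL	Pyruvate Metabolism
PGI	Glycolysis/Gluconeogenesis
PGK	Glycolysis/Gluconeogenesis
PGL	Pentose Phosphate Pathway
PGM	Glycolysis/Gluconeogenesis
PIt2r	Inorganic Ion Transport and Metabolism
PPC	Anaplerotic Reactions
PPCK	Anaplerotic Reactions
PPS	Glycolysis/Gluconeogenesis
PTAr	Pyruvate Metabolism
PYK	Glycolysis/Gluconeogenesis
PYRt2	Transport, Extracellular
RPE	Pentose Phosphate Pathway
RPI	Pentose Phosphate Pathway
SUCCt2_2	Transport, Extracellular
SUCCt3	Transport, Extracellular
SUCDi	Oxidative Phosphorylation
SUCOAS	Citric Acid Cycle
TALA	Pentose Phosphate Pathway
THD2	Oxidative Phosphorylation
TKT1	Pentose Phosphate Pathway
TKT2	Pentose Phosphate Pathway
TPI	Glycolysis/Gluconeogenesis
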