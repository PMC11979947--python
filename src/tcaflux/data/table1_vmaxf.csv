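# Printed forward limiting rates (nmol/min/mg) of the kinetic parameter
# table, one row per enzyme and tissue; NA = not determined/not detected.
# The NAD-dependent IDH has two printed blocks (simple Michaelis and
# allosteric); both are kept.
enzyme,HepM,RLM,RHM
CS,1260,495,1128
ACO,23,13,173
IDH_NAD_MM,125,35,225
IDH_NAD_allosteric,51,13,NA
OGDH,22,14,58
SDH,13,39,388
FH,3356,172,527
MDH,269,523,1320
IDH_NADP,587,108,1059
PDH,26,1.4,44
AST,527,417,NA
ME,6.5,NA,70
GDH,NA,NA,2
ALT,327,56,NA
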