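# Kinetic constants, boundary concentrations and initial state — RLM
# (rat liver mitochondria).  No malic enzyme and no malate/2-oxoglutarate
# exchanger in this model.  Provenance tags as in params_hepm.csv.
# PDH and OGDH limiting rates are supplementary-material slots (the model
# used previously reported liver activities, not the printed assay values);
# they are initialized near the printed values and calibrated.
reaction,name,value,units,provenance
PYRT,Vmaxf,36.53291466623568,nmol/min/mg,CALIBRATED
PYRT,Ka,0.3,mM,LITERATURE
PYRT,Kp,0.3,mM,LITERATURE
PYRT,Keq,1.0,dimensionless,SM1-ASSUMED
PDH,Vmaxf,9.054096739878323,nmol/min/mg,CALIBRATED
PDH,Ka,0.21,mM,SM1-ASSUMED
PDH,Kb,0.014,mM,SM1-ASSUMED
PDH,Kc,0.34,mM,SM1-ASSUMED
PDH,Kp,0.04,mM,SM1-ASSUMED
PDH,Kq,0.03,mM,SM1-ASSUMED
PDH,Keq,7.0e8,mM,LITERATURE
CS,Vmaxf,495.0,nmol/min/mg,PAPER-Table1
CS,Ka,0.005,mM,PAPER-Table1
CS,Kb,0.006,mM,PAPER-Table1
CS,Kp,0.02,mM,SM1-ASSUMED
CS,Kq,1.0,mM,SM1-ASSUMED
CS,Keq,1.0e6,dimensionless,LITERATURE
ACO,Vmaxf,65.98272023494529,nmol/min/mg,CALIBRATED
ACO,Ka,0.1,mM,PAPER-Table1
ACO,Kp,0.12,mM,SM1-ASSUMED
ACO,Keq,4.0,dimensionless,SM1-ASSUMED
IDH_NAD,Vmaxf,13.0,nmol/min/mg,PAPER-Table1
IDH_NAD,Ka,0.45,mM,PAPER-Table1
IDH_NAD,Kb,3.0,mM,PAPER-Table1
IDH_NAD,Kp,1.0,mM,SM1-ASSUMED
IDH_NAD,Kq,0.03,mM,SM1-ASSUMED
IDH_NAD,Ki_NADH_vs_Iso,0.03,mM,PAPER-Table1
IDH_NAD,Ki_NADH_vs_NAD,0.05,mM,PAPER-Table1
IDH_NAD,n,1.9,dimensionless,PAPER-Table1
IDH_NAD,L,1.5,dimensionless,PAPER-Table1
IDH_NAD,Keq,1200.0,mM,LITERATURE
IDH_NADP,Vmaxf,108.0,nmol/min/mg,PAPER-Table1
IDH_NADP,Ka,0.078,mM,SM1-ASSUMED
IDH_NADP,Kb,0.04,mM,PAPER-Table1
IDH_NADP,Kp,1.0,mM,SM1-ASSUMED
IDH_NADP,Kq,0.015,mM,SM1-ASSUMED
IDH_NADP,Ki_GSH,2.0,mM,SM1-ASSUMED
IDH_NADP,Ki_NAD,0.3,mM,SM1-ASSUMED
IDH_NADP,Keq,1200.0,mM,LITERATURE
OGDH,Vmaxf,131.8894110980063,nmol/min/mg,CALIBRATED
OGDH,Ka,1.1,mM,PAPER-Table1
OGDH,Kb,0.05,mM,PAPER-Table1
OGDH,Kc,0.4,mM,PAPER-Table1
OGDH,Kp,0.5,mM,SM1-ASSUMED
OGDH,Kq,0.03,mM,SM1-ASSUMED
OGDH,Keq,1.7e8,mM,LITERATURE
SCS,Vmaxf,68.97247630061445,nmol/min/mg,CALIBRATED
SCS,Ka,0.05,mM,LITERATURE
SCS,Kb,0.25,mM,LITERATURE
SCS,Kc,2.5,mM,LITERATURE
SCS,Kp,0.6,mM,LITERATURE
SCS,Kq,0.07,mM,LITERATURE
SCS,Kr,2.0,mM,LITERATURE
SCS,Keq,3.7,dimensionless,LITERATURE
SDH,Vmaxf,19.19096261849166,nmol/min/mg,CALIBRATED
SDH,Ka,0.07,mM,SM1-ASSUMED
SDH,Kb,0.1,mM,SM1-ASSUMED
SDH,Kp,0.15,mM,SM1-ASSUMED
SDH,Kq,0.6,mM,SM1-ASSUMED
SDH,Keq,30.0,dimensionless,LITERATURE
FH,Vmaxf,172.0,nmol/min/mg,PAPER-Table1
FH,Ka,0.53,mM,PAPER-Table1
FH,Vmaxr,187.0,nmol/min/mg,PAPER-Table1
FH,Kp,1.7,mM,PAPER-Table1
MDH,Vmaxf,523.0,nmol/min/mg,PAPER-Table1
MDH,Ka,0.11,mM,SM1-ASSUMED
MDH,Kb,0.45,mM,SM1-ASSUMED
MDH,Vmaxr,1103.0,nmol/min/mg,PAPER-Table1
MDH,Kp,0.05,mM,PAPER-Table1
MDH,Kq,0.04,mM,PAPER-Table1
AST,Vmaxf,417.0,nmol/min/mg,PAPER-Table1
AST,Ka,0.6,mM,SM1-ASSUMED
AST,Kb,1.3,mM,SM1-ASSUMED
AST,Kp,0.04,mM,SM1-ASSUMED
AST,Kq,4.0,mM,SM1-ASSUMED
AST,Keq,0.15,dimensionless,LITERATURE
ALT,Vmaxf,56.0,nmol/min/mg,PAPER-Table1
ALT,Ka,9.0,mM,PAPER-Table1
ALT,Kb,1.0,mM,PAPER-Table1
ALT,Kp,2.0,mM,SM1-ASSUMED
ALT,Kq,4.0,mM,SM1-ASSUMED
ALT,Keq,0.7,dimensionless,LITERATURE
GDH,Vmaxf,2.0,nmol/min/mg,SM1-ASSUMED
GDH,Vmaxr,19.0,nmol/min/mg,SM1-ASSUMED
GDH,Ka,0.53,mM,SM1-ASSUMED
GDH,Kb,8.8,mM,SM1-ASSUMED
GDH,Kp,0.08,mM,SM1-ASSUMED
GDH,Kq,0.04,mM,SM1-ASSUMED
GDH,Kr,1.1,mM,SM1-ASSUMED
GDH,L,1.0,dimensionless,SM1-ASSUMED
GDH,n,2.0,dimensionless,SM1-ASSUMED
GDH,Ki_GTP,0.2,mM,SM1-ASSUMED
GDH,Ka_ADP,1.0,mM,SM1-ASSUMED
GR,Vmaxf,4.863436553176677,nmol/min/mg,CALIBRATED
GR,Ka,0.01,mM,LITERATURE
GR,Kb,0.06,mM,LITERATURE
GR,Kp,0.02,mM,LITERATURE
GR,Kq,20.0,mM,LITERATURE
GR,Kr,20.0,mM,LITERATURE
GR,Keq,5.0e5,mM,LITERATURE
MAL_SUC,Vmaxf,256.21156595938726,nmol/min/mg,CALIBRATED
MAL_SUC,Ka,1.0,mM,LITERATURE
MAL_SUC,Kb,1.0,mM,LITERATURE
MAL_SUC,Kp,1.0,mM,LITERATURE
MAL_SUC,Kq,1.0,mM,LITERATURE
MAL_SUC,Keq,1.0,dimensionless,SM1-ASSUMED
MAL_ISO,Vmaxf,94.31333961066942,nmol/min/mg,CALIBRATED
MAL_ISO,Ka,1.0,mM,LITERATURE
MAL_ISO,Kb,1.0,mM,LITERATURE
MAL_ISO,Kp,1.0,mM,LITERATURE
MAL_ISO,Kq,1.0,mM,LITERATURE
MAL_ISO,Keq,1.0,dimensionless,SM1-ASSUMED
NADH_CONS,Vmaxf,95.0,nmol/min/mg,CALIBRATED
GSH_OX,Vmaxf,3.6331009526732245,nmol/min/mg,CALIBRATED
fixed,Pyr_out,2.0,mM,PROTOCOL
fixed,Mal_out,5.0,mM,PROTOCOL
fixed,Suc_out,0.85,mM,SM1-ASSUMED
fixed,OXO_out,0.05,mM,SM1-ASSUMED
fixed,Iso_out,0.3,mM,SM1-ASSUMED
fixed,ADP,5.0,mM,PROTOCOL
fixed,ATP,2.0,mM,SM1-ASSUMED
fixed,Pi,5.0,mM,PROTOCOL
fixed,GTP,0.3,mM,SM1-ASSUMED
fixed,NH4,1.0,mM,SM1-ASSUMED
fixed,Asp,4.6,mM,SM1-ASSUMED
fixed,Glu,0.31,mM,SM1-ASSUMED
fixed,Ala,4.7,mM,SM1-ASSUMED
fixed,CoQ,1.0,mM,SM1-ASSUMED
fixed,QH2,1.0,mM,SM1-ASSUMED
fixed,CO2,2.2,mM,PAPER
initial,Pyr,1.2,mM,PAPER-Table2
initial,AcCoA,0.003,mM,PAPER-Table2
initial,CoA,0.74,mM,PAPER-Table2
initial,Cit,0.2,mM,PAPER-Table2
initial,Iso,0.4,mM,PAPER-Table2
initial,OXO,0.11,mM,PAPER-Table2
initial,SCoA,0.85,mM,PAPER-Table2
initial,Suc,0.74,mM,PAPER-Table2
initial,Fum,1.2,mM,PAPER-Table2
initial,Mal,2.9,mM,PAPER-Table2
initial,OAA,0.56,mM,PAPER-Table2
initial,NAD,4.8,mM,PAPER-Table2
initial,NADH,0.4,mM,PAPER-Table2
initial,NADP,0.29,mM,PAPER-Table2
initial,NADPH,1.4,mM,PAPER-Table2
initial,GSH,5.3,mM,PAPER-Table2
initial,GSSG,0.18,mM,PAPER-Table2
GDH,activity,0.020000000000000004,dimensionless,CALIBRATED
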