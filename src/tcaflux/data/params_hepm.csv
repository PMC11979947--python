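# Kinetic constants, boundary concentrations and initial state — HepM
# (AS-30D hepatoma mitochondria).  Provenance tags:
#   PAPER-Table1  printed kinetic parameter table
#   PAPER         value stated in the main text
#   PROTOCOL      incubation-medium composition of the flux/metabolite assays
#   LITERATURE    standard literature value (thermodynamic or kinetic)
#   SM1-ASSUMED   stand-in for an unavailable supplementary value
#   CALIBRATED    free activity fitted to the measured fluxes/metabolites
reaction,name,value,units,provenance
PYRT,Vmaxf,24.0,nmol/min/mg,CALIBRATED
PYRT,Ka,0.3,mM,LITERATURE
PYRT,Kp,0.3,mM,LITERATURE
PYRT,Keq,1.0,dimensionless,SM1-ASSUMED
PDH,Vmaxf,15.0,nmol/min/mg,SM1-ASSUMED
PDH,Ka,0.21,mM,PAPER-Table1
PDH,Kb,0.014,mM,PAPER-Table1
PDH,Kc,0.34,mM,PAPER-Table1
PDH,Kp,0.04,mM,SM1-ASSUMED
PDH,Kq,0.03,mM,SM1-ASSUMED
PDH,Keq,7.0e8,mM,LITERATURE
CS,Vmaxf,1260.0,nmol/min/mg,PAPER-Table1
CS,Ka,0.003,mM,PAPER-Table1
CS,Kb,0.011,mM,PAPER-Table1
CS,Kp,0.02,mM,SM1-ASSUMED
CS,Kq,1.0,mM,SM1-ASSUMED
CS,Keq,1.0e6,dimensionless,LITERATURE
ACO,Vmaxf,120.0,nmol/min/mg,SM1-ASSUMED
ACO,Ka,0.26,mM,PAPER-Table1
ACO,Kp,0.12,mM,SM1-ASSUMED
ACO,Keq,4.0,dimensionless,SM1-ASSUMED
IDH_NAD,Vmaxf,51.0,nmol/min/mg,PAPER-Table1
IDH_NAD,Ka,0.25,mM,PAPER-Table1
IDH_NAD,Kb,5.7,mM,PAPER-Table1
IDH_NAD,Kp,1.0,mM,SM1-ASSUMED
IDH_NAD,Kq,0.03,mM,SM1-ASSUMED
IDH_NAD,Ki_NADH_vs_Iso,0.04,mM,PAPER-Table1
IDH_NAD,Ki_NADH_vs_NAD,0.08,mM,PAPER-Table1
IDH_NAD,n,2.33,dimensionless,PAPER-Table1
IDH_NAD,L,0.64,dimensionless,PAPER-Table1
IDH_NAD,Keq,1200.0,mM,LITERATURE
IDH_NADP,Vmaxf,587.0,nmol/min/mg,PAPER-Table1
IDH_NADP,Ka,0.078,mM,PAPER-Table1
IDH_NADP,Kb,0.046,mM,PAPER-Table1
IDH_NADP,Kp,1.0,mM,SM1-ASSUMED
IDH_NADP,Kq,0.015,mM,SM1-ASSUMED
IDH_NADP,Ki_GSH,2.0,mM,SM1-ASSUMED
IDH_NADP,Ki_NAD,0.3,mM,SM1-ASSUMED
IDH_NADP,Keq,1200.0,mM,LITERATURE
OGDH,Vmaxf,22.0,nmol/min/mg,PAPER-Table1
OGDH,Ka,1.0,mM,PAPER-Table1
OGDH,Kb,0.015,mM,PAPER-Table1
OGDH,Kc,0.4,mM,PAPER-Table1
OGDH,Kp,0.5,mM,SM1-ASSUMED
OGDH,Kq,0.03,mM,SM1-ASSUMED
OGDH,Keq,1.7e8,mM,LITERATURE
SCS,Vmaxf,31.5,nmol/min/mg,CALIBRATED
SCS,Ka,0.05,mM,LITERATURE
SCS,Kb,0.25,mM,LITERATURE
SCS,Kc,2.5,mM,LITERATURE
SCS,Kp,0.6,mM,LITERATURE
SCS,Kq,0.07,mM,LITERATURE
SCS,Kr,2.0,mM,LITERATURE
SCS,Keq,3.7,dimensionless,LITERATURE
SDH,Vmaxf,21.0,nmol/min/mg,SM1-ASSUMED
SDH,Ka,0.07,mM,PAPER-Table1
SDH,Kb,0.1,mM,SM1-ASSUMED
SDH,Kp,0.15,mM,SM1-ASSUMED
SDH,Kq,0.6,mM,SM1-ASSUMED
SDH,Keq,30.0,dimensionless,LITERATURE
FH,Vmaxf,3356.0,nmol/min/mg,PAPER-Table1
FH,Ka,1.0,mM,PAPER-Table1
FH,Vmaxr,340.0,nmol/min/mg,PAPER-Table1
FH,Kp,0.4,mM,PAPER-Table1
MDH,Vmaxf,269.0,nmol/min/mg,PAPER-Table1
MDH,Ka,0.11,mM,PAPER-Table1
MDH,Kb,0.45,mM,PAPER-Table1
MDH,Vmaxr,2074.0,nmol/min/mg,PAPER-Table1
MDH,Kp,0.007,mM,PAPER-Table1
MDH,Kq,0.017,mM,PAPER-Table1
AST,Vmaxf,527.0,nmol/min/mg,PAPER-Table1
AST,Ka,0.6,mM,PAPER-Table1
AST,Kb,1.3,mM,PAPER-Table1
AST,Kp,0.04,mM,SM1-ASSUMED
AST,Kq,4.0,mM,SM1-ASSUMED
AST,Keq,0.15,dimensionless,LITERATURE
ALT,Vmaxf,327.0,nmol/min/mg,PAPER-Table1
ALT,Ka,10.0,mM,PAPER-Table1
ALT,Kb,2.0,mM,PAPER-Table1
ALT,Kp,2.0,mM,SM1-ASSUMED
ALT,Kq,4.0,mM,SM1-ASSUMED
ALT,Keq,0.7,dimensionless,LITERATURE
ME,Vmaxf,6.5,nmol/min/mg,PAPER-Table1
ME,Ka,0.4,mM,PAPER-Table1
ME,Kb,1.1,mM,PAPER-Table1
ME,Kp,5.0,mM,SM1-ASSUMED
ME,Kq,0.05,mM,SM1-ASSUMED
ME,Keq,23.0,mM,SM1-ASSUMED
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
GR,Vmaxf,8.5,nmol/min/mg,CALIBRATED
GR,Ka,0.01,mM,LITERATURE
GR,Kb,0.06,mM,LITERATURE
GR,Kp,0.02,mM,LITERATURE
GR,Kq,20.0,mM,LITERATURE
GR,Kr,20.0,mM,LITERATURE
GR,Keq,5.0e5,mM,LITERATURE
MAL_SUC,Vmaxf,20.0,nmol/min/mg,CALIBRATED
MAL_SUC,Ka,1.0,mM,LITERATURE
MAL_SUC,Kb,1.0,mM,LITERATURE
MAL_SUC,Kp,1.0,mM,LITERATURE
MAL_SUC,Kq,1.0,mM,LITERATURE
MAL_SUC,Keq,1.0,dimensionless,SM1-ASSUMED
MAL_ISO,Vmaxf,60.0,nmol/min/mg,CALIBRATED
MAL_ISO,Ka,1.0,mM,LITERATURE
MAL_ISO,Kb,1.0,mM,LITERATURE
MAL_ISO,Kp,1.0,mM,LITERATURE
MAL_ISO,Kq,1.0,mM,LITERATURE
MAL_ISO,Keq,1.0,dimensionless,SM1-ASSUMED
MAL_OXO,Vmaxf,1000.0,nmol/min/mg,CALIBRATED
MAL_OXO,Ka,1.0,mM,LITERATURE
MAL_OXO,Kb,0.3,mM,LITERATURE
MAL_OXO,Kp,1.0,mM,LITERATURE
MAL_OXO,Kq,0.3,mM,LITERATURE
MAL_OXO,Keq,1.0,dimensionless,SM1-ASSUMED
NADH_CONS,Vmaxf,100.0,nmol/min/mg,CALIBRATED
GSH_OX,Vmaxf,7.2,nmol/min/mg,CALIBRATED
fixed,Pyr_out,2.0,mM,PROTOCOL
fixed,Mal_out,5.0,mM,PROTOCOL
fixed,Suc_out,2.0,mM,SM1-ASSUMED
fixed,OXO_out,1.0,mM,SM1-ASSUMED
fixed,Iso_out,0.15,mM,SM1-ASSUMED
fixed,ADP,5.0,mM,PROTOCOL
fixed,ATP,2.0,mM,SM1-ASSUMED
fixed,Pi,5.0,mM,PROTOCOL
fixed,GTP,0.3,mM,SM1-ASSUMED
fixed,NH4,1.0,mM,SM1-ASSUMED
fixed,Asp,1.5,mM,SM1-ASSUMED
fixed,Glu,3.0,mM,SM1-ASSUMED
fixed,Ala,1.8,mM,SM1-ASSUMED
fixed,CoQ,1.0,mM,SM1-ASSUMED
fixed,QH2,1.0,mM,SM1-ASSUMED
fixed,CO2,2.2,mM,PAPER
initial,Pyr,0.23,mM,PAPER-Table2
initial,AcCoA,0.003,mM,PAPER-Table2
initial,CoA,1.1,mM,PAPER-Table2
initial,Cit,0.11,mM,PAPER-Table2
initial,Iso,0.13,mM,PAPER-Table2
initial,OXO,0.1,mM,PAPER-Table2
initial,SCoA,0.8,mM,PAPER-Table2
initial,Suc,0.5,mM,PAPER-Table2
initial,Fum,0.42,mM,PAPER-Table2
initial,Mal,1.41,mM,PAPER-Table2
initial,OAA,0.07,mM,PAPER-Table2
initial,NAD,5.2,mM,PAPER-Table2
initial,NADH,0.02,mM,PAPER-Table2
initial,NADP,0.33,mM,PAPER-Table2
initial,NADPH,1.37,mM,PAPER-Table2
initial,GSH,3.2,mM,PAPER-Table2
initial,GSSG,0.39,mM,PAPER-Table2
GDH,activity,0.45,dimensionless,CALIBRATED
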