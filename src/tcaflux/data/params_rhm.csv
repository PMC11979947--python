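# Kinetic constants, boundary concentrations and initial state — RHM
# (rat heart mitochondria).  No alanine aminotransferase in this model;
# PDH runs at a fixed two-fold activity adjustment (activity = 2).
# The allosteric constants of the NAD-dependent IDH were not determined in
# heart; the liver values are used with the heart Michaelis block
# (tagged SM1-ASSUMED).  Provenance tags as in params_hepm.csv.
reaction,name,value,units,provenance
PYRT,Vmaxf,470.0,nmol/min/mg,CALIBRATED
PYRT,Ka,0.3,mM,LITERATURE
PYRT,Kp,0.3,mM,LITERATURE
PYRT,Keq,1.0,dimensionless,SM1-ASSUMED
PDH,Vmaxf,44.0,nmol/min/mg,PAPER-Table1
PDH,activity,2.0,dimensionless,PAPER
PDH,Ka,0.2,mM,PAPER-Table1
PDH,Kb,0.04,mM,PAPER-Table1
PDH,Kc,0.6,mM,PAPER-Table1
PDH,Kp,0.04,mM,SM1-ASSUMED
PDH,Kq,0.03,mM,SM1-ASSUMED
PDH,Keq,7.0e8,mM,LITERATURE
CS,Vmaxf,1128.0,nmol/min/mg,PAPER-Table1
CS,Ka,0.004,mM,PAPER-Table1
CS,Kb,0.007,mM,PAPER-Table1
CS,Kp,0.05,mM,SM1-ASSUMED
CS,Kq,1.0,mM,SM1-ASSUMED
CS,Keq,1.0e6,dimensionless,LITERATURE
ACO,Vmaxf,134.0834492109713,nmol/min/mg,CALIBRATED
ACO,Ka,0.22,mM,PAPER-Table1
ACO,Kp,0.12,mM,SM1-ASSUMED
ACO,Keq,4.0,dimensionless,SM1-ASSUMED
IDH_NAD,Vmaxf,225.0,nmol/min/mg,PAPER-Table1
IDH_NAD,Ka,0.2,mM,PAPER-Table1
IDH_NAD,Kb,1.8,mM,PAPER-Table1
IDH_NAD,Kp,1.0,mM,SM1-ASSUMED
IDH_NAD,Kq,0.03,mM,SM1-ASSUMED
IDH_NAD,Ki_NADH_vs_Iso,0.03,mM,SM1-ASSUMED
IDH_NAD,Ki_NADH_vs_NAD,0.05,mM,SM1-ASSUMED
IDH_NAD,n,1.9,dimensionless,SM1-ASSUMED
IDH_NAD,L,1.5,dimensionless,SM1-ASSUMED
IDH_NAD,Keq,1200.0,mM,LITERATURE
IDH_NADP,Vmaxf,1059.0,nmol/min/mg,PAPER-Table1
IDH_NADP,Ka,0.02,mM,PAPER-Table1
IDH_NADP,Kb,0.03,mM,PAPER-Table1
IDH_NADP,Kp,1.0,mM,SM1-ASSUMED
IDH_NADP,Kq,0.015,mM,SM1-ASSUMED
IDH_NADP,Ki_GSH,2.0,mM,SM1-ASSUMED
IDH_NADP,Ki_NAD,0.3,mM,SM1-ASSUMED
IDH_NADP,Keq,1200.0,mM,LITERATURE
OGDH,Vmaxf,58.0,nmol/min/mg,PAPER-Table1
OGDH,Ka,0.4,mM,PAPER-Table1
OGDH,Kb,0.02,mM,PAPER-Table1
OGDH,Kc,0.5,mM,PAPER-Table1
OGDH,Kp,0.5,mM,SM1-ASSUMED
OGDH,Kq,0.03,mM,SM1-ASSUMED
OGDH,Keq,1.7e8,mM,LITERATURE
SCS,Vmaxf,43.70039289607817,nmol/min/mg,CALIBRATED
SCS,Ka,0.05,mM,LITERATURE
SCS,Kb,0.25,mM,LITERATURE
SCS,Kc,2.5,mM,LITERATURE
SCS,Kp,0.6,mM,LITERATURE
SCS,Kq,0.07,mM,LITERATURE
SCS,Kr,2.0,mM,LITERATURE
SCS,Keq,3.7,dimensionless,LITERATURE
SDH,Vmaxf,18.055966211888954,nmol/min/mg,CALIBRATED
SDH,Ka,1.0,mM,PAPER-Table1
SDH,Kb,0.1,mM,SM1-ASSUMED
SDH,Kp,0.15,mM,SM1-ASSUMED
SDH,Kq,0.6,mM,SM1-ASSUMED
SDH,Keq,30.0,dimensionless,LITERATURE
FH,Vmaxf,527.0,nmol/min/mg,PAPER-Table1
FH,Ka,0.26,mM,PAPER-Table1
FH,Vmaxr,523.0,nmol/min/mg,PAPER-Table1
FH,Kp,0.3,mM,PAPER-Table1
MDH,Vmaxf,1320.0,nmol/min/mg,PAPER-Table1
MDH,Ka,0.2,mM,PAPER-Table1
MDH,Kb,1.4,mM,PAPER-Table1
MDH,Vmaxr,666.0,nmol/min/mg,PAPER-Table1
MDH,Kp,0.01,mM,PAPER-Table1
MDH,Kq,0.02,mM,PAPER-Table1
AST,Vmaxf,175.0,nmol/min/mg,SM1-ASSUMED
AST,Ka,0.6,mM,SM1-ASSUMED
AST,Kb,1.3,mM,SM1-ASSUMED
AST,Kp,0.04,mM,SM1-ASSUMED
AST,Kq,4.0,mM,SM1-ASSUMED
AST,Keq,0.15,dimensionless,LITERATURE
ME,Vmaxf,70.0,nmol/min/mg,PAPER-Table1
ME,Ka,0.5,mM,PAPER-Table1
ME,Kb,1.4,mM,PAPER-Table1
ME,Kp,5.0,mM,SM1-ASSUMED
ME,Kq,0.05,mM,SM1-ASSUMED
ME,Keq,23.0,mM,SM1-ASSUMED
GDH,Vmaxf,2.0,nmol/min/mg,PAPER-Table1
GDH,Vmaxr,19.0,nmol/min/mg,PAPER-Table1
GDH,Ka,0.53,mM,PAPER-Table1
GDH,Kb,8.8,mM,PAPER-Table1
GDH,Kp,0.08,mM,PAPER-Table1
GDH,Kq,0.04,mM,SM1-ASSUMED
GDH,Kr,1.1,mM,SM1-ASSUMED
GDH,L,1.0,dimensionless,SM1-ASSUMED
GDH,n,2.0,dimensionless,SM1-ASSUMED
GDH,Ki_GTP,0.2,mM,SM1-ASSUMED
GDH,Ka_ADP,1.0,mM,SM1-ASSUMED
GR,Vmaxf,3.6384188271115034,nmol/min/mg,CALIBRATED
GR,Ka,0.01,mM,LITERATURE
GR,Kb,0.06,mM,LITERATURE
GR,Kp,0.02,mM,LITERATURE
GR,Kq,20.0,mM,LITERATURE
GR,Kr,20.0,mM,LITERATURE
GR,Keq,5.0e5,mM,LITERATURE
MAL_SUC,Vmaxf,8.690936286993582,nmol/min/mg,CALIBRATED
MAL_SUC,Ka,1.0,mM,LITERATURE
MAL_SUC,Kb,1.0,mM,LITERATURE
MAL_SUC,Kp,1.0,mM,LITERATURE
MAL_SUC,Kq,1.0,mM,LITERATURE
MAL_SUC,Keq,1.0,dimensionless,SM1-ASSUMED
MAL_ISO,Vmaxf,1220.0193715403675,nmol/min/mg,CALIBRATED
MAL_ISO,Ka,1.0,mM,LITERATURE
MAL_ISO,Kb,1.0,mM,LITERATURE
MAL_ISO,Kp,1.0,mM,LITERATURE
MAL_ISO,Kq,1.0,mM,LITERATURE
MAL_ISO,Keq,1.0,dimensionless,SM1-ASSUMED
MAL_OXO,Vmaxf,65.62823330538168,nmol/min/mg,CALIBRATED
MAL_OXO,Ka,1.0,mM,LITERATURE
MAL_OXO,Kb,0.3,mM,LITERATURE
MAL_OXO,Kp,1.0,mM,LITERATURE
MAL_OXO,Kq,0.3,mM,LITERATURE
MAL_OXO,Keq,1.0,dimensionless,SM1-ASSUMED
NADH_CONS,Vmaxf,187.3038203331716,nmol/min/mg,CALIBRATED
GSH_OX,Vmaxf,3.2356497029578586,nmol/min/mg,CALIBRATED
fixed,Pyr_out,2.0,mM,PROTOCOL
fixed,Mal_out,5.0,mM,PROTOCOL
fixed,Suc_out,1.5,mM,SM1-ASSUMED
fixed,OXO_out,0.06,mM,SM1-ASSUMED
fixed,Iso_out,0.4,mM,SM1-ASSUMED
fixed,ADP,5.0,mM,PROTOCOL
fixed,ATP,2.0,mM,SM1-ASSUMED
fixed,Pi,5.0,mM,PROTOCOL
fixed,GTP,0.3,mM,SM1-ASSUMED
fixed,NH4,1.0,mM,SM1-ASSUMED
fixed,Asp,1.0,mM,SM1-ASSUMED
fixed,Glu,3.0,mM,SM1-ASSUMED
fixed,Ala,1.0,mM,SM1-ASSUMED
fixed,CoQ,1.0,mM,SM1-ASSUMED
fixed,QH2,1.0,mM,SM1-ASSUMED
fixed,CO2,2.2,mM,PAPER
initial,Pyr,1.3828190043853714,mM,STEADY-STATE
initial,AcCoA,0.029786743416318262,mM,STEADY-STATE
initial,CoA,1.7469552879079695,mM,STEADY-STATE
initial,Cit,0.5968625084866068,mM,STEADY-STATE
initial,Iso,0.08943536830496206,mM,STEADY-STATE
initial,OXO,0.00023536831201055426,mM,STEADY-STATE
initial,SCoA,0.1637163118760523,mM,STEADY-STATE
initial,Suc,1.0365692624266196,mM,STEADY-STATE
initial,Fum,0.10800193918162274,mM,STEADY-STATE
initial,Mal,0.11169351715719346,mM,STEADY-STATE
initial,OAA,0.007688002442140514,mM,STEADY-STATE
initial,NAD,5.115113228603475,mM,STEADY-STATE
initial,NADH,0.005064967373226814,mM,STEADY-STATE
initial,NADP,0.01091758964907387,mM,STEADY-STATE
initial,NADPH,1.6780274789413558,mM,STEADY-STATE
initial,GSH,3.907648624308768,mM,STEADY-STATE
initial,GSSG,0.4861757208089432,mM,STEADY-STATE
GDH,activity,0.3,dimensionless,CALIBRATED
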