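# Measured intramitochondrial metabolite concentrations (mM) and Krebs-cycle
# flux (nmol/min/mg) under the pyruvate/malate condition.  kind=point rows
# carry replicate mean/SD/n; kind=range rows are literature intervals.
tissue,name,kind,mean,sd,n,lo,hi
HepM,Pyr,point,0.21,0.17,5,,
HepM,Cit,point,0.06,0.03,3,,
HepM,Iso,point,0.07,0.05,4,,
HepM,OXO,point,0.5,0.4,3,,
HepM,SCoA,point,0.5,0.05,3,,
HepM,Suc,point,0.9,0.16,3,,
HepM,Fum,point,0.31,0.1,3,,
HepM,Mal,point,1.35,0.26,3,,
HepM,OAA,point,0.1,0.09,5,,
HepM,CoA,range,,,1,0.27,2.4
HepM,AcCoA,range,,,1,0.1,0.86
HepM,NAD,range,,,1,4.0,6.4
HepM,NADH,range,,,1,0.1,0.3
HepM,NADP,range,,,1,0.5,1.35
HepM,NADPH,range,,,1,0.2,1.2
HepM,GSH,range,,,1,1.6,5.0
HepM,GSSG,range,,,1,0.35,0.35
HepM,KC_flux,point,66.0,1.0,4,,
RLM,Pyr,point,1.0,0.6,4,,
RLM,Cit,point,3.0,1.8,5,,
RLM,Iso,point,0.15,0.08,5,,
RLM,OXO,point,0.18,0.17,4,,
RLM,SCoA,point,0.2,0.2,4,,
RLM,Suc,point,0.63,0.37,4,,
RLM,Fum,point,0.18,0.02,3,,
RLM,Mal,point,2.0,0.71,3,,
RLM,OAA,point,0.2,0.11,4,,
RLM,CoA,range,,,1,0.27,2.4
RLM,AcCoA,range,,,1,0.1,0.86
RLM,NAD,range,,,1,4.0,6.4
RLM,NADH,range,,,1,0.1,0.3
RLM,NADP,range,,,1,0.5,1.35
RLM,NADPH,range,,,1,0.5,1.35
RLM,GSH,range,,,1,2.8,7.4
RLM,GSSG,range,,,1,0.1,0.5
RLM,KC_flux,point,45.0,3.0,4,,
RHM,Pyr,point,0.16,0.11,6,,
RHM,Cit,point,0.8,0.8,6,,
RHM,Iso,point,0.31,0.02,5,,
RHM,OXO,point,0.05,0.004,3,,
RHM,SCoA,point,0.5,0.57,3,,
RHM,Suc,point,1.2,1.0,3,,
RHM,Fum,point,0.05,0.03,6,,
RHM,Mal,point,2.0,1.0,6,,
RHM,OAA,point,0.1,0.03,5,,
RHM,CoA,range,,,1,0.27,2.4
RHM,AcCoA,range,,,1,0.1,0.86
RHM,NAD,range,,,1,4.0,6.4
RHM,NADH,range,,,1,0.1,0.3
RHM,NADP,range,,,1,0.5,1.35
RHM,NADPH,range,,,1,0.5,1.35
RHM,GSH,range,,,1,3.4,5.0
RHM,GSSG,range,,,1,0.15,0.55
RHM,KC_flux,point,152.0,4.0,4,,
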