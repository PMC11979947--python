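# Shared reaction-network topology of the three mitochondrial Krebs-cycle
# models.  Tissue-specific kinetic constants, fixed boundary concentrations
# and initial concentrations live in params_<tissue>.csv; the `tissues` key
# of each reaction encodes which models include it.
#
# Species naming: OXO = 2-oxoglutarate, SCoA = succinyl-CoA; the `_out`
# suffix marks extramitochondrial (fixed) pools.

species:
  variable:
    [Pyr, AcCoA, CoA, Cit, Iso, OXO, SCoA, Suc, Fum, Mal, OAA,
     NAD, NADH, NADP, NADPH, GSH, GSSG]
  fixed:
    [Pyr_out, Mal_out, Suc_out, OXO_out, Iso_out,
     ADP, ATP, Pi, GTP, NH4, Asp, Glu, Ala, CoQ, QH2, CO2]

# Conserved cofactor pools; totals are set per tissue from the initial state.
moieties:
  - id: NAD_pool
    coefficients: {NAD: 1, NADH: 1}
  - id: NADP_pool
    coefficients: {NADP: 1, NADPH: 1}
  - id: glutathione_pool
    coefficients: {GSH: 1, GSSG: 2}
  - id: CoA_pool
    coefficients: {CoA: 1, AcCoA: 1, SCoA: 1}

reactions:
  - id: PYRT
    name: pyruvate transporter
    mechanism: uni_uni
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Pyr_out: -1, Pyr: 1}
    roles: {A: Pyr_out, P: Pyr}

  - id: PDH
    name: pyruvate dehydrogenase complex
    mechanism: ter_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Pyr: -1, CoA: -1, NAD: -1, AcCoA: 1, NADH: 1}
    roles: {A: Pyr, B: CoA, C: NAD, P: AcCoA, Q: NADH}
    co2_folded: true

  - id: CS
    name: citrate synthase
    mechanism: random_bi_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {AcCoA: -1, OAA: -1, CoA: 1, Cit: 1}
    roles: {A: AcCoA, B: OAA, P: CoA, Q: Cit}

  - id: ACO
    name: aconitase
    mechanism: uni_uni
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Cit: -1, Iso: 1}
    roles: {A: Cit, P: Iso}

  - id: IDH_NAD
    name: NAD-dependent isocitrate dehydrogenase
    mechanism: mwc_idh
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NAD: -1, Iso: -1, OXO: 1, NADH: 1}
    roles: {A: NAD, B: Iso, P: OXO, Q: NADH}
    co2_folded: true

  - id: IDH_NADP
    name: NADP-dependent isocitrate dehydrogenase
    mechanism: bi_bi_inhib
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NADP: -1, Iso: -1, OXO: 1, NADPH: 1}
    roles: {A: NADP, B: Iso, P: OXO, Q: NADPH, GSH: GSH, NAD: NAD}
    co2_folded: true

  - id: OGDH
    name: 2-oxoglutarate dehydrogenase complex
    mechanism: ter_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {OXO: -1, CoA: -1, NAD: -1, SCoA: 1, NADH: 1}
    roles: {A: OXO, B: CoA, C: NAD, P: SCoA, Q: NADH}
    co2_folded: true

  - id: SCS
    name: succinyl-CoA synthetase (ADP isoform)
    mechanism: ter_ter
    tissues: [HepM, RLM, RHM]
    stoichiometry: {SCoA: -1, CoA: 1, Suc: 1}
    roles: {A: SCoA, B: ADP, C: Pi, P: ATP, Q: CoA, R: Suc}

  - id: SDH
    name: succinate dehydrogenase
    mechanism: bi_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Suc: -1, Fum: 1}
    roles: {A: Suc, B: CoQ, P: QH2, Q: Fum}

  - id: FH
    name: fumarase
    mechanism: uni_uni_2V
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Fum: -1, Mal: 1}
    roles: {A: Fum, P: Mal}

  - id: MDH
    name: malate dehydrogenase
    mechanism: bi_bi_2V
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NAD: -1, Mal: -1, OAA: 1, NADH: 1}
    roles: {A: NAD, B: Mal, P: OAA, Q: NADH}

  - id: AST
    name: aspartate aminotransferase
    mechanism: bi_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {OXO: -1, OAA: 1}
    roles: {A: Asp, B: OXO, P: OAA, Q: Glu}

  - id: ALT
    name: alanine aminotransferase
    mechanism: bi_bi
    tissues: [HepM, RLM]
    stoichiometry: {OXO: -1, Pyr: 1}
    roles: {A: Ala, B: OXO, P: Pyr, Q: Glu}

  - id: ME
    name: malic enzyme
    mechanism: bi_bi
    tissues: [HepM, RHM]
    stoichiometry: {NADP: -1, Mal: -1, Pyr: 1, NADPH: 1}
    roles: {A: NADP, B: Mal, P: Pyr, Q: NADPH}

  - id: GDH
    name: glutamate dehydrogenase
    mechanism: gdh_mwc
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NADP: -1, OXO: 1, NADPH: 1}
    roles: {A: NADP, B: Glu, P: OXO, Q: NADPH, R: NH4, GTP: GTP, ADP: ADP}

  - id: GR
    name: glutathione reductase
    mechanism: gr_bi_ter
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NADPH: -1, GSSG: -1, NADP: 1, GSH: 2}
    roles: {A: NADPH, B: GSSG, P: NADP, Q: GSH}

  - id: MAL_SUC
    name: malate/succinate exchanger
    mechanism: bi_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Suc: -1, Mal: 1}
    roles: {A: Mal_out, B: Suc, P: Mal, Q: Suc_out}

  - id: MAL_ISO
    name: malate/isocitrate exchanger
    mechanism: bi_bi
    tissues: [HepM, RLM, RHM]
    stoichiometry: {Iso: -1, Mal: 1}
    roles: {A: Mal_out, B: Iso, P: Mal, Q: Iso_out}

  - id: MAL_OXO
    name: malate/2-oxoglutarate exchanger
    mechanism: bi_bi
    tissues: [HepM, RHM]
    stoichiometry: {OXO: -1, Mal: 1}
    roles: {A: Mal_out, B: OXO, P: Mal, Q: OXO_out}

  - id: NADH_CONS
    name: NADH consumption (complex I)
    mechanism: constant_flux
    tissues: [HepM, RLM, RHM]
    stoichiometry: {NADH: -1, NAD: 1}
    roles: {S: NADH}

  - id: GSH_OX
    name: GSH oxidation (peroxidase + ROS)
    mechanism: constant_flux
    tissues: [HepM, RLM, RHM]
    stoichiometry: {GSH: -2, GSSG: 1}
    roles: {S: GSH}
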