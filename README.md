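# tcaflux

Tissue-specific kinetic models of the mitochondrial Krebs cycle with
steady-state solving, least-squares calibration and metabolic control
analysis (MCA).

Three models are shipped, one per mitochondrial preparation:

| id   | tissue                         | notes                                            |
|------|--------------------------------|--------------------------------------------------|
| HepM | AS-30D hepatoma mitochondria   | full network                                     |
| RLM  | rat liver mitochondria         | no malic enzyme, no malate/2-oxoglutarate exchanger |
| RHM  | rat heart mitochondria         | no alanine aminotransferase; PDH at fixed 2× activity |

Each model couples the cycle proper (citrate synthase through malate
dehydrogenase) with the anaplerotic enzymes (PDH, GDH, AST, ALT, ME), the
membrane exchangers (pyruvate transport, Mal/Suc, Mal/Iso, Mal/2-oxo), the
glutathione system (NADP-IDH, glutathione reductase, GSH oxidation) and a
constant-flux NADH-consumption reaction standing in for respiratory
complex I.  Four cofactor pools (NAD, NADP, glutathione, CoA) are conserved
moieties.  Concentrations are mM, rates nmol·min⁻¹·mg⁻¹ (numerically equal
to mM·min⁻¹ at the default matrix volume of 1 µL per mg protein).

## Library quick start

```python
from tcaflux import build_model, solve_steady_state
from tcaflux.mca import control_analysis

net = build_model("HepM")
ss = solve_steady_state(net)
print(ss.kc_flux)                       # Krebs-cycle flux = MDH flux
ca = control_analysis(net, ss)          # FCCs on MDH, CCCs on NADH
print(ca.fcc["NADH_CONS"], ca.ccc["NADH_CONS"])
```

Module map: `rate_laws` (all kinetic rate equations), `model_assembly`
(network construction from the `data/` fixtures), `steady_state` (stiff
integration + damped Newton with moiety elimination), `mca`
(finite-difference and matrix-method control coefficients), `calibration`
(bounded multi-start least squares over the free activities),
`scenarios` (O₂↔flux stoichiometry, activity titrations), `synthetic_data`
(log-normal replicate observation sets, recovery experiments),
`interfaces` (tabular IO, SBML Level 3 export/import, CLI).

## Command line

```sh
tcaflux build --tissue HepM
tcaflux steady-state --tissue HepM --out-dir results
tcaflux mca --tissue HepM --flux MDH --species NADH
tcaflux calibrate --tissue RLM --targets table2 --seed 1
tcaflux titrate --tissue HepM --reaction NADH_CONS
tcaflux synth --tissue RHM --seed 7 --noise-cv 0.25
tcaflux recover --tissue HepM --seed 3
tcaflux export-sbml --tissue RLM
```

All subcommands accept repeatable `--override key=value` parameter
overrides (for example `--override NADH_CONS.Vmaxf=90` or
`--override fixed.ADP=3`).

## Data provenance

`src/tcaflux/data/params_<tissue>.csv` carries every constant with a
provenance tag: `PAPER-Table1` (printed kinetic constants), `PAPER`/
`PROTOCOL` (main-text and assay-medium values), `LITERATURE` (standard
thermodynamic/kinetic values), `SM1-ASSUMED` (stand-ins for unavailable
supplementary values), and `CALIBRATED` (free activities fitted to the
measured data).  The supplementary parameterization of the original study
is not public; quantities that depend on it (notably the exact published
control-coefficient magnitudes and the heart-model flux level) are
approximated by the shipped calibration, and the acceptance suite marks
the corresponding checks accordingly.
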