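"""Assembly of the tissue-specific Krebs-cycle reaction networks.

The network topology (species, reactions, role bindings, conserved
moieties, tissue inclusion) is declared in ``data/network.yaml``; kinetic
constants, fixed boundary concentrations and initial concentrations are
read from ``data/params_<tissue>.csv``.  :func:`build_model` combines the
two into a :class:`ReactionNetwork` ready for simulation.

Tissue-specific exclusions: the liver model (RLM) carries neither malic
enzyme nor the malate/2-oxoglutarate exchanger; the heart model (RHM)
carries no alanine aminotransferase and runs pyruvate dehydrogenase at a
fixed two-fold activity adjustment.
"""

from __future__ import annotations

import copy as _copy
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .rate_laws import MECHANISMS, ConfigurationError, KineticParameterSet

__all__ = [
    "TISSUES",
    "Species",
    "Reaction",
    "Moiety",
    "ReactionNetwork",
    "build_model",
    "stoichiometric_matrix",
    "fold_co2_keq",
    "implied_haldane_keq",
    "load_parameter_table",
    "KC_FLUX_REACTION",
    "CO2_FOLDED_DEFAULT",
]

TISSUES = ("HepM", "RLM", "RHM")

#: The reaction whose flux is reported as the Krebs-cycle flux.
KC_FLUX_REACTION = "MDH"

#: Default CO2 concentration (mM) folded into the equilibrium constants of
#: the decarboxylating reactions.
CO2_FOLDED_DEFAULT = 2.2

_SCALAR_NAMES = {"Vmaxf": "vmaxf", "Vmaxr": "vmaxr", "Keq": "keq",
                 "L": "L", "n": "n"}


def fold_co2_keq(keq_raw: float, co2: float) -> float:
    """Effective equilibrium constant of a decarboxylating reaction.

    The fixed CO2 concentration is folded into the constant as
    ``keq_raw / co2`` so CO2 never appears as a model species.
    """
    return keq_raw / co2


def implied_haldane_keq(p: KineticParameterSet) -> float | None:
    """Equilibrium constant implied by the Haldane relation.

    Only meaningful for the two-Vmax mechanisms, whose parameters are used
    as printed without enforcing thermodynamic consistency; returned purely
    as a diagnostic.
    """
    if p.mechanism == "uni_uni_2V":
        return (p.vmaxf * p.km["Kp"]) / (p.vmaxr * p.km["Ka"])
    if p.mechanism == "bi_bi_2V":
        return ((p.vmaxf * p.km["Kp"] * p.km["Kq"])
                / (p.vmaxr * p.km["Ka"] * p.km["Kb"]))
    return None


@dataclass
class Species:
    """One chemical species: ``variable`` (ODE state) or ``fixed`` boundary."""

    id: str
    role: str  # "variable" | "fixed"
    conc: float  # initial (variable) or clamped (fixed) concentration, mM

    def __post_init__(self) -> None:
        if self.role not in ("variable", "fixed"):
            raise ConfigurationError(f"{self.id}: bad species role {self.role}")
        if self.conc < 0:
            raise ConfigurationError(f"{self.id}: negative concentration")


@dataclass
class Reaction:
    """A reaction: stoichiometry, rate-law binding and an activity factor."""

    id: str
    name: str
    stoichiometry: dict[str, float]
    params: KineticParameterSet
    bindings: dict[str, str]  # role -> species id
    activity: float = 1.0
    keq_raw: float | None = None  # pre-CO2-fold value, kept for round trips

    def __post_init__(self) -> None:
        info = MECHANISMS[self.params.mechanism]
        for role in info.roles:
            if role not in self.bindings:
                raise ConfigurationError(
                    f"{self.id}: role {role!r} required by mechanism "
                    f"{self.params.mechanism!r} is not bound")
        if self.activity <= 0:
            raise ConfigurationError(f"{self.id}: activity must be > 0")


@dataclass
class Moiety:
    """A conserved linear combination of species."""

    id: str
    coefficients: dict[str, float]
    total: float  # mM


@dataclass
class ReactionNetwork:
    tissue: str
    species: dict[str, Species]
    reactions: list[Reaction]
    moieties: list[Moiety] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    # -- structure --------------------------------------------------------
    @property
    def variable_ids(self) -> list[str]:
        return [s.id for s in self.species.values() if s.role == "variable"]

    @property
    def fixed_ids(self) -> list[str]:
        return [s.id for s in self.species.values() if s.role == "fixed"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> np.ndarray:
        return np.array([self.species[s].conc for s in self.variable_ids])

    def stoichiometric_matrix(self) -> np.ndarray:
        """Rows = variable species (in ``variable_ids`` order), columns =
        reactions."""
        var = self.variable_ids
        idx = {s: i for i, s in enumerate(var)}
        S = np.zeros((len(var), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoichiometry.items():
                if sp in idx:
                    S[idx[sp], j] = coeff
        return S

    def moiety_matrix(self) -> np.ndarray:
        """Rows = moieties, columns = variable species."""
        var = self.variable_ids
        idx = {s: i for i, s in enumerate(var)}
        G = np.zeros((len(self.moieties), len(var)))
        for i, m in enumerate(self.moieties):
            for sp, coeff in m.coefficients.items():
                G[i, idx[sp]] = coeff
        return G

    def moiety_totals(self, x: np.ndarray | None = None) -> np.ndarray:
        if x is None:
            x = self.initial_state()
        return self.moiety_matrix() @ x

    # -- evaluation -------------------------------------------------------
    def _compile(self):
        var = self.variable_ids
        pos = {s: i for i, s in enumerate(var)}
        nvar = len(var)
        for i, s in enumerate(self.fixed_ids):
            pos[s] = nvar + i
        compiled = []
        for rxn in self.reactions:
            info = MECHANISMS[rxn.params.mechanism]
            arg_idx = tuple(pos[rxn.bindings[r]] for r in info.roles)
            compiled.append((info.fn, rxn.params, arg_idx))
        fixed_vals = np.array([self.species[s].conc for s in self.fixed_ids])
        self._compiled = compiled
        self._fixed_vals = fixed_vals
        return compiled

    def _invalidate(self) -> None:
        self._compiled = None

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction rates at variable state ``x`` (activity applied)."""
        compiled = getattr(self, "_compiled", None) or self._compile()
        full = np.concatenate([x, self._fixed_vals])
        out = np.empty(len(self.reactions))
        for j, ((fn, p, idx), rxn) in enumerate(zip(compiled, self.reactions)):
            out[j] = rxn.activity * fn(p, *full.take(idx))
        return out

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Time derivative ``S @ v(x)`` of the variable concentrations."""
        return self.stoichiometric_matrix() @ self.rates(x)

    # -- mutation ---------------------------------------------------------
    def set_value(self, key: str, value: float) -> None:
        """Override one quantity.

        Keys: ``"<reaction>.<constant>"`` with constant one of ``Vmaxf``,
        ``Vmaxr``, ``Keq`` (pre-fold value for decarboxylating reactions),
        ``L``, ``n``, ``activity``, any Michaelis constant role name, or an
        inhibition/activation constant; ``"fixed.<species>"`` and
        ``"initial.<species>"`` set clamped and initial concentrations.
        """
        scope, _, name = key.partition(".")
        if scope in ("fixed", "initial"):
            sp = self.species.get(name)
            if sp is None:
                raise KeyError(f"unknown species {name!r} in override {key!r}")
            expected = "fixed" if scope == "fixed" else "variable"
            if sp.role != expected:
                raise ConfigurationError(
                    f"{key}: species {name} has role {sp.role}")
            sp.conc = float(value)
        else:
            rxn = self.reaction(scope)
            if not name:
                raise KeyError(f"override {key!r} lacks a constant name")
            _apply_reaction_param(rxn, name, float(value),
                                  co2=self._co2_for_fold())
        self._invalidate()

    def get_value(self, key: str) -> float:
        scope, _, name = key.partition(".")
        if scope in ("fixed", "initial"):
            return self.species[name].conc
        rxn = self.reaction(scope)
        if name == "activity":
            return rxn.activity
        if name == "Keq" and rxn.keq_raw is not None:
            return rxn.keq_raw
        v = rxn.params._get(_SCALAR_NAMES.get(name, name))
        if v is None:
            raise KeyError(key)
        return v

    def _co2_for_fold(self) -> float:
        sp = self.species.get("CO2")
        return sp.conc if sp is not None else 1.0

    def copy(self) -> "ReactionNetwork":
        new = _copy.deepcopy(self)
        new._invalidate()
        return new

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "species": [
                {"id": s.id, "role": s.role, "conc": s.conc}
                for s in self.species.values()
            ],
            "moieties": [
                {"id": m.id, "coefficients": dict(m.coefficients),
                 "total": m.total}
                for m in self.moieties
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "mechanism": r.params.mechanism,
                    "stoichiometry": dict(r.stoichiometry),
                    "bindings": dict(r.bindings),
                    "activity": r.activity,
                    "keq_raw": r.keq_raw,
                    "params": {
                        "vmaxf": r.params.vmaxf,
                        "vmaxr": r.params.vmaxr,
                        "km": dict(r.params.km),
                        "ki": dict(r.params.ki),
                        "ka_act": dict(r.params.ka_act),
                        "L": r.params.L,
                        "n": r.params.n,
                        "keq": r.params.keq,
                        "co2_folded": r.params.co2_folded,
                    },
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ReactionNetwork":
        species = {
            d["id"]: Species(d["id"], d["role"], d["conc"])
            for d in payload["species"]
        }
        reactions = []
        for d in payload["reactions"]:
            pd_ = d["params"]
            params = KineticParameterSet(
                enzyme_id=d["id"], mechanism=d["mechanism"],
                vmaxf=pd_["vmaxf"], vmaxr=pd_["vmaxr"],
                km=dict(pd_["km"]), ki=dict(pd_["ki"]),
                ka_act=dict(pd_["ka_act"]), L=pd_["L"], n=pd_["n"],
                keq=pd_["keq"], co2_folded=pd_["co2_folded"])
            reactions.append(Reaction(
                id=d["id"], name=d["name"],
                stoichiometry=dict(d["stoichiometry"]), params=params,
                bindings=dict(d["bindings"]), activity=d["activity"],
                keq_raw=d.get("keq_raw")))
        moieties = [Moiety(m["id"], dict(m["coefficients"]), m["total"])
                    for m in payload["moieties"]]
        return cls(tissue=payload["tissue"], species=species,
                   reactions=reactions, moieties=moieties)


def stoichiometric_matrix(net: ReactionNetwork
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Stoichiometric matrix of ``net`` plus a conserved-moiety basis.

    Returns ``(S, G)`` with ``S`` of shape (variable species, reactions)
    and ``G`` a basis of the left null space of ``S`` (rows = conservation
    relations) computed by SVD.
    """
    S = net.stoichiometric_matrix()
    u, s, _ = np.linalg.svd(S)
    tol = max(S.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    rank = int((s > tol).sum())
    G = u[:, rank:].T
    return S, G


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("tcaflux.data").joinpath(name)


def load_network_config() -> dict:
    with _data_path("network.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def load_parameter_table(tissue: str) -> pd.DataFrame:
    """Tabular kinetic-constant fixture for one tissue.

    Columns: ``reaction`` (or ``fixed``/``initial``), ``name``, ``value``,
    ``units``, ``provenance``.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of "
                         f"{TISSUES}")
    fname = f"params_{tissue.lower()}.csv"
    with _data_path(fname).open("r") as fh:
        table = pd.read_csv(fh, comment="#")
    expected = {"reaction", "name", "value", "units", "provenance"}
    if set(table.columns) != expected:
        raise ConfigurationError(f"{fname}: bad columns {list(table.columns)}")
    return table


def printed_vmaxf_table() -> pd.DataFrame:
    """Printed forward limiting rates per enzyme and tissue (NaN where not
    determined); used for cross-tissue activity comparisons."""
    with _data_path("table1_vmaxf.csv").open("r") as fh:
        return pd.read_csv(fh, comment="#", na_values=["NA"]).set_index(
            "enzyme")


def _apply_reaction_param(rxn: Reaction, name: str, value: float,
                          co2: float) -> None:
    p = rxn.params
    if name == "activity":
        if value <= 0:
            raise ConfigurationError(f"{rxn.id}: activity must be > 0")
        rxn.activity = value
        return
    if name in _SCALAR_NAMES:
        attr = _SCALAR_NAMES[name]
        if name == "Keq":
            rxn.keq_raw = value
            p.keq = fold_co2_keq(value, co2) if p.co2_folded else value
        else:
            setattr(p, attr, value)
    elif name.startswith("Ki"):
        p.ki[name] = value
    elif name.startswith("Ka_"):
        p.ka_act[name] = value
    elif name in ("Ka", "Kb", "Kc", "Kp", "Kq", "Kr"):
        p.km[name] = value
    else:
        raise KeyError(f"{rxn.id}: unknown constant {name!r}")
    p.validate()


def build_model(tissue: str,
                overrides: dict[str, float] | None = None
                ) -> ReactionNetwork:
    """Build the reaction network of one tissue from the shipped fixtures.

    Parameters
    ----------
    tissue:
        ``"HepM"``, ``"RLM"`` or ``"RHM"``.
    overrides:
        Optional ``{key: value}`` map applied after loading, with keys as
        accepted by :meth:`ReactionNetwork.set_value`.

    Raises
    ------
    ConfigurationError
        If a required constant is missing from the fixture, naming the
        constant and its provenance slot.
    """
    config = load_network_config()
    table = load_parameter_table(tissue)

    by_reaction: dict[str, dict[str, float]] = {}
    provenance: dict[str, str] = {}
    for row in table.itertuples(index=False):
        by_reaction.setdefault(row.reaction, {})[row.name] = float(row.value)
        provenance[f"{row.reaction}.{row.name}"] = str(row.provenance)

    fixed_vals = by_reaction.pop("fixed", {})
    initial_vals = by_reaction.pop("initial", {})
    co2 = fixed_vals.get("CO2", CO2_FOLDED_DEFAULT)

    species: dict[str, Species] = {}
    for sid in config["species"]["variable"]:
        if sid not in initial_vals:
            raise ConfigurationError(
                f"{tissue}: missing initial concentration for {sid} "
                f"(fixture slot 'initial.{sid}')")
        species[sid] = Species(sid, "variable", initial_vals[sid])
    for sid in config["species"]["fixed"]:
        if sid not in fixed_vals:
            raise ConfigurationError(
                f"{tissue}: missing fixed concentration for {sid} "
                f"(fixture slot 'fixed.{sid}')")
        species[sid] = Species(sid, "fixed", fixed_vals[sid])

    reactions: list[Reaction] = []
    for rdef in config["reactions"]:
        if tissue not in rdef["tissues"]:
            continue
        rid = rdef["id"]
        vals = by_reaction.get(rid)
        if vals is None:
            raise ConfigurationError(
                f"{tissue}: no parameters for reaction {rid} "
                f"(fixture slot '{rid}.*')")
        vals = dict(vals)
        activity = vals.pop("activity", 1.0)
        co2_folded = bool(rdef.get("co2_folded", False))
        keq_raw = vals.pop("Keq", None)
        km = {k: v for k, v in vals.items()
              if k in ("Ka", "Kb", "Kc", "Kp", "Kq", "Kr")}
        ki = {k: v for k, v in vals.items() if k.startswith("Ki")}
        ka_act = {k: v for k, v in vals.items() if k.startswith("Ka_")}
        params = KineticParameterSet(
            enzyme_id=rid, mechanism=rdef["mechanism"],
            vmaxf=vals.get("Vmaxf"), vmaxr=vals.get("Vmaxr"),
            km=km, ki=ki, ka_act=ka_act,
            L=vals.get("L"), n=vals.get("n"),
            keq=(fold_co2_keq(keq_raw, co2) if (co2_folded and
                                                keq_raw is not None)
                 else keq_raw),
            co2_folded=co2_folded)
        reactions.append(Reaction(
            id=rid, name=rdef.get("name", rid),
            stoichiometry=dict(rdef["stoichiometry"]), params=params,
            bindings=dict(rdef["roles"]), activity=activity,
            keq_raw=keq_raw))

    net = ReactionNetwork(tissue=tissue, species=species,
                          reactions=reactions, provenance=provenance)
    net.moieties = [
        Moiety(m["id"], dict(m["coefficients"]), 0.0)
        for m in config["moieties"]
    ]
    totals = net.moiety_totals()
    for m, t in zip(net.moieties, totals):
        m.total = float(t)

    if overrides:
        for key, value in overrides.items():
            net.set_value(key, value)
        # overriding initial concentrations moves the conserved totals
        totals = net.moiety_totals()
        for m, t in zip(net.moieties, totals):
            m.total = float(t)
    return net


def provenance_summary(net: ReactionNetwork) -> dict[str, int]:
    """Counts of fixture values per provenance tag, for run logs."""
    counts: dict[str, int] = {}
    for tag in net.provenance.values():
        counts[tag] = counts.get(tag, 0) + 1
    return counts
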