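import numpy as np
import pytest

from tcaflux.model_assembly import (Moiety, Reaction, ReactionNetwork,
                                    Species, build_model)
from tcaflux.rate_laws import KineticParameterSet
from tcaflux.steady_state import solve_steady_state

TISSUES = ("HepM", "RLM", "RHM")


@pytest.fixture(scope="session")
def tissue_networks():
    return {t: build_model(t) for t in TISSUES}


@pytest.fixture(scope="session")
def tissue_steady_states(tissue_networks):
    return {t: solve_steady_state(net.copy())
            for t, net in tissue_networks.items()}


def make_toy_chain(v0=1.0, vmax=2.0, km=1.0):
    """Constant influx v0 into X, consumed by an irreversible MM sink.

    Closed-form steady state: X* = km * v0 / (vmax - v0).
    """
    species = {
        "SRC": Species("SRC", "fixed", 1.0),
        "X": Species("X", "variable", 0.5),
        "SINK": Species("SINK", "fixed", 0.0),
    }
    influx = Reaction(
        id="influx", name="constant influx",
        stoichiometry={"X": 1},
        params=KineticParameterSet("influx", "constant_flux", vmaxf=v0),
        bindings={"S": "SRC"})
    consumer = Reaction(
        id="consumer", name="MM consumer",
        stoichiometry={"X": -1},
        params=KineticParameterSet(
            "consumer", "uni_uni", vmaxf=vmax,
            km={"Ka": km, "Kp": 1e9}, keq=1e12),
        bindings={"A": "X", "P": "SINK"})
    return ReactionNetwork(tissue="HepM", species=species,
                           reactions=[influx, consumer])


def make_toy_three(v0=1.0):
    """Influx -> X -> Y -> out, with a reversible middle step."""
    species = {
        "SRC": Species("SRC", "fixed", 1.0),
        "X": Species("X", "variable", 0.5),
        "Y": Species("Y", "variable", 0.5),
        "SINK": Species("SINK", "fixed", 0.0),
    }
    r1 = Reaction(
        id="r1", name="influx", stoichiometry={"X": 1},
        params=KineticParameterSet("r1", "constant_flux", vmaxf=v0),
        bindings={"S": "SRC"})
    r2 = Reaction(
        id="r2", name="isomerase", stoichiometry={"X": -1, "Y": 1},
        params=KineticParameterSet(
            "r2", "uni_uni", vmaxf=5.0, km={"Ka": 0.7, "Kp": 1.3}, keq=2.0),
        bindings={"A": "X", "P": "Y"})
    r3 = Reaction(
        id="r3", name="sink", stoichiometry={"Y": -1},
        params=KineticParameterSet(
            "r3", "uni_uni", vmaxf=3.0, km={"Ka": 0.9, "Kp": 1e9}, keq=1e12),
        bindings={"A": "Y", "P": "SINK"})
    return ReactionNetwork(tissue="HepM", species=species,
                           reactions=[r1, r2, r3])


def make_toy_conserved(v0=1.0):
    """Toy with a conserved A/B pool cycled by two reactions, plus the
    chain of :func:`make_toy_chain` coupled to it."""
    species = {
        "SRC": Species("SRC", "fixed", 1.0),
        "X": Species("X", "variable", 0.5),
        "A": Species("A", "variable", 1.5),
        "B": Species("B", "variable", 0.5),
        "SINK": Species("SINK", "fixed", 0.0),
    }
    influx = Reaction(
        id="influx", name="influx", stoichiometry={"X": 1},
        params=KineticParameterSet("influx", "constant_flux", vmaxf=v0),
        bindings={"S": "SRC"})
    convert = Reaction(
        id="convert", name="X + A -> B", stoichiometry={"X": -1, "A": -1,
                                                        "B": 1},
        params=KineticParameterSet(
            "convert", "bi_bi", vmaxf=4.0,
            km={"Ka": 0.5, "Kb": 0.5, "Kp": 1.0, "Kq": 1e6}, keq=1e9),
        bindings={"A": "X", "B": "A", "P": "B", "Q": "SINK"})
    recycle = Reaction(
        id="recycle", name="B -> A", stoichiometry={"B": -1, "A": 1},
        params=KineticParameterSet(
            "recycle", "uni_uni", vmaxf=6.0, km={"Ka": 0.4, "Kp": 2.0},
            keq=50.0),
        bindings={"A": "B", "P": "A"})
    net = ReactionNetwork(tissue="HepM", species=species,
                          reactions=[influx, convert, recycle])
    net.moieties = [Moiety("AB_pool", {"A": 1.0, "B": 1.0}, 2.0)]
    return net


@pytest.fixture
def toy_chain():
    return make_toy_chain()


@pytest.fixture
def toy_three():
    return make_toy_three()


@pytest.fixture
def toy_conserved():
    return make_toy_conserved()


def random_positive_params(rng, mechanism):
    """Random strictly-positive parameter set for one mechanism."""
    def r(lo=0.01, hi=10.0, size=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    km_roles = {"ter_bi": ["Ka", "Kb", "Kc", "Kp", "Kq"],
                "random_bi_bi": ["Ka", "Kb", "Kp", "Kq"],
                "uni_uni": ["Ka", "Kp"],
                "mwc_idh": ["Ka", "Kb", "Kp", "Kq"],
                "bi_bi_inhib": ["Ka", "Kb", "Kp", "Kq"],
                "ter_ter": ["Ka", "Kb", "Kc", "Kp", "Kq", "Kr"],
                "bi_bi": ["Ka", "Kb", "Kp", "Kq"],
                "uni_uni_2V": ["Ka", "Kp"],
                "bi_bi_2V": ["Ka", "Kb", "Kp", "Kq"],
                "gdh_mwc": ["Ka", "Kb", "Kp", "Kq", "Kr"],
                "gr_bi_ter": ["Ka", "Kb", "Kp", "Kq", "Kr"],
                "constant_flux": []}
    ki = {}
    ka_act = {}
    if mechanism == "mwc_idh":
        ki = {"Ki_NADH_vs_Iso": float(r()), "Ki_NADH_vs_NAD": float(r())}
    elif mechanism == "bi_bi_inhib":
        ki = {"Ki_GSH": float(r()), "Ki_NAD": float(r())}
    elif mechanism == "gdh_mwc":
        ki = {"Ki_GTP": float(r())}
        ka_act = {"Ka_ADP": float(r())}
    return KineticParameterSet(
        enzyme_id="rand", mechanism=mechanism,
        vmaxf=float(r(1.0, 1000.0)),
        vmaxr=float(r(1.0, 1000.0))
        if mechanism in ("uni_uni_2V", "bi_bi_2V", "gdh_mwc") else None,
        km={k: float(r()) for k in km_roles[mechanism]},
        ki=ki, ka_act=ka_act,
        L=float(r(0.1, 10.0)) if mechanism in ("mwc_idh", "gdh_mwc")
        else None,
        n=float(rng.uniform(1.0, 4.0)) if mechanism in ("mwc_idh",
                                                        "gdh_mwc") else None,
        keq=float(r(0.1, 1e6))
        if mechanism not in ("uni_uni_2V", "bi_bi_2V", "gdh_mwc",
                             "constant_flux") else None)
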