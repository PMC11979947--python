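"""Kinetic rate laws for the Krebs-cycle models.

Every rate law is a stateless function of non-negative concentrations and a
:class:`KineticParameterSet`.  Concentrations are in mM, rates in
nmol·min⁻¹·mg⁻¹ (numerically equal to mM·min⁻¹ at the default matrix volume
of 1 µL per mg protein).

Substrate/product roles follow the usual ordered-mechanism naming:
``A, B, C`` are substrates with Michaelis constants ``Ka, Kb, Kc``;
``P, Q, R`` are products with ``Kp, Kq, Kr``.  Allosteric mechanisms add a
transition constant ``L``, a site count ``n`` and dedicated
inhibition/activation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "KineticParameterSet",
    "ConfigurationError",
    "MECHANISMS",
    "rate_ter_bi",
    "rate_random_bi_bi",
    "rate_uni_uni",
    "rate_mwc_idh_nad",
    "rate_idh_nadp",
    "rate_ter_ter",
    "rate_bi_bi",
    "rate_uni_uni_2V",
    "rate_bi_bi_2V",
    "rate_gdh",
    "rate_gr",
    "rate_constant_flux",
    "evaluate",
    "CONSTANT_FLUX_GUARD",
]

#: Saturation guard (mM) for the irreversible constant-flux boundary
#: reactions; keeps them from driving their substrate pool negative while
#: being numerically constant at physiological concentrations.
CONSTANT_FLUX_GUARD = 1e-6


class ConfigurationError(ValueError):
    """A mechanism is missing a required constant or has an invalid one."""


@dataclass
class KineticParameterSet:
    """Kinetic constants of one enzyme or transporter.

    Parameters
    ----------
    enzyme_id:
        Identifier of the reaction the set belongs to.
    mechanism:
        One of the keys of :data:`MECHANISMS`.
    vmaxf, vmaxr:
        Forward / reverse limiting rates (nmol·min⁻¹·mg⁻¹).  ``vmaxf``
        doubles as the flux constant of ``constant_flux`` reactions.
    km:
        Michaelis constants keyed by role (``Ka`` … ``Kr``), mM.
    ki:
        Inhibition constants (``Ki_GSH``, ``Ki_NAD``, ``Ki_NADH_vs_Iso``,
        ``Ki_NADH_vs_NAD``, ``Ki_GTP``), mM.
    ka_act:
        Activation constants (``Ka_ADP``), mM.
    L, n:
        MWC transition constant and site count.
    keq:
        Equilibrium constant (dimensionless or mM, per stoichiometry).
    co2_folded:
        True when ``keq`` has already been divided by the fixed CO₂
        concentration of a decarboxylating reaction.
    """

    enzyme_id: str
    mechanism: str
    vmaxf: float | None = None
    vmaxr: float | None = None
    km: dict[str, float] = field(default_factory=dict)
    ki: dict[str, float] = field(default_factory=dict)
    ka_act: dict[str, float] = field(default_factory=dict)
    L: float | None = None
    n: float | None = None
    keq: float | None = None
    co2_folded: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"{self.enzyme_id}: unknown mechanism {self.mechanism!r}"
            )
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        spec = MECHANISMS[self.mechanism]
        for name in spec.required:
            if self._get(name) is None:
                raise ConfigurationError(
                    f"{self.enzyme_id} ({self.mechanism}): missing required "
                    f"constant {name!r}"
                )
        for name, value in [("vmaxf", self.vmaxf), ("vmaxr", self.vmaxr),
                            ("keq", self.keq)]:
            if value is not None and value <= 0:
                raise ConfigurationError(
                    f"{self.enzyme_id}: {name} must be strictly positive"
                )
        for table in (self.km, self.ki, self.ka_act):
            for name, value in table.items():
                if value <= 0:
                    raise ConfigurationError(
                        f"{self.enzyme_id}: constant {name} must be "
                        f"strictly positive"
                    )
        if self.L is not None and self.L < 0:
            raise ConfigurationError(f"{self.enzyme_id}: L must be >= 0")
        if self.n is not None and self.n < 1:
            raise ConfigurationError(f"{self.enzyme_id}: n must be >= 1")
        if self.mechanism in ("mwc_idh", "gdh_mwc"):
            if self.L is not None and self.L <= 0:
                raise ConfigurationError(
                    f"{self.enzyme_id}: allosteric L must be > 0"
                )

    def _get(self, name: str):
        if name in ("vmaxf", "vmaxr", "L", "n", "keq"):
            return getattr(self, name)
        if name.startswith("Ki"):
            return self.ki.get(name)
        if name.startswith("Ka_"):
            return self.ka_act.get(name)
        return self.km.get(name)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def rate_ter_bi(p: KineticParameterSet, A: float, B: float, C: float,
                P: float, Q: float) -> float:
    """Ordered reversible ter-bi rate (three substrates, two products).

    Used for the pyruvate- and 2-oxoglutarate-dehydrogenase complexes with
    CO₂ folded into ``keq``.
    """
    Ka, Kb, Kc = p.km["Ka"], p.km["Kb"], p.km["Kc"]
    Kp, Kq = p.km["Kp"], p.km["Kq"]
    num = (p.vmaxf / (Ka * Kb * Kc)) * (A * B * C - P * Q / p.keq)
    den = (1.0 + A / Ka + A * B / (Ka * Kb) + A * B * C / (Ka * Kb * Kc)
           + P * Q / (Kp * Kq) + Q / Kq)
    return num / den


def rate_random_bi_bi(p: KineticParameterSet, A: float, B: float,
                      P: float, Q: float) -> float:
    """Random-order reversible bi-bi rate (citrate synthase)."""
    Ka, Kb, Kp, Kq = p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"]
    num = (p.vmaxf / (Ka * Kb)) * (A * B - P * Q / p.keq)
    den = (1.0 + A / Ka + B / Kb + A * B / (Ka * Kb)
           + P / Kp + Q / Kq + P * Q / (Kp * Kq)
           + A * Q / (Ka * Kq) + P * B / (Kp * Kb))
    return num / den


def rate_uni_uni(p: KineticParameterSet, A: float, P: float) -> float:
    """Mono-reactant reversible rate (aconitase, pyruvate transport)."""
    Ka, Kp = p.km["Ka"], p.km["Kp"]
    return (p.vmaxf / Ka) * (A - P / p.keq) / (1.0 + A / Ka + P / Kp)


def rate_mwc_idh_nad(p: KineticParameterSet, NAD: float, Iso: float,
                     OXO: float, NADH: float) -> float:
    """NAD⁺-dependent isocitrate dehydrogenase.

    Concerted MWC transition with exclusive isocitrate binding (site count
    ``n``, transition constant ``L``, NADH as allosteric inhibitor via
    ``Ki_NADH_vs_Iso``), gated by a Michaelis term in NAD⁺ (optionally with
    NADH competitive inhibition via ``Ki_NADH_vs_NAD``), minus a reversible
    product term.
    """
    Ka, Kb, Kp, Kq = p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"]
    ki_iso = p.ki["Ki_NADH_vs_Iso"]
    a = NAD / Ka
    ki_nad = p.ki.get("Ki_NADH_vs_NAD")
    if ki_nad is not None:
        a = a / (1.0 + NADH / ki_nad)
    beta = Iso / Kb
    gate = a / (1.0 + a)
    mwc = (beta * (1.0 + beta) ** (p.n - 1.0)
           / (p.L * (1.0 + NADH / ki_iso) ** p.n + (1.0 + beta) ** p.n))
    rev = ((P := OXO) * (Q := NADH) / (Kp * Kq * p.keq)
           / (1.0 + P / Kp + Q / Kq + P * Q / (Kp * Kq)))
    return p.vmaxf * (gate * mwc - rev)


def rate_idh_nadp(p: KineticParameterSet, NADP: float, Iso: float,
                  OXO: float, NADPH: float, GSH: float, NAD: float) -> float:
    """NADP⁺-dependent isocitrate dehydrogenase.

    Ordered bi-bi with GSH competitive inhibition versus isocitrate and
    NAD⁺ competitive inhibition versus NADP⁺.
    """
    Ka, Kb, Kp, Kq = p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"]
    A, B, P, Q = NADP, Iso, OXO, NADPH
    num = (p.vmaxf / (Ka * Kb)) * (A * B - P * Q / p.keq)
    den = (1.0 + A / Ka + A * GSH / (Ka * p.ki["Ki_GSH"])
           + A * B / (Ka * Kb)
           + Q * B / (Kq * Kb) + Q * P / (Kq * Kp) + Q / Kq
           + NAD / p.ki["Ki_NAD"])
    return num / den


def rate_ter_ter(p: KineticParameterSet, A: float, B: float, C: float,
                 P: float, Q: float, R: float) -> float:
    """Ordered reversible ter-ter rate (succinyl-CoA synthetase)."""
    Ka, Kb, Kc = p.km["Ka"], p.km["Kb"], p.km["Kc"]
    Kp, Kq, Kr = p.km["Kp"], p.km["Kq"], p.km["Kr"]
    num = (p.vmaxf / (Ka * Kb * Kc)) * (A * B * C - P * Q * R / p.keq)
    den = (1.0 + A / Ka + A * B / (Ka * Kb) + A * B * C / (Ka * Kb * Kc)
           + P * Q * R / (Kp * Kq * Kr) + Q * R / (Kq * Kr) + R / Kr)
    return num / den


def rate_bi_bi(p: KineticParameterSet, A: float, B: float,
               P: float, Q: float) -> float:
    """Ordered reversible bi-bi rate (SDH, AST, ALT, ME, exchangers)."""
    Ka, Kb, Kp, Kq = p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"]
    num = (p.vmaxf / (Ka * Kb)) * (A * B - P * Q / p.keq)
    den = (1.0 + A / Ka + A * B / (Ka * Kb) + P * Q / (Kp * Kq) + Q / Kq)
    return num / den


def rate_uni_uni_2V(p: KineticParameterSet, A: float, P: float) -> float:
    """Mono-reactant reversible rate with independent Vmaxf/Vmaxr (FH)."""
    Ka, Kp = p.km["Ka"], p.km["Kp"]
    return ((p.vmaxf * A / Ka - p.vmaxr * P / Kp)
            / (1.0 + A / Ka + P / Kp))


def rate_bi_bi_2V(p: KineticParameterSet, A: float, B: float,
                  P: float, Q: float) -> float:
    """Ordered reversible bi-bi rate with independent Vmaxf/Vmaxr (MDH)."""
    Ka, Kb, Kp, Kq = p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"]
    num = (p.vmaxf * A * B / (Ka * Kb) - p.vmaxr * P * Q / (Kp * Kq))
    den = (1.0 + A / Ka + A * B / (Ka * Kb) + P * Q / (Kp * Kq) + Q / Kq)
    return num / den


def rate_gdh(p: KineticParameterSet, NADP: float, Glu: float, OXO: float,
             NADPH: float, NH4: float, GTP: float, ADP: float) -> float:
    """Glutamate dehydrogenase.

    Forward Michaelis terms in NADP⁺ and glutamate; reverse terms in
    2-oxoglutarate and NADPH multiplied by a concerted MWC gate for NH₄⁺
    with GTP inhibition (``Ki_GTP``) and ADP activation (``Ka_ADP``).
    """
    Ka, Kb, Kp, Kq, Kr = (p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"],
                          p.km["Kr"])
    A, B, P, Q, R = NADP, Glu, OXO, NADPH, NH4
    fwd = (A * B / (Ka * Kb)) / (1.0 + A / Ka + A * B / (Ka * Kb))
    rev = (P * Q / (Kp * Kq)) / (1.0 + P / Kp + P * Q / (Kp * Kq))
    rho = R / Kr
    L_eff = (p.L * (1.0 + GTP / p.ki["Ki_GTP"]) ** p.n
             / (1.0 + ADP / p.ka_act["Ka_ADP"]))
    gate = rho * (1.0 + rho) ** (p.n - 1.0) / (L_eff + (1.0 + rho) ** p.n)
    return p.vmaxf * fwd - p.vmaxr * rev * gate


def rate_gr(p: KineticParameterSet, NADPH: float, GSSG: float,
            NADP: float, GSH: float) -> float:
    """Glutathione reductase: ordered bi-ter, products NADP⁺ + 2 GSH."""
    Ka, Kb, Kp, Kq, Kr = (p.km["Ka"], p.km["Kb"], p.km["Kp"], p.km["Kq"],
                          p.km["Kr"])
    A, B, P, Q, R = NADPH, GSSG, NADP, GSH, GSH
    num = (p.vmaxf / (Ka * Kb)) * (A * B - P * Q * R / p.keq)
    den = (1.0 + A / Ka + A * B / (Ka * Kb)
           + P * Q * R / (Kp * Kq * Kr) + Q * R / (Kq * Kr)
           + Q / Kq + R / Kr)
    return num / den


def rate_constant_flux(p: KineticParameterSet, S: float) -> float:
    """Irreversible constant flux with a substrate-depletion guard.

    ``v = Vc * S / (S + eps)`` with ``eps = CONSTANT_FLUX_GUARD``: constant
    for physiological ``S``, zero when the pool is empty.
    """
    return p.vmaxf * S / (S + CONSTANT_FLUX_GUARD)


# ---------------------------------------------------------------------------
# mechanism registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanismInfo:
    """Binding contract of a mechanism: callable, roles, required constants."""

    fn: Callable[..., float]
    roles: tuple[str, ...]
    required: tuple[str, ...]
    reversible: bool = True


MECHANISMS: dict[str, MechanismInfo] = {
    "ter_bi": MechanismInfo(
        rate_ter_bi, ("A", "B", "C", "P", "Q"),
        ("vmaxf", "Ka", "Kb", "Kc", "Kp", "Kq", "keq")),
    "random_bi_bi": MechanismInfo(
        rate_random_bi_bi, ("A", "B", "P", "Q"),
        ("vmaxf", "Ka", "Kb", "Kp", "Kq", "keq")),
    "uni_uni": MechanismInfo(
        rate_uni_uni, ("A", "P"), ("vmaxf", "Ka", "Kp", "keq")),
    "mwc_idh": MechanismInfo(
        rate_mwc_idh_nad, ("A", "B", "P", "Q"),
        ("vmaxf", "Ka", "Kb", "Kp", "Kq", "keq", "L", "n",
         "Ki_NADH_vs_Iso")),
    "bi_bi_inhib": MechanismInfo(
        rate_idh_nadp, ("A", "B", "P", "Q", "GSH", "NAD"),
        ("vmaxf", "Ka", "Kb", "Kp", "Kq", "keq", "Ki_GSH", "Ki_NAD")),
    "ter_ter": MechanismInfo(
        rate_ter_ter, ("A", "B", "C", "P", "Q", "R"),
        ("vmaxf", "Ka", "Kb", "Kc", "Kp", "Kq", "Kr", "keq")),
    "bi_bi": MechanismInfo(
        rate_bi_bi, ("A", "B", "P", "Q"),
        ("vmaxf", "Ka", "Kb", "Kp", "Kq", "keq")),
    "uni_uni_2V": MechanismInfo(
        rate_uni_uni_2V, ("A", "P"),
        ("vmaxf", "vmaxr", "Ka", "Kp")),
    "bi_bi_2V": MechanismInfo(
        rate_bi_bi_2V, ("A", "B", "P", "Q"),
        ("vmaxf", "vmaxr", "Ka", "Kb", "Kp", "Kq")),
    "gdh_mwc": MechanismInfo(
        rate_gdh, ("A", "B", "P", "Q", "R", "GTP", "ADP"),
        ("vmaxf", "vmaxr", "Ka", "Kb", "Kp", "Kq", "Kr", "L", "n",
         "Ki_GTP", "Ka_ADP")),
    "gr_bi_ter": MechanismInfo(
        rate_gr, ("A", "B", "P", "Q"),
        ("vmaxf", "Ka", "Kb", "Kp", "Kq", "Kr", "keq")),
    "constant_flux": MechanismInfo(
        rate_constant_flux, ("S",), ("vmaxf",), reversible=False),
}


def evaluate(p: KineticParameterSet, concentrations: dict[str, float]) -> float:
    """Evaluate the rate law of ``p`` at role-keyed ``concentrations``."""
    info = MECHANISMS[p.mechanism]
    args = [concentrations[r] for r in info.roles]
    return info.fn(p, *args)
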