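"""Post-model analyses: oxygen-rate/flux stoichiometry and in-silico
activity titrations of the NADH-consumption reaction (complex I analogue)
and succinate dehydrogenase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_assembly import KC_FLUX_REACTION, ReactionNetwork
from .steady_state import SteadyStateError, solve_steady_state

__all__ = [
    "TitrationCurve",
    "kc_flux_from_o2",
    "count_redox_per_turn",
    "titrate_activity",
    "flux_ic50",
    "default_titration_factors",
]


def default_titration_factors(n: int = 40, floor: float = 0.01) -> np.ndarray:
    """Log-spaced activity factors descending from 1 to ``floor``."""
    return np.logspace(0.0, np.log10(floor), n)


@dataclass
class TitrationCurve:
    """Flux response to scaling one reaction's activity below 1."""

    reaction: str
    factors: np.ndarray
    kc_flux: np.ndarray           # NaN where the re-solve failed
    normalized: np.ndarray        # J / J0

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("titration factors must lie in (0, 1]")

    @property
    def flux_ic50(self) -> float | None:
        return flux_ic50(self)


def kc_flux_from_o2(state3_rate: float, nadh_per_turn: int = 4,
                    fadh2_per_turn: int = 1) -> float:
    """Convert a state-3 O2-consumption rate into a Krebs-cycle flux.

    Each reducing equivalent consumes half an O2 molecule, so one cycle
    turn consumes ``(nadh + fadh2) / 2`` O2 — 2.5 for pyruvate/malate
    (4 NADH + 1 FADH2).
    """
    return state3_rate / (0.5 * (nadh_per_turn + fadh2_per_turn))


def count_redox_per_turn(net: ReactionNetwork,
                         substrate_condition: str = "Pyr/Mal"
                         ) -> tuple[int, int]:
    """Count NADH-producing and CoQ-reducing reactions of the cycle path.

    Only the pyruvate/malate condition is modelled; NADH producers are the
    reactions whose stoichiometry releases NADH, CoQ reducers those binding
    CoQ as a substrate.
    """
    if substrate_condition != "Pyr/Mal":
        raise ValueError(
            f"unsupported substrate condition {substrate_condition!r}")
    nadh = sum(1 for r in net.reactions
               if r.stoichiometry.get("NADH", 0) > 0)
    fadh2 = sum(1 for r in net.reactions
                if r.bindings.get("B") == "CoQ")
    return nadh, fadh2


def titrate_activity(net: ReactionNetwork, reaction: str,
                     factors: np.ndarray | None = None,
                     ref_flux: str = KC_FLUX_REACTION) -> TitrationCurve:
    """Steady-state flux response to scaling one reaction's activity.

    Factors must descend from 1; each point re-solves the steady state,
    warm-started from the previous point.  Non-convergent points are kept
    as NaN and excluded from IC50 interpolation.
    """
    if factors is None:
        factors = default_titration_factors()
    factors = np.asarray(factors, dtype=float)
    if factors[0] != 1.0 or np.any(np.diff(factors) >= 0):
        raise ValueError("factors must start at 1 and strictly descend")

    base_activity = net.reaction(reaction).activity
    work = net.copy()
    x0 = work.initial_state()
    fluxes = np.full(factors.size, np.nan)
    for i, f in enumerate(factors):
        work.reaction(reaction).activity = base_activity * f
        work._invalidate()
        try:
            ss = solve_steady_state(work, x0=x0,
                                    newton_first=(i > 0))
        except SteadyStateError:
            continue
        if ss.converged:
            fluxes[i] = ss.fluxes[ref_flux]
            x0 = ss.x
    j0 = fluxes[0]
    return TitrationCurve(reaction=reaction, factors=factors,
                          kc_flux=fluxes, normalized=fluxes / j0)


def flux_ic50(curve: TitrationCurve) -> float | None:
    """Activity factor halving the reference flux, by log-linear
    interpolation; ``None`` when the curve never crosses 0.5."""
    ok = np.isfinite(curve.normalized)
    f = curve.factors[ok]
    y = curve.normalized[ok]
    for i in range(1, f.size):
        y0, y1 = y[i - 1], y[i]
        if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1:
            t = (0.5 - y0) / (y1 - y0)
            return float(np.exp(np.log(f[i - 1])
                                + t * (np.log(f[i]) - np.log(f[i - 1]))))
    return None
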