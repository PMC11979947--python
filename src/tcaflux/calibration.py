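"""Least-squares calibration of the free activities.

The measured Vmax/Km constants are data and are never fitted; the free
parameters are the adjusted activities and boundary fluxes (transporters,
succinyl-CoA synthetase, NADH consumption, GSH oxidation, ...) that the
models require to attain the measured metabolite concentrations and
Krebs-cycle flux.  Fitting happens in log-parameter space with bounded
multi-start least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model_assembly import ReactionNetwork
from .steady_state import SteadyStateError, solve_steady_state
from .synthetic_data import KC_FLUX_NAME, ObservationSet

__all__ = [
    "FreeParameter",
    "CalibrationSpec",
    "CalibrationResult",
    "CalibrationError",
    "residuals",
    "calibrate",
    "default_free_parameters",
]

PENALTY_RESIDUAL = 1e3


class CalibrationError(RuntimeError):
    pass


@dataclass
class FreeParameter:
    key: str          # override key understood by ReactionNetwork.set_value
    lo: float
    hi: float
    init: float

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.init <= self.hi):
            raise ValueError(
                f"{self.key}: require 0 < lo <= init <= hi "
                f"({self.lo}, {self.init}, {self.hi})")


@dataclass
class CalibrationSpec:
    """Free parameters, targets and weighting of one calibration run."""

    free_params: list[FreeParameter]
    targets: ObservationSet
    weights: dict[str, float] = field(default_factory=dict)
    include_ranges: bool = True


@dataclass
class CalibrationResult:
    values: dict[str, float]
    loss: float
    residuals: dict[str, float]
    converged: bool
    n_evaluations: int
    loss_history: list[float]
    identifiability: dict[str, float]
    message: str = ""


def _target_items(spec_targets: ObservationSet, include_ranges: bool):
    for name, obs in spec_targets.all_observations().items():
        if obs.kind == "range" and not include_ranges:
            continue
        yield name, obs


def residuals(net: ReactionNetwork, targets: ObservationSet,
              weights: dict[str, float] | None = None,
              include_ranges: bool = True,
              x0: np.ndarray | None = None,
              t_max: float = 2e4) -> dict[str, float]:
    """Weighted relative residuals of the steady state against targets.

    Point targets contribute ``w * (model - obs) / obs`` with default weight
    ``obs / sd`` (i.e. residuals in SD units) when an SD is available,
    otherwise 1.  Range targets contribute zero inside the interval and the
    relative excess beyond the violated bound outside.  A non-convergent
    steady state yields a flat penalty vector.
    """
    weights = weights or {}
    try:
        ss = solve_steady_state(net, x0=x0, newton_first=x0 is not None,
                                t_max=t_max)
        failed = not ss.converged
    except SteadyStateError:
        ss, failed = None, True

    out: dict[str, float] = {}
    for name, obs in _target_items(targets, include_ranges):
        if failed:
            out[name] = PENALTY_RESIDUAL
            continue
        model = (ss.kc_flux if name == KC_FLUX_NAME
                 else ss.concentrations[name])
        if obs.kind == "point":
            rel = (model - obs.mean) / obs.mean if obs.mean else model
            w = weights.get(name)
            if w is None:
                w = obs.mean / obs.sd if (obs.sd or 0) > 0 else 1.0
            out[name] = w * rel
        else:
            lo, hi = obs.lo, obs.hi
            scale = 0.5 * (lo + hi) or 1.0
            if model < lo:
                out[name] = weights.get(name, 1.0) * (model - lo) / scale
            elif model > hi:
                out[name] = weights.get(name, 1.0) * (model - hi) / scale
            else:
                out[name] = 0.0
    return out


def calibrate(net: ReactionNetwork, spec: CalibrationSpec, seed: int = 0,
              n_starts: int = 3, max_nfev: int = 60,
              xtol: float = 1e-10, ftol: float = 1e-10) -> CalibrationResult:
    """Bounded multi-start least squares over the free parameters.

    Deterministic for a given ``seed``.  Returns the best fit found; the
    input network is updated in place with the fitted values.
    """
    names = list(dict.fromkeys(
        name for name, _ in _target_items(spec.targets, spec.include_ranges)))
    if not spec.free_params:
        res = residuals(net, spec.targets, spec.weights,
                        spec.include_ranges)
        loss = float(sum(r * r for r in res.values()))
        return CalibrationResult(values={}, loss=loss, residuals=res,
                                 converged=True, n_evaluations=1,
                                 loss_history=[loss], identifiability={},
                                 message="no free parameters")
    if len(spec.free_params) > len(names):
        import warnings
        warnings.warn("more free parameters than targets; fit may be "
                      "under-determined", stacklevel=2)

    keys = [fp.key for fp in spec.free_params]
    lo = np.log([fp.lo for fp in spec.free_params])
    hi = np.log([fp.hi for fp in spec.free_params])
    init = np.log([fp.init for fp in spec.free_params])

    warm_x0 = {"x": net.initial_state()}
    history: list[float] = []
    n_eval = {"count": 0}

    def vector(theta: np.ndarray) -> np.ndarray:
        n_eval["count"] += 1
        for key, value in zip(keys, np.exp(theta)):
            net.set_value(key, value)
        res = residuals(net, spec.targets, spec.weights,
                        spec.include_ranges, x0=warm_x0["x"])
        vec = np.array([res[n] for n in names])
        cost = float(vec @ vec)
        history.append(min(cost, history[-1]) if history else cost)
        if cost < 4 * len(names) * PENALTY_RESIDUAL ** 2:
            try:
                ss = solve_steady_state(net, x0=warm_x0["x"],
                                        newton_first=True, t_max=2e4)
                if ss.converged:
                    warm_x0["x"] = ss.x
            except SteadyStateError:
                pass
        return vec

    rng = np.random.default_rng(seed)
    starts = [init]
    for _ in range(n_starts - 1):
        starts.append(np.clip(init + rng.normal(0.0, 0.3, size=init.size),
                              lo, hi))

    best = None
    failures = []
    for start in starts:
        try:
            fit = least_squares(vector, start, bounds=(lo, hi),
                                method="trf", max_nfev=max_nfev,
                                xtol=xtol, ftol=ftol)
        except Exception as exc:  # noqa: BLE001 - collected into the report
            failures.append(str(exc))
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise CalibrationError(
            "all calibration starts failed: " + "; ".join(failures))

    values = dict(zip(keys, np.exp(best.x)))
    for key, value in values.items():
        net.set_value(key, value)
    final = residuals(net, spec.targets, spec.weights, spec.include_ranges,
                      x0=warm_x0["x"])
    loss = float(sum(r * r for r in final.values()))
    jtj = best.jac.T @ best.jac
    identifiability = {k: float(jtj[i, i]) for i, k in enumerate(keys)}
    return CalibrationResult(
        values=values, loss=loss, residuals=final,
        converged=bool(best.success or loss < PENALTY_RESIDUAL),
        n_evaluations=n_eval["count"], loss_history=history,
        identifiability=identifiability, message=best.message)


# ---------------------------------------------------------------------------
# default free-parameter sets
# ---------------------------------------------------------------------------

#: Activities treated as free (adjusted) in each tissue.  Bounds are wide
#: multiplicative windows around the shipped initial values, except where
#: the source constrains them (aconitase and liver NAD-IDH were adjusted
#: only within their measured ranges; heart PDH carries a fixed 2x
#: adjustment and is not free).
_FREE_KEYS = {
    "HepM": ["PYRT.Vmaxf", "SCS.Vmaxf", "MAL_SUC.Vmaxf", "MAL_ISO.Vmaxf",
             "MAL_OXO.Vmaxf", "NADH_CONS.Vmaxf", "GSH_OX.Vmaxf",
             "GR.Vmaxf", "PDH.Vmaxf", "OGDH.Vmaxf"],
    "RLM": ["PYRT.Vmaxf", "SCS.Vmaxf", "MAL_SUC.Vmaxf", "MAL_ISO.Vmaxf",
            "NADH_CONS.Vmaxf", "GSH_OX.Vmaxf", "GR.Vmaxf", "PDH.Vmaxf",
            "OGDH.Vmaxf", "ACO.Vmaxf", "IDH_NAD.Vmaxf"],
    "RHM": ["PYRT.Vmaxf", "SCS.Vmaxf", "MAL_SUC.Vmaxf", "MAL_ISO.Vmaxf",
            "MAL_OXO.Vmaxf", "NADH_CONS.Vmaxf", "GSH_OX.Vmaxf",
            "GR.Vmaxf"],
}

_TIGHT_BOUNDS = {
    # liver NAD-IDH was adjusted only within its measured range
    ("RLM", "IDH_NAD.Vmaxf"): (9.0, 17.0),
}


def default_free_parameters(net: ReactionNetwork,
                            span: float = 4.0) -> list[FreeParameter]:
    """The tissue's standard free-activity list, centred on current values."""
    out = []
    for key in _FREE_KEYS[net.tissue]:
        init = net.get_value(key)
        lo, hi = _TIGHT_BOUNDS.get((net.tissue, key),
                                   (init / span, init * span))
        init = min(max(init, lo), hi)
        out.append(FreeParameter(key=key, lo=lo, hi=hi, init=init))
    return out
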