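"""Metabolic control analysis at a solved steady state.

Two routes are implemented.  The primary one perturbs each reaction's
activity by a small factor, re-solves the steady state and forms scaled
finite-difference control coefficients; it is robust in the presence of
conserved moieties.  The matrix route (elasticities + link matrix) serves
as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_assembly import KC_FLUX_REACTION, ReactionNetwork
from .rate_laws import MECHANISMS
from .steady_state import (SteadyStateError, SteadyStateResult, _Reduction,
                           solve_steady_state)

__all__ = [
    "ControlAnalysisResult",
    "scaled_elasticities",
    "flux_control_coefficients",
    "concentration_control_coefficients",
    "control_analysis",
    "check_summation",
    "control_matrices",
]

DEFAULT_DELTA = 1e-3
DEFAULT_SPECIES = "NADH"


@dataclass
class ControlAnalysisResult:
    """Control coefficients for one reference flux and one species."""

    elasticities: pd.DataFrame
    fcc: dict[str, float]
    ccc: dict[str, float]
    ref_flux: str
    species: str
    method: str
    unavailable: list[str] = field(default_factory=list)

    @property
    def fcc_sum(self) -> float:
        return float(np.nansum(list(self.fcc.values())))

    @property
    def ccc_sum(self) -> float:
        return float(np.nansum(list(self.ccc.values())))


# ---------------------------------------------------------------------------
# elasticities
# ---------------------------------------------------------------------------

def _dv_dx(net: ReactionNetwork, x: np.ndarray,
           rel_step: float = 1e-5) -> np.ndarray:
    """Unscaled derivative matrix dv/dx (reactions x variable species)."""
    var = net.variable_ids
    bound = [set(r.bindings.values()) for r in net.reactions]
    out = np.zeros((len(net.reactions), len(var)))
    for i, sp in enumerate(var):
        s = x[i]
        h = rel_step * s if s > 0 else 1e-8
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(s - h, 0.0)
        vp, vm = net.rates(xp), net.rates(xm)
        col = (vp - vm) / (xp[i] - xm[i])
        for j in range(len(net.reactions)):
            out[j, i] = col[j] if sp in bound[j] else 0.0
    return out


def scaled_elasticities(net: ReactionNetwork,
                        ss: SteadyStateResult) -> pd.DataFrame:
    """Scaled elasticity coefficients ``(s/v) dv/ds`` at the steady state.

    Entries for species that do not appear in a reaction's rate law are
    exactly zero; rows with near-zero flux are left unscaled-safe (zero).
    """
    x = ss.x
    E = _dv_dx(net, x)
    v = net.rates(x)
    out = np.zeros_like(E)
    for j, vj in enumerate(v):
        if abs(vj) > 1e-12:
            out[j, :] = E[j, :] * x / vj
    return pd.DataFrame(out, index=net.reaction_ids,
                        columns=net.variable_ids)


# ---------------------------------------------------------------------------
# finite-difference control coefficients
# ---------------------------------------------------------------------------

def _perturbed_solutions(net: ReactionNetwork, ss: SteadyStateResult,
                         delta: float):
    """Yield (reaction_id, up-solution, down-solution); failed re-solves
    yield ``None`` entries."""
    for rxn in net.reactions:
        pair = []
        for sign in (+1.0, -1.0):
            pert = net.copy()
            pert.reaction(rxn.id).activity = rxn.activity * (1 + sign * delta)
            try:
                sol = solve_steady_state(pert, x0=ss.x, newton_first=True)
            except SteadyStateError:
                sol = None
            if sol is not None and not sol.converged:
                sol = None
            pair.append(sol)
        yield rxn.id, pair[0], pair[1]


def flux_control_coefficients(net: ReactionNetwork, ss: SteadyStateResult,
                              ref_flux: str = KC_FLUX_REACTION,
                              delta: float = DEFAULT_DELTA
                              ) -> dict[str, float]:
    """Scaled flux control coefficients ``(a/J) dJ/da`` on ``ref_flux``.

    Each reaction's activity (its limiting rates, or the flux constant of
    the constant-flux boundary reactions) is perturbed by ``±delta`` and the
    steady state re-solved.  A non-convergent perturbed solve yields NaN,
    never a silent zero.
    """
    if not ss.converged:
        raise ValueError("control analysis requires a converged steady state")
    J0 = ss.fluxes[ref_flux]
    out: dict[str, float] = {}
    for rid, up, down in _perturbed_solutions(net, ss, delta):
        if up is None or down is None:
            out[rid] = float("nan")
            continue
        out[rid] = (up.fluxes[ref_flux] - down.fluxes[ref_flux]) / (
            2.0 * delta * J0)
    return out


def concentration_control_coefficients(net: ReactionNetwork,
                                       ss: SteadyStateResult,
                                       species: str = DEFAULT_SPECIES,
                                       delta: float = DEFAULT_DELTA
                                       ) -> dict[str, float]:
    """Scaled concentration control coefficients ``(a/s) ds/da``."""
    if not ss.converged:
        raise ValueError("control analysis requires a converged steady state")
    s0 = ss.concentrations[species]
    out: dict[str, float] = {}
    for rid, up, down in _perturbed_solutions(net, ss, delta):
        if up is None or down is None:
            out[rid] = float("nan")
            continue
        out[rid] = (up.concentrations[species]
                    - down.concentrations[species]) / (2.0 * delta * s0)
    return out


def control_analysis(net: ReactionNetwork, ss: SteadyStateResult,
                     ref_flux: str = KC_FLUX_REACTION,
                     species: str = DEFAULT_SPECIES,
                     delta: float = DEFAULT_DELTA) -> ControlAnalysisResult:
    """Full control analysis; FCC and CCC share one set of perturbed solves."""
    if not ss.converged:
        raise ValueError("control analysis requires a converged steady state")
    J0 = ss.fluxes[ref_flux]
    s0 = ss.concentrations[species]
    fcc: dict[str, float] = {}
    ccc: dict[str, float] = {}
    unavailable: list[str] = []
    for rid, up, down in _perturbed_solutions(net, ss, delta):
        if up is None or down is None:
            fcc[rid] = ccc[rid] = float("nan")
            unavailable.append(rid)
            continue
        fcc[rid] = (up.fluxes[ref_flux] - down.fluxes[ref_flux]) / (
            2.0 * delta * J0)
        ccc[rid] = (up.concentrations[species]
                    - down.concentrations[species]) / (2.0 * delta * s0)
    return ControlAnalysisResult(
        elasticities=scaled_elasticities(net, ss),
        fcc=fcc, ccc=ccc, ref_flux=ref_flux, species=species,
        method="finite_difference", unavailable=unavailable)


def check_summation(result: ControlAnalysisResult,
                    tol: float = 1e-3) -> dict:
    """Summation-theorem diagnostics: sum of FCC must be 1, of CCC 0."""
    fcc_sum, ccc_sum = result.fcc_sum, result.ccc_sum
    diag = {
        "fcc_sum": fcc_sum,
        "ccc_sum": ccc_sum,
        "fcc_pass": bool(abs(fcc_sum - 1.0) <= tol),
        "ccc_pass": bool(abs(ccc_sum) <= tol),
        "unavailable": list(result.unavailable),
    }
    if not (diag["fcc_pass"] and diag["ccc_pass"]):
        top = sorted(result.fcc.items(),
                     key=lambda kv: -abs(kv[1]) if np.isfinite(kv[1]) else 0)
        diag["largest_contributors"] = [k for k, _ in top[:5]]
    return diag


# ---------------------------------------------------------------------------
# matrix method (cross-check)
# ---------------------------------------------------------------------------

def control_matrices(net: ReactionNetwork, ss: SteadyStateResult,
                     ref_flux: str = KC_FLUX_REACTION,
                     species: str = DEFAULT_SPECIES
                     ) -> ControlAnalysisResult:
    """Control coefficients from elasticities and the link matrix.

    Uses the classical expressions ``C_v = I - E L M^-1 N_R`` and
    ``C_x = -L M^-1 N_R`` with ``M = N_R E L`` on the moiety-reduced
    system, then scales to enzyme-activity coefficients.
    """
    x = ss.x
    totals = net.moiety_totals(x)
    S = net.stoichiometric_matrix()
    if net.moieties:
        red = _Reduction(net, totals)
        ind, dep = red.ind, red.dep
        nvar = S.shape[0]
        L = np.zeros((nvar, ind.size))
        L[ind, np.arange(ind.size)] = 1.0
        L[dep, :] = -np.linalg.solve(red.G_dep, red.G_ind)
        N_R = S[ind, :]
    else:
        L = np.eye(S.shape[0])
        N_R = S
    E = _dv_dx(net, x)
    M = N_R @ E @ L
    Minv = np.linalg.inv(M)
    C_v = np.eye(len(net.reactions)) - E @ L @ Minv @ N_R
    C_x = -L @ Minv @ N_R

    v = net.rates(x)
    ref = net.reaction_ids.index(ref_flux)
    sp = net.variable_ids.index(species)
    J0, s0 = v[ref], x[sp]
    fcc = {rid: float(C_v[ref, j] * v[j] / J0)
           for j, rid in enumerate(net.reaction_ids)}
    ccc = {rid: float(C_x[sp, j] * v[j] / s0)
           for j, rid in enumerate(net.reaction_ids)}
    return ControlAnalysisResult(
        elasticities=scaled_elasticities(net, ss),
        fcc=fcc, ccc=ccc, ref_flux=ref_flux, species=species,
        method="matrix")
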