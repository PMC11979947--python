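"""Steady-state solution of the reaction networks.

The ODE system ``dx/dt = S v(x)`` is rank-deficient because of the
conserved cofactor pools, so the solver integrates the full system with a
stiff method and then polishes the solution with a damped Newton iteration
on the reduced system (one species per conserved moiety eliminated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_assembly import KC_FLUX_REACTION, ReactionNetwork

__all__ = [
    "SteadyStateResult",
    "SteadyStateError",
    "flux_profile",
    "integrate_to_steady_state",
    "newton_refine",
    "solve_steady_state",
    "perturbed_initial_states",
]

DEFAULT_TOL = 1e-9       # mM/min, max |dx/dt|
DEFAULT_T_MAX = 1e6      # min
NEG_CONC_TOL = -1e-9     # mM, tolerated integration undershoot


class SteadyStateError(RuntimeError):
    pass


@dataclass
class SteadyStateResult:
    """Converged state of one network.

    ``concentrations`` are in mM, ``fluxes`` in nmol·min⁻¹·mg⁻¹ and
    ``kc_flux`` is the flux through the reaction designated as the
    Krebs-cycle flux (malate dehydrogenase).
    """

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    kc_flux: float
    residual_norm: float
    converged: bool
    moiety_drift: float
    x: np.ndarray = field(repr=False, default=None)
    jacobian_eigenvalues: np.ndarray | None = field(repr=False, default=None)

    @property
    def stable(self) -> bool | None:
        if self.jacobian_eigenvalues is None:
            return None
        return bool(np.all(self.jacobian_eigenvalues.real < 1e-9))


# ---------------------------------------------------------------------------
# moiety elimination
# ---------------------------------------------------------------------------

class _Reduction:
    """Split the variable species into independent and dependent sets so the
    dependent ones follow algebraically from the conserved totals."""

    def __init__(self, net: ReactionNetwork, totals: np.ndarray):
        G = net.moiety_matrix()
        self.G = G
        self.totals = np.asarray(totals, dtype=float)
        n = G.shape[1]
        dep: list[int] = []
        work = G.copy()
        for i in range(work.shape[0]):
            # choose as dependent the last not-yet-used species in each
            # conservation row (picks the reduced cofactor by convention)
            candidates = [j for j in range(n - 1, -1, -1)
                          if abs(work[i, j]) > 1e-12 and j not in dep]
            if not candidates:
                raise SteadyStateError("degenerate moiety set")
            dep.append(candidates[0])
        self.dep = np.array(sorted(dep), dtype=int)
        self.ind = np.array([j for j in range(n) if j not in dep], dtype=int)
        self.G_dep = G[:, self.dep]
        self.G_ind = G[:, self.ind]

    def full_state(self, y: np.ndarray) -> np.ndarray:
        x = np.empty(self.G.shape[1])
        x[self.ind] = y
        x[self.dep] = np.linalg.solve(self.G_dep,
                                      self.totals - self.G_ind @ y)
        return x

    def reduce(self, x: np.ndarray) -> np.ndarray:
        return x[self.ind]


def _residual_norm(net: ReactionNetwork, x: np.ndarray) -> float:
    return float(np.max(np.abs(net.rhs(x))))


def _moiety_drift(net: ReactionNetwork, x: np.ndarray,
                  totals: np.ndarray) -> float:
    if not net.moieties:
        return 0.0
    return float(np.max(np.abs(net.moiety_matrix() @ x - totals)))


def _result(net: ReactionNetwork, x: np.ndarray, totals: np.ndarray,
            tol: float, eigvals: np.ndarray | None = None
            ) -> SteadyStateResult:
    x = np.clip(x, 0.0, None)
    v = net.rates(x)
    res = _residual_norm(net, x)
    return SteadyStateResult(
        concentrations=dict(zip(net.variable_ids, x)),
        fluxes=dict(zip(net.reaction_ids, v)),
        kc_flux=float(v[net.reaction_ids.index(KC_FLUX_REACTION)])
        if KC_FLUX_REACTION in net.reaction_ids else float("nan"),
        residual_norm=res,
        converged=res < tol,
        moiety_drift=_moiety_drift(net, x, totals),
        x=x,
        jacobian_eigenvalues=eigvals,
    )


def flux_profile(net: ReactionNetwork, x: np.ndarray) -> dict[str, float]:
    """Evaluate every rate law (with activity scaling) at state ``x``."""
    return dict(zip(net.reaction_ids, net.rates(np.asarray(x, dtype=float))))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_to_steady_state(net: ReactionNetwork,
                              x0: np.ndarray | None = None,
                              t_max: float = DEFAULT_T_MAX,
                              tol: float = DEFAULT_TOL) -> SteadyStateResult:
    """Integrate ``dx/dt = S v(x)`` with a stiff method until relaxed.

    Integration proceeds in geometrically growing time chunks and stops as
    soon as ``max |dx/dt| < tol``; the ``converged`` flag reports whether
    that happened before ``t_max``.
    """
    if x0 is None:
        x0 = net.initial_state()
    x = np.asarray(x0, dtype=float).copy()
    totals = net.moiety_totals(x)
    S = net.stoichiometric_matrix()

    def rhs(_t, state):
        return S @ net.rates(np.clip(state, 0.0, None))

    t, chunk = 0.0, 10.0
    while t < t_max:
        t_end = min(t + chunk, t_max)
        sol = solve_ivp(rhs, (t, t_end), x, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            sol = solve_ivp(rhs, (t, t_end), x, method="BDF",
                            rtol=1e-7, atol=1e-9)
            if not sol.success:
                raise SteadyStateError(
                    f"{net.tissue}: integration failed at t={t:g}: "
                    f"{sol.message}")
        x = sol.y[:, -1]
        if float(np.min(x)) < NEG_CONC_TOL:
            raise SteadyStateError(
                f"{net.tissue}: concentration went negative during "
                f"integration (min {np.min(x):.3e} mM)")
        x = np.clip(x, 0.0, None)
        t = t_end
        chunk *= 10.0
        if _residual_norm(net, x) < tol:
            break
    return _result(net, x, totals, tol)


# ---------------------------------------------------------------------------
# Newton refinement
# ---------------------------------------------------------------------------

def newton_refine(net: ReactionNetwork, x: np.ndarray,
                  tol: float = 1e-12, max_iter: int = 60,
                  ss_tol: float = DEFAULT_TOL) -> SteadyStateResult:
    """Damped Newton polish of a near-steady state.

    The conserved moieties are eliminated first so the Jacobian of the
    reduced system is non-singular; the returned residual never exceeds the
    entry residual, and the eigenvalues of the reduced Jacobian are attached
    for stability diagnostics.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, None)
    totals = net.moiety_totals(x)
    red = _Reduction(net, totals)
    S = net.stoichiometric_matrix()

    def f(y):
        full = red.full_state(y)
        return (S @ net.rates(np.clip(full, 0.0, None)))[red.ind]

    def jac(y):
        base = f(y)
        J = np.empty((y.size, y.size))
        for j in range(y.size):
            step = 1e-7 * max(abs(y[j]), 1e-6)
            yp = y.copy()
            yp[j] += step
            J[:, j] = (f(yp) - base) / step
        return J

    y = red.reduce(x)
    fy = f(y)
    best_norm = np.linalg.norm(fy, ord=np.inf)
    for _ in range(max_iter):
        if best_norm < tol:
            break
        J = jac(y)
        try:
            delta = np.linalg.solve(J, -fy)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(J, -fy, rcond=None)[0]
        lam, improved = 1.0, False
        for _ in range(30):
            y_new = y + lam * delta
            x_new = red.full_state(y_new)
            if np.min(x_new) < NEG_CONC_TOL * 1e3 - 1e-12:
                lam *= 0.5
                continue
            f_new = f(y_new)
            norm_new = np.linalg.norm(f_new, ord=np.inf)
            if norm_new < best_norm:
                y, fy, best_norm, improved = y_new, f_new, norm_new, True
                break
            lam *= 0.5
        if not improved:
            break

    x_final = np.clip(red.full_state(y), 0.0, None)
    J = jac(red.reduce(x_final))
    eigvals = np.linalg.eigvals(J)
    return _result(net, x_final, totals, ss_tol, eigvals=eigvals)


def solve_steady_state(net: ReactionNetwork,
                       x0: np.ndarray | None = None,
                       t_max: float = DEFAULT_T_MAX,
                       tol: float = DEFAULT_TOL,
                       newton_first: bool = False) -> SteadyStateResult:
    """Integrate to the steady state and Newton-polish it.

    With ``newton_first=True`` (used for warm starts, e.g. re-solving after
    a small parameter perturbation) the Newton step is attempted directly
    and integration only runs as a fallback.
    """
    if x0 is None:
        x0 = net.initial_state()
    if newton_first:
        try:
            result = newton_refine(net, x0, ss_tol=tol)
            if result.converged and result.stable:
                return result
        except (SteadyStateError, np.linalg.LinAlgError):
            pass
    result = integrate_to_steady_state(net, x0=x0, t_max=t_max, tol=tol)
    refined = newton_refine(net, result.x, ss_tol=tol)
    if refined.residual_norm <= result.residual_norm:
        return refined
    return result


def perturbed_initial_states(net: ReactionNetwork, n: int, seed: int,
                             scale: float = 2.0) -> list[np.ndarray]:
    """Feasible alternative initial states with identical moiety totals.

    Non-conserved species are scaled by log-uniform factors in
    ``[1/scale, scale]``; species inside a conserved pool are redistributed
    randomly while keeping the configured total.
    """
    rng = np.random.default_rng(seed)
    x0 = net.initial_state()
    var = net.variable_ids
    in_moiety = {sp for m in net.moieties for sp in m.coefficients}
    states = []
    for _ in range(n):
        x = x0 * np.exp(rng.uniform(np.log(1 / scale), np.log(scale),
                                    size=x0.size))
        for m in net.moieties:
            ids = list(m.coefficients)
            w = rng.dirichlet(np.ones(len(ids)))
            for sp, frac in zip(ids, w):
                x[var.index(sp)] = frac * m.total / m.coefficients[sp]
        for i, sp in enumerate(var):
            if sp not in in_moiety:
                x[i] = max(x[i], 1e-6)
        states.append(x)
    return states
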