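"""Synthetic observation sets with the replicate structure of the measured
data: per-metabolite intramitochondrial concentrations (mean ± SD over n
replicates) and one Krebs-cycle flux, under multiplicative log-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_assembly import ReactionNetwork, build_model
from .steady_state import solve_steady_state

__all__ = [
    "Observation",
    "ObservationSet",
    "generate_observations",
    "table2_fixture",
    "recovery_experiment",
]

KC_FLUX_NAME = "KC_flux"


@dataclass
class Observation:
    """One observed quantity: a replicate mean or a literature range."""

    name: str
    mean: float | None = None
    sd: float | None = None
    n: int = 1
    kind: str = "point"  # "point" | "range"
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "range"):
            raise ValueError(f"{self.name}: bad observation kind {self.kind}")
        if self.kind == "point":
            if self.mean is None or self.mean < 0:
                raise ValueError(f"{self.name}: point mean must be >= 0")
            if self.sd is not None and self.sd < 0:
                raise ValueError(f"{self.name}: SD must be >= 0")
        if self.n < 1:
            raise ValueError(f"{self.name}: n must be >= 1")


@dataclass
class ObservationSet:
    """Observed metabolite concentrations and Krebs-cycle flux."""

    condition: str
    provenance: str
    metabolites: dict[str, Observation] = field(default_factory=dict)
    kc_flux: Observation | None = None

    def all_observations(self) -> dict[str, Observation]:
        out = dict(self.metabolites)
        if self.kc_flux is not None:
            out[KC_FLUX_NAME] = self.kc_flux
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, obs in self.all_observations().items():
            rows.append({"name": name, "kind": obs.kind, "mean": obs.mean,
                         "sd": obs.sd, "n": obs.n, "lo": obs.lo,
                         "hi": obs.hi})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition: str,
                   provenance: str) -> "ObservationSet":
        obs_set = cls(condition=condition, provenance=provenance)
        for row in frame.itertuples(index=False):
            obs = Observation(
                name=row.name,
                mean=None if pd.isna(row.mean) else float(row.mean),
                sd=None if pd.isna(row.sd) else float(row.sd),
                n=int(row.n),
                kind=str(row.kind),
                lo=None if pd.isna(row.lo) else float(row.lo),
                hi=None if pd.isna(row.hi) else float(row.hi))
            if row.name == KC_FLUX_NAME:
                obs_set.kc_flux = obs
            else:
                obs_set.metabolites[row.name] = obs
        return obs_set


def generate_observations(net: ReactionNetwork, noise_cv: float = 0.25,
                          n_reps: int = 3, seed: int = 0) -> ObservationSet:
    """Sample a synthetic observation set from a ground-truth network.

    The network is solved to steady state, and every variable concentration
    plus the Krebs-cycle flux is observed as the mean of ``n_reps``
    multiplicative log-normal replicates with coefficient of variation
    ``noise_cv`` (mean-preserving parameterization).  Deterministic given
    ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    ss = solve_steady_state(net)
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(noise_cv ** 2)
    sigma = math.sqrt(sigma2)

    def observe(name: str, value: float) -> Observation:
        if noise_cv == 0 or value == 0:
            return Observation(name=name, mean=value, sd=0.0, n=n_reps)
        reps = value * np.exp(rng.normal(-sigma2 / 2.0, sigma, size=n_reps))
        return Observation(name=name, mean=float(np.mean(reps)),
                           sd=float(np.std(reps, ddof=1)) if n_reps > 1
                           else 0.0,
                           n=n_reps)

    obs_set = ObservationSet(condition="Pyr/Mal",
                             provenance=f"SYNTHETIC(seed={seed})")
    for name, value in ss.concentrations.items():
        obs_set.metabolites[name] = observe(name, value)
    obs_set.kc_flux = observe(KC_FLUX_NAME, ss.kc_flux)
    return obs_set


def table2_fixture(tissue: str) -> ObservationSet:
    """The printed in-vivo observation set (Pyr/Mal condition) of a tissue."""
    from .model_assembly import _data_path  # shared fixture directory
    with _data_path("table2.csv").open("r") as fh:
        table = pd.read_csv(fh, comment="#")
    sub = table[table["tissue"] == tissue].drop(columns=["tissue"])
    if sub.empty:
        raise ValueError(f"no observations for tissue {tissue!r}")
    return ObservationSet.from_frame(sub, condition="Pyr/Mal",
                                     provenance="TABLE2")


def recovery_experiment(tissue: str, free_params: list[str],
                        noise_cv: float, n_datasets: int, seed: int,
                        target_names: list[str] | None = None,
                        start_spread: tuple[float, float] = (0.5, 2.0),
                        **calibrate_kwargs) -> pd.DataFrame:
    """Parameter-recovery study on synthetic data from a known truth.

    For each dataset: observations are generated from the ground-truth
    tissue network at ``noise_cv``; the optimizer starts from the truth
    perturbed by log-uniform factors in ``start_spread``; relative recovery
    errors per free parameter are reported (one row per dataset/parameter,
    plus summary columns via :meth:`pandas.DataFrame.groupby` downstream).
    """
    from .calibration import CalibrationSpec, FreeParameter, calibrate

    if n_datasets == 0:
        return pd.DataFrame(columns=["dataset", "parameter", "truth",
                                     "fitted", "rel_error"])
    truth_net = build_model(tissue)
    truth = {k: truth_net.get_value(k) for k in free_params}
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_datasets):
        obs = generate_observations(truth_net, noise_cv=noise_cv, n_reps=5,
                                    seed=int(rng.integers(2 ** 31)))
        if target_names is not None:
            keep = {n: o for n, o in obs.metabolites.items()
                    if n in target_names}
            obs = ObservationSet(condition=obs.condition,
                                 provenance=obs.provenance,
                                 metabolites=keep, kc_flux=obs.kc_flux)
        start_factors = np.exp(rng.uniform(np.log(start_spread[0]),
                                           np.log(start_spread[1]),
                                           size=len(free_params)))
        free = [FreeParameter(key=k,
                              lo=truth[k] / 20.0, hi=truth[k] * 20.0,
                              init=truth[k] * f)
                for k, f in zip(free_params, start_factors)]
        net = truth_net.copy()
        for fp in free:
            net.set_value(fp.key, fp.init)
        spec = CalibrationSpec(free_params=free, targets=obs)
        result = calibrate(net, spec, seed=int(rng.integers(2 ** 31)),
                           **calibrate_kwargs)
        for k in free_params:
            fitted = result.values[k]
            rows.append({"dataset": d, "parameter": k, "truth": truth[k],
                         "fitted": fitted,
                         "rel_error": abs(fitted - truth[k]) / truth[k]})
    return pd.DataFrame(rows)
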