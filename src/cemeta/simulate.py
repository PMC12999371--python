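"""Synthetic meta-datasets and estimator-comparison simulations.

The generator mirrors the random-effects structure the pooling methods
assume, extended bivariately: study j draws a size :math:`N_j` from a
configurable distribution, then a cost/effect pair

.. math::

   (\\Delta C_j, \\Delta E_j) \\sim
   \\mathrm{BVN}\\!\\left((\\mu_C, \\mu_E),\\;
   \\mathrm{SD}_j = \\sqrt{\\tau^2 + \\mathrm{within}^2 / N_j},\\;
   \\rho_{CE}\\right),

so each observed difference carries a between-study component (SD tau)
and a within-study sampling component shrinking with study size.  The
reported per-study SEs are the within components
:math:`\\mathrm{within}/\\sqrt{N_j}`.  An optional lognormal cost option
mimics the right-skew of real cost data, and an optional size-effect
correlation lets bigger studies show systematically different effects
(the studies-at-random framing allows it; off by default).

``run_coverage_sim`` repeatedly generates datasets, pools each outcome by
each requested method, and reports bias, empirical SE, mean CI width and
coverage of the true parameter — the standard way to audit the nominal
95% level of the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import MetaDataset, StudyRecord
from .ivw import pool_ivw_fe, pool_ivw_re
from .ratio import pool_ratio, pool_ratio_constant

__all__ = ["SimParams", "SimulationSummary", "generate_meta_dataset", "run_coverage_sim"]

_METHODS = {
    "ratio": lambda ds, outcome, alpha: pool_ratio(ds, outcome, alpha),
    "ratio_constant": lambda ds, outcome, alpha: pool_ratio_constant(ds, outcome, alpha),
    "ivw_fe": lambda ds, outcome, alpha: pool_ivw_fe(
        ds.deltas(outcome), ds.se(outcome), alpha, outcome
    ),
    "ivw_re": lambda ds, outcome, alpha: pool_ivw_re(
        ds.deltas(outcome), ds.se(outcome), alpha, outcome
    ),
}


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Defaults are sized like the bundled wound-intervention data: around
    twenty studies of 25-450 patients, a true cost saving of 2000 (2013
    USD) with between-study SD 4000, a true effectiveness gain of 0.2
    QALY with between-study SD 0.5, moderately negative cost-effect
    correlation (more effective interventions tend to save money), and
    within-study noise of 10 000 USD and 1.5 QALY per sqrt(patient).
    """

    M: int = 20
    n_dist: tuple = ("uniform", 25, 450)  # or ("lognormal", mean_log, sd_log)
    true_delta_c: float = -2000.0
    true_delta_e: float = 0.2
    tau_c: float = 4000.0
    tau_e: float = 0.5
    rho_ce: float = -0.5
    within_sd_c: float = 10_000.0
    within_sd_e: float = 1.5
    n_effect_rho: float = 0.0  # correlation between study size and effect deviation
    lognormal_cost: bool = False  # right-skewed costs instead of normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if not -1.0 <= self.rho_ce <= 1.0:
            raise ValueError(f"rho_ce must be in [-1, 1], got {self.rho_ce}")
        if not -1.0 <= self.n_effect_rho <= 1.0:
            raise ValueError(f"n_effect_rho must be in [-1, 1], got {self.n_effect_rho}")
        if min(self.tau_c, self.tau_e, self.within_sd_c, self.within_sd_e) < 0:
            raise ValueError("tau and within-SD parameters must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "n_dist" in raw:
            raw["n_dist"] = tuple(raw["n_dist"])
        return cls(**raw)


@dataclass(frozen=True)
class SimulationSummary:
    """Per-method/outcome operating characteristics over `reps` replications."""

    table: pd.DataFrame  # columns: method, outcome, bias, empirical_se, mean_ci_width, coverage
    reps: int

    def __post_init__(self) -> None:
        cov = self.table["coverage"]
        if self.reps <= 0 or ((cov < 0) | (cov > 1)).any():
            raise ValueError("invalid summary: reps must be > 0 and coverage within [0, 1]")


def _draw_sizes(params: SimParams, rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """Map standard-normal scores u to study sizes via the size distribution."""
    from scipy import stats

    p = stats.norm.cdf(u)
    kind = params.n_dist[0]
    if kind == "uniform":
        lo, hi = int(params.n_dist[1]), int(params.n_dist[2])
        n = np.floor(lo + p * (hi - lo + 1)).astype(int)
        n = np.clip(n, lo, hi)
    elif kind == "lognormal":
        mu, sd = float(params.n_dist[1]), float(params.n_dist[2])
        n = np.round(np.exp(mu + sd * u)).astype(int)
    else:
        raise ValueError(f"unknown n_dist kind {kind!r}")
    return np.maximum(n, 10)


def generate_meta_dataset(
    params: SimParams, rng: np.random.Generator | None = None
) -> MetaDataset:
    """Draw one synthetic meta-dataset (deterministic given the seed)."""
    rng = rng or np.random.default_rng(params.seed)
    m = params.M

    # latent standard-normal scores for (cost dev, effect dev, size)
    r, rn = params.rho_ce, params.n_effect_rho
    corr = np.array([[1.0, r, 0.0], [r, 1.0, rn], [0.0, rn, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("rho_ce and n_effect_rho give a non-PSD correlation matrix")
    zc, ze, zn = rng.multivariate_normal(np.zeros(3), corr, size=m, method="svd").T

    n = _draw_sizes(params, rng, zn)
    se_c = params.within_sd_c / np.sqrt(n)
    se_e = params.within_sd_e / np.sqrt(n)
    sd_c = np.sqrt(params.tau_c**2 + se_c**2)
    sd_e = np.sqrt(params.tau_e**2 + se_e**2)
    if params.lognormal_cost:
        # lognormal with matched mean/SD, shifted to allow negative true cost
        mu_ln = np.log(sd_c**2) - 0.5 * np.log(2 * sd_c**2)  # => mean sd_c, sd sd_c
        dc = params.true_delta_c + (np.exp(mu_ln + np.sqrt(np.log(2.0)) * zc) - sd_c)
    else:
        dc = params.true_delta_c + sd_c * zc
    de = params.true_delta_e + sd_e * ze

    studies = tuple(
        StudyRecord(
            study_id=f"sim{j + 1:03d}",
            delta_c=float(dc[j]),
            delta_e=float(de[j]),
            n=int(n[j]),
            se_delta_c=float(se_c[j]) if params.within_sd_c > 0 else None,
            se_delta_e=float(se_e[j]) if params.within_sd_e > 0 else None,
        )
        for j in range(m)
    )
    return MetaDataset(studies, cost_label="sim currency", effect_label="sim effect")


def run_coverage_sim(
    params: SimParams,
    reps: int = 2000,
    methods: tuple[str, ...] = ("ratio", "ratio_constant"),
    alpha: float = 0.05,
    seed: int | None = None,
) -> SimulationSummary:
    """Monte-Carlo audit of the pooling estimators.

    One master seed spawns an independent child RNG stream per replicate
    (``SeedSequence.spawn``), so results are reproducible and adding
    methods does not perturb the generated datasets.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful summary")
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}")
        if m.startswith("ivw") and (params.within_sd_c == 0 or params.within_sd_e == 0):
            raise ValueError(
                f"{m} needs within-study SEs; set within_sd_c/within_sd_e > 0"
            )
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    streams = [np.random.default_rng(s) for s in master.spawn(reps)]
    truth = {"cost": params.true_delta_c, "effect": params.true_delta_e}

    rows = {(m, o): {"err": [], "width": [], "cover": 0} for m in methods for o in ("cost", "effect")}
    for rng in streams:
        ds = generate_meta_dataset(params, rng)
        for m in methods:
            for outcome in ("cost", "effect"):
                pd_ = _METHODS[m](ds, outcome, alpha)
                cell = rows[(m, outcome)]
                cell["err"].append(pd_.estimate - truth[outcome])
                cell["width"].append(pd_.ci_upper - pd_.ci_lower)
                cell["cover"] += pd_.ci_lower <= truth[outcome] <= pd_.ci_upper

    records = []
    for (m, outcome), cell in rows.items():
        err = np.asarray(cell["err"])
        records.append(
            {
                "method": m,
                "outcome": outcome,
                "bias": float(err.mean()),
                "empirical_se": float(err.std(ddof=1)),
                "mean_ci_width": float(np.mean(cell["width"])),
                "coverage": cell["cover"] / reps,
            }
        )
    return SimulationSummary(table=pd.DataFrame.from_records(records), reps=reps)
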