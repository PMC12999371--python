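"""Inverse-variance-weighted pooling (scenario 2: per-study SEs known).

Fixed-effect weights are :math:`w_j = 1/\\mathrm{SE}_j^2`.  The
random-effects model adds a between-study component,

.. math:: ES_j = \\mu + u_j + \\sigma_j \\epsilon_j, \\qquad
          u_j \\sim N(0, \\tau^2),\\ \\epsilon_j \\sim N(0, 1),

with the DerSimonian-Laird moment estimator for :math:`\\tau^2` and
starred weights :math:`w_j^* = 1/(\\mathrm{SE}_j^2 + \\tau^2)`.
Heterogeneity is summarised by Cochran's Q and
:math:`I^2 = \\max\\{(Q - df)/Q, 0\\}`.  Intervals use normal quantiles.
Cost and effectiveness are pooled independently (univariately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MetaDataset
from .ratio import PooledDifference

__all__ = [
    "Heterogeneity",
    "REModelSpec",
    "se_from_ci",
    "i_squared",
    "pool_ivw_fe",
    "pool_ivw_re",
    "heterogeneity",
    "pool_ivw",
]


def i_squared(Q: float, M: int) -> float:
    """Inconsistency proportion I^2 = max{(Q - df)/Q, 0} with df = M - 1.

    The share of the observed dispersion Q attributable to between-study
    heterogeneity rather than within-study sampling error.
    """
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    if M < 2:
        raise ValueError("M must be >= 2")
    if Q == 0:
        return 0.0
    return max((Q - (M - 1)) / Q, 0.0)


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q, its degrees of freedom (M-1), the inconsistency
    proportion I^2 in [0, 1), and the DerSimonian-Laird between-study
    variance tau^2 (truncated at 0)."""

    Q: float
    df: int
    I2: float
    tau2: float

    def to_dict(self) -> dict:
        return {"Q": self.Q, "df": self.df, "I2": self.I2, "tau2": self.tau2}


@dataclass(frozen=True)
class REModelSpec:
    """Generating model for one outcome's random-effects structure:
    grand mean, between-study SD tau, and per-study within SEs."""

    true_es: float
    tau: float
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.tau < 0 or any(s < 0 for s in self.sigma):
            raise ValueError("tau and all sigma_j must be nonnegative")

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one vector of observed effect sizes ES_j."""
        sig = np.asarray(self.sigma, dtype=float)
        m = sig.size
        return self.true_es + rng.normal(0.0, self.tau, m) + sig * rng.normal(size=m)


def se_from_ci(
    lower: float,
    upper: float,
    level: float = 0.95,
    dist: str = "normal",
    df: int | None = None,
) -> float:
    """Back out a standard error from a reported confidence interval.

    SE = (upper - lower) / (2 q), where q is the normal or Student-t
    quantile at the interval's level.  Only the width matters, so
    asymmetric reporting around the estimate is irrelevant.
    """
    if upper < lower:
        raise ValueError(f"upper < lower: ({lower}, {upper})")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if dist == "normal":
        q = stats.norm.ppf(0.5 + level / 2)
    elif dist == "t":
        if df is None:
            raise ValueError("df is required for a t-based interval")
        q = stats.t.ppf(0.5 + level / 2, df)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    return float((upper - lower) / (2.0 * q))


def _weights(es: np.ndarray, se: np.ndarray) -> np.ndarray:
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    if es.shape != se.shape or es.ndim != 1:
        raise ValueError("es and se must be one-dimensional vectors of equal length")
    if es.size < 2:
        raise ValueError("need at least 2 studies")
    if np.any(np.isnan(se)):
        idx = np.flatnonzero(np.isnan(se))
        raise ValueError(
            f"missing SE for study index(es) {idx.tolist()}: inverse-variance pooling "
            "needs every SE; consider the ratio (scenario 1) methods, which do not"
        )
    if np.any(se <= 0):
        idx = np.flatnonzero(se <= 0)
        raise ValueError(f"nonpositive SE for study index(es) {idx.tolist()}")
    return 1.0 / se**2


def _pool(es: np.ndarray, w: np.ndarray, alpha: float, method: str, outcome: str) -> PooledDifference:
    est = float(np.sum(w * es) / np.sum(w))
    se_pooled = float(np.sqrt(1.0 / np.sum(w)))
    half = stats.norm.ppf(1 - alpha / 2) * se_pooled
    return PooledDifference(
        method=method,
        outcome=outcome,
        estimate=est,
        se=se_pooled,
        df=None,
        ci_lower=est - half,
        ci_upper=est + half,
        alpha=alpha,
    )


def pool_ivw_fe(
    es: np.ndarray, se: np.ndarray, alpha: float = 0.05, outcome: str = "effect"
) -> PooledDifference:
    """Fixed-effect inverse-variance pooled estimate with z-based CI."""
    w = _weights(np.asarray(es, float), np.asarray(se, float))
    return _pool(np.asarray(es, float), w, alpha, "ivw_fe", outcome)


def heterogeneity(es: np.ndarray, se: np.ndarray) -> Heterogeneity:
    """Q, I^2 and the DerSimonian-Laird tau^2 from fixed-effect weights."""
    es = np.asarray(es, dtype=float)
    w = _weights(es, np.asarray(se, float))
    sw = np.sum(w)
    Q = float(np.sum(w * es**2) - np.sum(w * es) ** 2 / sw)
    Q = max(Q, 0.0)  # guard tiny negative rounding
    df = es.size - 1
    I2 = i_squared(Q, es.size)
    denom = sw - np.sum(w**2) / sw
    tau2 = max((Q - df) / denom, 0.0) if denom > 0 else 0.0
    return Heterogeneity(Q=Q, df=df, I2=float(I2), tau2=float(tau2))


def pool_ivw_re(
    es: np.ndarray, se: np.ndarray, alpha: float = 0.05, outcome: str = "effect"
) -> PooledDifference:
    """DerSimonian-Laird random-effects pooled estimate with z-based CI.

    Reduces exactly to :func:`pool_ivw_fe` when the estimated tau^2 is 0.
    """
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    tau2 = heterogeneity(es, se).tau2
    w_star = 1.0 / (se**2 + tau2)
    return _pool(es, w_star, alpha, "ivw_re", outcome)


def pool_ivw(
    dataset: MetaDataset,
    outcome: str = "cost",
    method: str = "ivw_re",
    alpha: float = 0.05,
    complete_case: bool = False,
) -> PooledDifference:
    """Pool one outcome of a dataset by inverse-variance weighting.

    Refuses datasets with missing SEs (pointing the user to the ratio
    methods) unless ``complete_case=True``, which silently restricts to
    the studies reporting an SE — the pragmatic subset re-analysis.
    """
    es = dataset.deltas(outcome)
    se = dataset.se(outcome)
    if complete_case:
        keep = ~np.isnan(se)
        es, se = es[keep], se[keep]
    fn = {"ivw_fe": pool_ivw_fe, "ivw_re": pool_ivw_re}[method]
    return fn(es, se, alpha=alpha, outcome=outcome)
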