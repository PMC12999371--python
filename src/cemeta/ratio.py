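"""Ratio ("studies-at-random") pooling of incremental costs and effects.

Scenario 1 in the cost-effectiveness meta-analysis workflow: each study
reports :math:`(\\Delta C_j, \\Delta E_j, N_j)` but no standard errors.
Each study is treated as a sampled cluster, and the pooled difference is
the ratio of sample means

.. math:: \\bar Y / \\bar Z = \\sum_j N_j \\Delta_j \\Big/ \\sum_j N_j,

with :math:`Y_j = N_j \\Delta_j` and :math:`Z_j = N_j`.  Its variance is
the Taylor-linearisation (delta-method) form from classical survey
sampling,

.. math::

   V^2 = \\frac{1}{M}\\left[\\frac{\\sigma_y^2}{\\mu_z^2}
         + \\frac{\\mu_y^2 \\sigma_z^2}{\\mu_z^4}
         - \\frac{2\\rho_{y,z}\\,\\mu_y \\sigma_y \\sigma_z}{\\mu_z^3}\\right],

estimated by plugging in sample moments (M-1 divisor), and the reference
distribution is Student t with M-2 degrees of freedom.  A variant treats
the study sizes :math:`N_j` as fixed constants, which yields the simpler
variance :math:`(\\sum N_j^2 / (\\sum N_j)^2)\\, s^2(\\Delta_j)` with
M-1 degrees of freedom; its intervals are typically wider.  The two
variants share the identical point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MetaDataset

__all__ = [
    "RatioComponents",
    "PooledDifference",
    "ratio_components",
    "taylor_ratio_variance",
    "pool_ratio",
    "pool_ratio_constant",
]


@dataclass(frozen=True)
class RatioComponents:
    """Sample moments of the paired vectors (Y_j, Z_j) feeding the
    Taylor-linearised ratio variance: means, SDs (M-1 divisor), their
    correlation, and the number of studies."""

    mu_y: float
    mu_z: float
    sigma_y: float
    sigma_z: float
    rho_yz: float
    M: int

    def __post_init__(self) -> None:
        if self.sigma_y < 0 or self.sigma_z < 0:
            raise ValueError("sigma components must be nonnegative")
        if not -1.0 <= self.rho_yz <= 1.0 + 1e-12:
            raise ValueError(f"rho_yz out of [-1, 1]: {self.rho_yz}")
        if self.M < 2:
            raise ValueError("M must be >= 2")


@dataclass(frozen=True)
class PooledDifference:
    """A pooled incremental cost or effectiveness with its interval.

    ``df`` is the Student-t degrees of freedom, or ``None`` for a
    normal-quantile (z) interval.
    """

    method: str  # ratio | ratio_constant | ivw_fe | ivw_re
    outcome: str  # cost | effect
    estimate: float
    se: float
    df: int | None
    ci_lower: float
    ci_upper: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be nonnegative")
        if not self.ci_lower <= self.estimate <= self.ci_upper:
            raise ValueError("estimate must lie inside its CI")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def quantile(self) -> float:
        """The critical value used for the CI half-width."""
        if self.df is None:
            return float(stats.norm.ppf(1 - self.alpha / 2))
        return float(stats.t.ppf(1 - self.alpha / 2, self.df))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "outcome": self.outcome,
            "estimate": self.estimate,
            "se": self.se,
            "df": self.df,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "alpha": self.alpha,
        }


def ratio_components(y: np.ndarray, z: np.ndarray) -> RatioComponents:
    """Method-of-moments estimates of the five ratio-variance parameters.

    Uses the unbiased (M-1 divisor) sample variance and covariance.  If
    either vector is constant the correlation is undefined; it is set to 0
    with a warning, which zeroes the cross term of the variance.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.ndim != 1:
        raise ValueError("y and z must be one-dimensional vectors of equal length")
    M = y.size
    if M < 3:
        raise ValueError(f"need at least 3 studies for ratio pooling, got {M}")
    sigma_y = float(np.std(y, ddof=1))
    sigma_z = float(np.std(z, ddof=1))
    if sigma_y == 0.0 or sigma_z == 0.0:
        if sigma_y > 0 or sigma_z > 0:
            warnings.warn(
                "zero variance in one component; correlation set to 0", stacklevel=2
            )
        rho = 0.0
    else:
        cov = float(np.cov(y, z, ddof=1)[0, 1])
        rho = min(1.0, max(-1.0, cov / (sigma_y * sigma_z)))
    return RatioComponents(
        mu_y=float(np.mean(y)),
        mu_z=float(np.mean(z)),
        sigma_y=sigma_y,
        sigma_z=sigma_z,
        rho_yz=rho,
        M=M,
    )


def taylor_ratio_variance(c: RatioComponents) -> float:
    """The Taylor-linearised variance of the ratio of means, truncated at 0.

    Plug-in evaluation of the delta-method form; tiny negative values can
    occur in near-degenerate configurations and are clipped.
    """
    if c.mu_z == 0:
        raise ZeroDivisionError("mu_z is zero; the ratio of means is undefined")
    v2 = (
        c.sigma_y**2 / c.mu_z**2
        + c.mu_y**2 * c.sigma_z**2 / c.mu_z**4
        - 2.0 * c.rho_yz * c.mu_y * c.sigma_y * c.sigma_z / c.mu_z**3
    ) / c.M
    return max(v2, 0.0)


def _check_dataset(dataset: MetaDataset, min_m: int) -> None:
    if dataset.M < min_m:
        raise ValueError(f"need at least {min_m} studies, got {dataset.M}")
    if np.all(dataset.n == 0):
        raise ValueError("all study sizes are zero")


def pool_ratio(dataset: MetaDataset, outcome: str = "cost", alpha: float = 0.05) -> PooledDifference:
    """Pool one outcome by the ratio (studies-at-random) estimator.

    Point estimate :math:`\\sum N_j\\Delta_j / \\sum N_j`; variance by
    :func:`taylor_ratio_variance` on :math:`(Y_j, Z_j) = (N_j\\Delta_j, N_j)`;
    CI from Student t with M-2 degrees of freedom.
    """
    _check_dataset(dataset, min_m=3)
    delta = dataset.deltas(outcome)
    n = dataset.n
    comp = ratio_components(n * delta, n)
    est = float(np.sum(n * delta) / np.sum(n))
    se = float(np.sqrt(taylor_ratio_variance(comp)))
    df = dataset.M - 2
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return PooledDifference(
        method="ratio",
        outcome=outcome,
        estimate=est,
        se=se,
        df=df,
        ci_lower=est - half,
        ci_upper=est + half,
        alpha=alpha,
    )


def pool_ratio_constant(
    dataset: MetaDataset, outcome: str = "cost", alpha: float = 0.05
) -> PooledDifference:
    """Pool one outcome treating the study sizes as fixed constants.

    Same point estimate as :func:`pool_ratio`; the variance is
    :math:`(\\sum N_j^2/(\\sum N_j)^2)\\, s^2(\\Delta_j)` with the
    unweighted M-1-divisor sample variance of the per-study differences,
    and the CI uses Student t with M-1 degrees of freedom.  With equal
    study sizes this reduces to the classical variance-of-a-mean
    :math:`s^2/M`.
    """
    _check_dataset(dataset, min_m=2)
    delta = dataset.deltas(outcome)
    n = dataset.n
    est = float(np.sum(n * delta) / np.sum(n))
    v2 = float(np.sum(n**2) / np.sum(n) ** 2 * np.var(delta, ddof=1))
    se = float(np.sqrt(v2))
    df = dataset.M - 1
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return PooledDifference(
        method="ratio_constant",
        outcome=outcome,
        estimate=est,
        se=se,
        df=df,
        ci_lower=est - half,
        ci_upper=est + half,
        alpha=alpha,
    )
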