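"""ICER estimation and the bootstrap "wedge" confidence arc.

The incremental cost-effectiveness ratio ICER = deltaC/deltaE is a slope
through the origin of the cost-effectiveness plane (deltaE on x, deltaC
on y), so a confidence statement about it is an *arc* of directions, not
an ordinary interval: slopes wrap through +/-infinity when the pooled
effect crosses zero, and the same numeric slope means opposite things in
opposite quadrants.  The wedge method bootstraps studies (resampling the
(deltaE, deltaC, N) triple of each study with replacement), recomputes
the pooled pair for each replicate, and reads off an angular central
region:

* replicates confined to at most three quadrants -- cut the circle in the
  largest empty angular gap, sort counterclockwise, and take the
  alpha/2-th order statistic in from each end: a clockwise bound (CB) and
  a counterclockwise bound (CCB);
* replicates in all four quadrants -- no gap exists; centre the count on
  the point-estimate direction and keep the central 1-alpha mass
  (the excluded tail is antipodal to the estimate).  Such arcs are
  flagged: four occupied quadrants mean the data barely constrain the
  direction.

When the cloud lives in a single quadrant this reduces to the ordinary
bootstrap percentile interval on the slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MetaDataset
from .ratio import PooledDifference, ratio_components, taylor_ratio_variance

__all__ = [
    "ICEREstimate",
    "BootstrapCloud",
    "WedgeInterval",
    "TaylorICERInterval",
    "classify_quadrant",
    "quadrant_summary",
    "icer_point",
    "bootstrap_cloud",
    "wedge_ci",
    "taylor_icer_ci",
]

#: Quadrants in counterclockwise order starting at angle -pi.
_QUADRANT_ORDER = ("SW", "SE", "NE", "NW")


def classify_quadrant(delta_e: float, delta_c: float) -> str:
    """Sign-based quadrant of a (deltaE, deltaC) point; exact zeros -> 'on_axis'."""
    if delta_e > 0 and delta_c > 0:
        return "NE"
    if delta_e > 0 and delta_c < 0:
        return "SE"
    if delta_e < 0 and delta_c > 0:
        return "NW"
    if delta_e < 0 and delta_c < 0:
        return "SW"
    return "on_axis"


def _angles(delta_e: np.ndarray, delta_c: np.ndarray) -> np.ndarray:
    """Direction of each point, atan2(deltaC, deltaE) in (-pi, pi]."""
    th = np.arctan2(delta_c, delta_e)
    # fold the branch point so quadrant bins are half-open on a full circle
    return np.where(th == np.pi, -np.pi, th)


def _quadrant_of_angle(theta: float) -> str:
    """Quadrant bin of an angle; axis points go to the counterclockwise
    neighbour (theta = 0 -> NE, pi/2 -> NW, -pi -> SW, -pi/2 -> SE)."""
    idx = int(np.floor((theta + np.pi) / (np.pi / 2))) % 4
    return _QUADRANT_ORDER[idx]


def quadrant_summary(dataset: MetaDataset) -> dict[str, int]:
    """Tally each study's quadrant on the CE plane.

    Counts are invariant to study order; points exactly on an axis are
    reported separately under ``on_axis``.
    """
    counts = {"NE": 0, "NW": 0, "SE": 0, "SW": 0, "on_axis": 0}
    for s in dataset.studies:
        counts[classify_quadrant(s.delta_e, s.delta_c)] += 1
    return counts


@dataclass(frozen=True)
class ICEREstimate:
    """Pooled ICER: the pooled (deltaE, deltaC) pair, the slope through
    the origin, its quadrant, and an optional willingness-to-pay decision."""

    delta_e_pooled: float
    delta_c_pooled: float
    slope: float  # may be +/-inf when the pooled effect is exactly zero
    quadrant: str
    wtp: float | None = None
    decision: str | None = None

    def to_dict(self) -> dict:
        return {
            "delta_e_pooled": self.delta_e_pooled,
            "delta_c_pooled": self.delta_c_pooled,
            "icer": self.slope,
            "quadrant": self.quadrant,
            "wtp": self.wtp,
            "decision": self.decision,
        }


def icer_point(
    dc: PooledDifference, de: PooledDifference, wtp: float | None = None
) -> ICEREstimate:
    """Form the pooled ICER from pooled cost and effect differences.

    The decision logic follows the CE-plane quadrants: SE (more effective,
    cheaper) is dominant and NW is dominated regardless of the threshold;
    in NE the ICER must not exceed the willingness-to-pay lambda; in SW
    (cheaper but less effective) the savings per unit of effect forgone
    must be at least lambda, i.e. slope >= lambda.
    """
    de_est, dc_est = de.estimate, dc.estimate
    if de_est == 0:
        warnings.warn(
            "pooled effectiveness difference is exactly zero: ICER is unbounded",
            stacklevel=2,
        )
        slope = math.inf if dc_est > 0 else (-math.inf if dc_est < 0 else math.nan)
    else:
        slope = dc_est / de_est
    quadrant = classify_quadrant(de_est, dc_est)
    decision: str | None
    if quadrant == "SE":
        decision = "dominant"
    elif quadrant == "NW":
        decision = "dominated"
    elif wtp is None or quadrant == "on_axis":
        decision = "indeterminate"
    elif quadrant == "NE":
        decision = "cost_effective_under_wtp" if slope <= wtp else "not_cost_effective_under_wtp"
    else:  # SW: forgone-effect logic
        decision = "cost_effective_under_wtp" if slope >= wtp else "not_cost_effective_under_wtp"
    return ICEREstimate(
        delta_e_pooled=de_est,
        delta_c_pooled=dc_est,
        slope=slope,
        quadrant=quadrant,
        wtp=wtp,
        decision=decision,
    )


@dataclass(frozen=True)
class BootstrapCloud:
    """B bootstrap replicates of the pooled (deltaE, deltaC) pair."""

    delta_e: np.ndarray
    delta_c: np.ndarray
    B: int
    seed: int
    method: str
    quadrant_counts: dict

    def __post_init__(self) -> None:
        if len(self.delta_e) != self.B or len(self.delta_c) != self.B:
            raise ValueError("replicate arrays must have length B")
        if sum(self.quadrant_counts.values()) != self.B:
            raise ValueError("quadrant counts must sum to B")

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "method": self.method,
            "quadrant_counts": dict(self.quadrant_counts),
        }


def _pooled_pairs(dataset: MetaDataset, method: str, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (deltaE, deltaC) point estimates for each resample row of idx."""
    de, dc, n = dataset.delta_e, dataset.delta_c, dataset.n
    if method in ("ratio", "ratio_constant"):
        nn = n[idx]
        tot = nn.sum(axis=1)
        return (nn * de[idx]).sum(axis=1) / tot, (nn * dc[idx]).sum(axis=1) / tot
    if method in ("ivw_fe", "ivw_re"):
        out = []
        for outcome in ("effect", "cost"):
            se = dataset.se(outcome)
            if np.any(np.isnan(se)) or np.any(se <= 0):
                raise ValueError(
                    f"method {method!r} needs a positive SE for every study's {outcome}; "
                    "use the ratio methods when SEs are unavailable"
                )
            es = dataset.deltas(outcome)[idx]
            w = 1.0 / se[idx] ** 2
            sw = w.sum(axis=1)
            if method == "ivw_re":
                swe = (w * es).sum(axis=1)
                Q = np.maximum((w * es**2).sum(axis=1) - swe**2 / sw, 0.0)
                denom = sw - (w**2).sum(axis=1) / sw
                dfq = idx.shape[1] - 1
                tau2 = np.where(denom > 0, np.maximum((Q - dfq) / denom, 0.0), 0.0)
                w = 1.0 / (se[idx] ** 2 + tau2[:, None])
                sw = w.sum(axis=1)
            out.append((w * es).sum(axis=1) / sw)
        return out[0], out[1]
    raise ValueError(f"unknown pooling method {method!r}")


def bootstrap_cloud(
    dataset: MetaDataset, method: str = "ratio", B: int = 500, seed: int = 0
) -> BootstrapCloud:
    """Resample studies with replacement and re-pool each replicate.

    Each bootstrap draw keeps a study's (deltaE, deltaC, N, SE) together,
    preserving the within-study cost-effect pairing.  Deterministic for a
    given seed.
    """
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    if dataset.M < 2:
        raise ValueError("need at least 2 studies to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, dataset.M, size=(B, dataset.M))
    de_rep, dc_rep = _pooled_pairs(dataset, method, idx)
    th = _angles(de_rep, dc_rep)
    counts = {q: 0 for q in ("NE", "NW", "SE", "SW")}
    for t in th:
        counts[_quadrant_of_angle(float(t))] += 1
    return BootstrapCloud(
        delta_e=de_rep, delta_c=dc_rep, B=B, seed=seed, method=method, quadrant_counts=counts
    )


@dataclass(frozen=True)
class WedgeInterval:
    """The wedge confidence arc for the ICER.

    ``cb_slope``/``ccb_slope`` are the clockwise and counterclockwise
    bounds as slopes, each with its quadrant label; the angles (radians,
    direction of (deltaE, deltaC)) locate the bounds unambiguously even
    where the slope alone would not.  ``informative`` is False for the
    four-quadrant case, where an arc adds little to decision-making.
    """

    cb_slope: float
    cb_quadrant: str
    ccb_slope: float
    ccb_quadrant: str
    cb_angle: float
    ccb_angle: float
    mode: str  # percentile_1to3_quadrants | inward_4_quadrants
    level: float
    occupied_quadrants: tuple[str, ...]
    contained_fraction: float
    B: int
    informative: bool = True

    def to_dict(self) -> dict:
        return {
            "cb_slope": self.cb_slope,
            "cb_quadrant": self.cb_quadrant,
            "ccb_slope": self.ccb_slope,
            "ccb_quadrant": self.ccb_quadrant,
            "cb_angle": self.cb_angle,
            "ccb_angle": self.ccb_angle,
            "mode": self.mode,
            "level": self.level,
            "occupied_quadrants": list(self.occupied_quadrants),
            "contained_fraction": self.contained_fraction,
            "B": self.B,
            "informative": self.informative,
        }


def _slope(de: float, dc: float) -> float:
    if de == 0:
        return math.inf if dc > 0 else (-math.inf if dc < 0 else math.nan)
    return dc / de


def wedge_ci(cloud: BootstrapCloud, point: ICEREstimate, level: float = 0.95) -> WedgeInterval:
    """Wedge confidence arc from a bootstrap cloud.

    Bounds are the ceil(B*alpha/2)-th replicate in from each end of the
    counterclockwise ordering (ties broken by replicate index); the arc
    between them contains at least ``level - 1/B`` of the replicates and
    the point-estimate direction.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    de, dc = np.asarray(cloud.delta_e, float), np.asarray(cloud.delta_c, float)
    at_origin = (de == 0) & (dc == 0)
    if np.any(at_origin):
        warnings.warn(
            f"dropping {int(at_origin.sum())} bootstrap replicate(s) at the exact origin "
            "(no direction defined)",
            stacklevel=2,
        )
        de, dc = de[~at_origin], dc[~at_origin]
    B = de.size
    if B < 1.0 / alpha:
        raise ValueError(f"{B} replicates cannot resolve a {level:.0%} arc (need >= {1/alpha:.0f})")

    th = _angles(de, dc)
    occupied = tuple(q for q in _QUADRANT_ORDER if any(_quadrant_of_angle(float(t)) == q for t in th))
    theta_hat = float(_angles(np.array([point.delta_e_pooled]), np.array([point.delta_c_pooled]))[0])
    # guard against binary rounding of alpha (1 - 0.95 is slightly above 0.05)
    k = math.ceil(B * alpha / 2.0 - 1e-9)

    if len(occupied) <= 3:
        # Cut the circle in the middle of the largest empty angular gap and
        # sort counterclockwise from the cut: the two tails are then apparent.
        order_th = np.sort(th)
        gaps = np.diff(np.concatenate([order_th, [order_th[0] + 2.0 * np.pi]]))
        gi = int(np.argmax(gaps))
        cut = float(order_th[gi] + gaps[gi] / 2.0)
        rel = (th - cut) % (2.0 * np.pi)
        mode = "percentile_1to3_quadrants"
        informative = True
    else:
        # All four quadrants occupied: count inward around the point
        # estimate; the excluded tail sits antipodal to it.
        rel = (th - theta_hat + np.pi) % (2.0 * np.pi)
        mode = "inward_4_quadrants"
        informative = False
        warnings.warn(
            "bootstrap replicates occupy all four quadrants: high uncertainty, "
            "the wedge arc is not informative for decision-making",
            stacklevel=2,
        )

    order = np.argsort(rel, kind="stable")
    cb_i, ccb_i = int(order[k - 1]), int(order[B - k])
    cb_angle, ccb_angle = float(th[cb_i]), float(th[ccb_i])

    # containment of the point-estimate direction (counterclockwise cb -> ccb)
    rel_hat = (theta_hat - (cb_angle)) % (2.0 * np.pi)
    rel_ccb = (ccb_angle - cb_angle) % (2.0 * np.pi)
    if mode == "percentile_1to3_quadrants" and rel_hat > rel_ccb:
        warnings.warn(
            "point-estimate direction lies outside the wedge arc; the bootstrap "
            "cloud may be severely skewed relative to the point estimate",
            stacklevel=2,
        )
    return WedgeInterval(
        cb_slope=_slope(float(de[cb_i]), float(dc[cb_i])),
        cb_quadrant=_quadrant_of_angle(cb_angle),
        ccb_slope=_slope(float(de[ccb_i]), float(dc[ccb_i])),
        ccb_quadrant=_quadrant_of_angle(ccb_angle),
        cb_angle=cb_angle,
        ccb_angle=ccb_angle,
        mode=mode,
        level=level,
        occupied_quadrants=occupied,
        contained_fraction=(B - 2 * (k - 1)) / B,
        B=B,
        informative=informative,
    )


@dataclass(frozen=True)
class TaylorICERInterval:
    """Taylor-linearisation CI for the ICER treated as a ratio of
    N-weighted means (Y_j = N_j deltaC_j over Z_j = N_j deltaE_j).

    ``reliable`` is False when the pooled effect is not clearly away from
    zero (|t| below the CI critical value): the linearisation then breaks
    down.  Unlike the wedge, this symmetric interval carries no quadrant
    awareness and may not handle multi-quadrant uncertainty well.
    """

    estimate: float
    se: float
    df: int
    ci_lower: float
    ci_upper: float
    alpha: float
    reliable: bool
    caveat: str = "symmetric slope interval; may not handle multi-quadrant scenarios well"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "df": self.df,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "alpha": self.alpha,
            "reliable": self.reliable,
            "caveat": self.caveat,
        }


def taylor_icer_ci(dataset: MetaDataset, alpha: float = 0.05) -> TaylorICERInterval:
    """Closed-form ICER CI by the ratio method on (N deltaC, N deltaE)."""
    from .ratio import pool_ratio  # local import avoids cycle at module load

    if dataset.M < 3:
        raise ValueError("need at least 3 studies")
    n = dataset.n
    y = n * dataset.delta_c
    z = n * dataset.delta_e
    if np.sum(z) == 0:
        raise ZeroDivisionError("pooled effectiveness difference is zero; ICER undefined")
    comp = ratio_components(y, z)
    est = float(np.sum(y) / np.sum(z))
    se = float(np.sqrt(taylor_ratio_variance(comp)))
    df = dataset.M - 2
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    eff = pool_ratio(dataset, "effect", alpha)
    reliable = bool(eff.se > 0 and abs(eff.estimate / eff.se) > tcrit)
    if not reliable:
        warnings.warn(
            "pooled effectiveness difference is not clearly nonzero; the Taylor "
            "ICER interval is unreliable (prefer the bootstrap wedge)",
            stacklevel=2,
        )
    return TaylorICERInterval(
        estimate=est,
        se=se,
        df=df,
        ci_lower=est - tcrit * se,
        ci_upper=est + tcrit * se,
        alpha=alpha,
        reliable=reliable,
    )
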