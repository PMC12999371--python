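"""Study-level input data for cost-effectiveness meta-analysis.

The unit of analysis is one published study contributing an incremental
cost :math:`\\Delta C_j` (treatment minus control, in a common currency),
an incremental effectiveness :math:`\\Delta E_j` (e.g. QALYs), and the
total sample size :math:`N_j` of both arms combined.  Within-study
standard errors are optional: the ratio ("studies-at-random") pooling
methods do not need them, while inverse-variance weighting does.

Effectiveness is normalised so that larger values are better.  Rows whose
outcome scale runs the other way (``effect_direction = higher_worse``,
e.g. sick-leave days) have ``delta_e`` negated on load.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "MetaDataset",
    "FewStudiesWarning",
    "read_studies",
    "write_studies",
    "bundled_tricco",
    "write_results",
    "read_results",
]

HIGHER_BETTER = "higher_better"
HIGHER_WORSE = "higher_worse"

#: Minimum number of studies below which bootstrap-wedge inference is
#: expected to behave poorly (many ties among resampled ICERs).
MIN_RELIABLE_STUDIES = 5


class FewStudiesWarning(UserWarning):
    """Raised when a dataset has fewer studies than inference comfortably supports."""


@dataclass(frozen=True)
class StudyRecord:
    """One study's summary row.

    Parameters
    ----------
    study_id:
        Label, unique within a dataset.
    delta_c:
        Incremental cost, treatment arm minus control arm, common currency.
    delta_e:
        Incremental effectiveness on the larger-is-better scale.
    n:
        Total sample size, both arms combined (>= 1).
    se_delta_c, se_delta_e:
        Optional within-study standard errors (>= 0).
    effect_direction:
        Scale orientation of ``delta_e`` *as stored*.  Loading flips
        ``higher_worse`` rows onto the ``higher_better`` scale.
    """

    study_id: str
    delta_c: float
    delta_e: float
    n: int
    se_delta_c: float | None = None
    se_delta_e: float | None = None
    effect_direction: str = HIGHER_BETTER

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(
                f"study {self.study_id!r}: n must be a positive integer, got {self.n!r}"
            )
        for name in ("se_delta_c", "se_delta_e"):
            v = getattr(self, name)
            if v is not None and not (v >= 0):
                raise ValueError(f"study {self.study_id!r}: {name} must be >= 0, got {v!r}")
        if self.effect_direction not in (HIGHER_BETTER, HIGHER_WORSE):
            raise ValueError(
                f"study {self.study_id!r}: unknown effect_direction {self.effect_direction!r}"
            )

    def normalized(self) -> "StudyRecord":
        """Return the record on the larger-is-better effectiveness scale.

        Involutive in the sense that toggling the direction twice restores
        the original record.
        """
        if self.effect_direction == HIGHER_BETTER:
            return self
        return replace(self, delta_e=-self.delta_e, effect_direction=HIGHER_BETTER)

    def flipped(self) -> "StudyRecord":
        """Toggle the stored direction, negating ``delta_e``."""
        other = HIGHER_WORSE if self.effect_direction == HIGHER_BETTER else HIGHER_BETTER
        return replace(self, delta_e=-self.delta_e, effect_direction=other)


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of studies with unit labels.

    Invariants: at least two studies are required for any pooling; a
    :class:`FewStudiesWarning` is emitted below five studies (wedge
    inference is unreliable with so few).  Study ids must be unique.
    """

    studies: tuple[StudyRecord, ...]
    cost_label: str = "currency"
    effect_label: str = "effect"

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study ids: {dupes}")
        if self.M < MIN_RELIABLE_STUDIES:
            warnings.warn(
                f"only {self.M} studies: pooled inference (especially the bootstrap "
                f"wedge) is unreliable with fewer than {MIN_RELIABLE_STUDIES} studies",
                FewStudiesWarning,
                stacklevel=2,
            )

    @property
    def M(self) -> int:
        """Number of studies."""
        return len(self.studies)

    @property
    def delta_c(self) -> np.ndarray:
        return np.array([s.delta_c for s in self.studies], dtype=float)

    @property
    def delta_e(self) -> np.ndarray:
        return np.array([s.delta_e for s in self.studies], dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.array([s.n for s in self.studies], dtype=float)

    def se(self, outcome: str) -> np.ndarray:
        """Per-study SEs for ``outcome`` in {'cost', 'effect'}; NaN where absent."""
        attr = {"cost": "se_delta_c", "effect": "se_delta_e"}[outcome]
        return np.array(
            [math.nan if getattr(s, attr) is None else getattr(s, attr) for s in self.studies],
            dtype=float,
        )

    def deltas(self, outcome: str) -> np.ndarray:
        return {"cost": self.delta_c, "effect": self.delta_e}[outcome]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [s.study_id for s in self.studies],
                "delta_c": self.delta_c,
                "delta_e": self.delta_e,
                "n": [s.n for s in self.studies],
                "se_delta_c": self.se("cost"),
                "se_delta_e": self.se("effect"),
            }
        )


_REQUIRED = ("study_id", "delta_c", "delta_e", "n")
_OPTIONAL = ("se_delta_c", "se_delta_e", "effect_direction")


def read_studies(
    path: str | Path,
    *,
    delimiter: str = ",",
    cost_label: str = "currency",
    effect_label: str = "effect",
) -> MetaDataset:
    """Read a study-level CSV into a validated :class:`MetaDataset`.

    The file must have a header with columns ``study_id, delta_c, delta_e, n``;
    ``se_delta_c, se_delta_e, effect_direction`` are optional.  Empty cells are
    missing values.  Rows flagged ``higher_worse`` have ``delta_e`` negated so
    that the returned dataset is uniformly on the larger-is-better scale.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"study_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected a header row with {_REQUIRED}") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records = []
    for i, row in df.iterrows():
        def _num(col: str, *, required: bool) -> float | None:
            if col not in df.columns:
                return None
            v = row[col]
            if pd.isna(v):
                if required:
                    raise ValueError(f"{path}: row {i + 2}: missing value in {col!r}")
                return None
            try:
                return float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i + 2}: non-numeric value {v!r} in column {col!r}"
                ) from None

        n_val = _num("n", required=True)
        if n_val is None or n_val <= 0 or n_val != int(n_val):
            raise ValueError(f"{path}: row {i + 2}: n must be a positive integer, got {row['n']!r}")
        direction = HIGHER_BETTER
        if "effect_direction" in df.columns and not pd.isna(row["effect_direction"]):
            direction = str(row["effect_direction"]).strip()
        rec = StudyRecord(
            study_id=str(row["study_id"]),
            delta_c=_num("delta_c", required=True),
            delta_e=_num("delta_e", required=True),
            n=int(n_val),
            se_delta_c=_num("se_delta_c", required=False),
            se_delta_e=_num("se_delta_e", required=False),
            effect_direction=direction,
        ).normalized()
        records.append(rec)
    return MetaDataset(tuple(records), cost_label=cost_label, effect_label=effect_label)


def write_studies(dataset: MetaDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset back to CSV (inverse of :func:`read_studies`)."""
    dataset.to_frame().to_csv(Path(path), sep=delimiter, index=False)


# The 16 wound-intervention studies (complex-wound cost-effectiveness
# systematic review; costs in 2013 USD, effectiveness in QALY-like time
# units).  Within-study SEs were not reported -- the scenario the ratio
# methods exist for.  Two studies by the same first author are suffixed
# to keep ids unique.
_TRICCO_ROWS: tuple[tuple[str, float, float, int], ...] = (
    ("Augustin", -3362.0, 0.025, 25),
    ("DePalma", -601.0, 0.033, 38),
    ("Iglesias_a", -213.0, 0.01, 434),
    ("Iglesias_b", -566.0, 0.02, 387),
    ("Michaels", 183.0, 0.0002, 213),
    ("Morrell", 44.0, 0.11, 233),
    ("Watson", 371.0, -0.009, 337),
    ("Pham", 395.0, 0.009, 424),
    ("Schonfeld", -13883.0, 0.24, 240),
    ("Guest", -835.0, 0.054, 83),
    ("Dumville", 195.0, 0.011, 267),
    ("Guo", 2137.0, 0.609, 126),
    ("Habacher", -7625.0, 2.97, 119),
    ("Jansen", -822.0, 0.12, 402),
    ("Hailey", -9337.0, 0.63, 305),
    ("Xakellis", -25.0, 0.005, 39),
)


def bundled_tricco() -> MetaDataset:
    """The bundled 16-study wound-intervention dataset.

    Incremental costs are in 2013 USD; effectiveness measures are
    time-scale outcomes (QALY, ulcer-free time, patient-years) pooled on a
    common larger-is-better convention.  No within-study SEs are
    available, so only the ratio (scenario 1) methods apply.
    """
    return MetaDataset(
        tuple(StudyRecord(sid, dc, de, n) for sid, dc, de, n in _TRICCO_ROWS),
        cost_label="2013 USD",
        effect_label="QALY",
    )


def _jsonable(obj):
    """Recursively convert results objects / numpy scalars to JSON-clean values."""
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def write_results(results: Mapping, path: str | Path) -> None:
    """Serialise a results bundle (pooled differences, ICER, wedge, cloud
    summaries...) to a round-trippable JSON document.

    Any nested object exposing ``to_dict()`` is expanded; infinities are
    encoded as the strings ``"inf"`` / ``"-inf"`` so the document stays
    strict JSON.
    """
    doc = _jsonable(results)
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    """Load a JSON results document written by :func:`write_results`."""

    def _revive(v):
        if v == "inf":
            return math.inf
        if v == "-inf":
            return -math.inf
        if isinstance(v, dict):
            return {k: _revive(x) for k, x in v.items()}
        if isinstance(v, list):
            return [_revive(x) for x in v]
        return v

    with open(Path(path), encoding="utf-8") as fh:
        return _revive(json.load(fh))
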