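"""Sample-size-weighted pooling of per-study estimates.

Model inputs pooled from several clinical studies use the weighted average
sum(n_i * v_i) / sum(n_i), on the reported scale (proportions are pooled
as proportions).  A per-study CSV (columns: label, parameter, value, n)
can be pooled into per-parameter values and applied onto a parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["StudyEstimate", "pool_weighted", "read_studies_csv",
           "pool_study_table", "pooled_overrides"]


@dataclass(frozen=True)
class StudyEstimate:
    """One study's estimate of one model input, with its sample size."""

    label: str
    value: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"study {self.label!r}: n must be >= 1")


def pool_weighted(studies: Sequence[StudyEstimate]) -> float:
    """Sample-size-weighted mean of study estimates.

    Lies within [min, max] of the inputs, is invariant to ordering, and is
    unchanged by scaling all sample sizes by a constant.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty list of studies")
    total_n = sum(s.n for s in studies)
    return sum(s.n * s.value for s in studies) / total_n


_COLUMNS = ["label", "parameter", "value", "n"]


def read_studies_csv(path) -> pd.DataFrame:
    """Read a per-study table (columns: label, parameter, value, n)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV is missing columns: {missing}")
    if (df["n"] < 1).any():
        raise ValueError("study CSV contains n < 1")
    return df[_COLUMNS]


def pool_study_table(df: pd.DataFrame) -> dict[str, float]:
    """Pool a study table into one value per ``parameter`` key.

    Parameter keys address model fields as ``"<arm>.<field>"`` (or
    ``"care.<field>"`` / ``"emissions.<field>"``).
    """
    out: dict[str, float] = {}
    for parameter, group in df.groupby("parameter", sort=True):
        studies = [
            StudyEstimate(label=str(r.label), value=float(r.value), n=int(r.n))
            for r in group.itertuples()
        ]
        out[str(parameter)] = pool_weighted(studies)
    return out


def pooled_overrides(df: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Pool a study table into nested ``{scope: {field: value}}`` overrides.

    The result plugs directly into
    :func:`carbonablate.scenarios.apply_parameter_swap` to build a
    parameter set field-by-field from study-level evidence.
    """
    nested: dict[str, dict[str, float]] = {}
    for key, value in pool_study_table(df).items():
        scope, _, field = key.partition(".")
        if not field:
            raise ValueError(f"parameter key {key!r} is not of the form 'scope.field'")
        nested.setdefault(scope, {})[field] = value
    return nested
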