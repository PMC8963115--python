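"""SSQ and MSSQ scoring and susceptibility grouping.

The Simulator Sickness Questionnaire (SSQ) rates 16 symptoms on a 0-3 scale
and aggregates them into three subscales — nausea (sN), oculomotor (sO) and
disorientation (sD) — plus a total score (sT).  Each symptom belongs to one
or more subscales; a subscale score is the raw sum of its member symptom
levels times a fixed weight (N: 9.54, O: 7.58, D: 13.92), and the total is
the sum of the three raw sums times 3.74.  Scores are left unnormalized so
they can be compared relatively across conditions.

The Motion Sickness Susceptibility Questionnaire (MSSQ) has two sections —
A (childhood experiences) and B (the last 10 years) — whose scores add up
to the overall susceptibility score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSQResponse",
    "SSQScores",
    "MSSQScores",
    "SSQ_TIMEPOINTS",
    "SSQ_SYMPTOMS",
    "ssq_mapping",
    "score_ssq",
    "score_mssq",
    "tertile_groups",
]

SSQ_TIMEPOINTS = ("rest", "post_CCU", "post_CUA", "post_CUU")

_WEIGHT_N = 9.54
_WEIGHT_O = 7.58
_WEIGHT_D = 13.92
_WEIGHT_T = 3.74


def _load_mapping() -> pd.DataFrame:
    ref = importlib.resources.files("cyresick.data") / "ssq_mapping.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


_MAPPING = _load_mapping()

SSQ_SYMPTOMS = tuple(_MAPPING["symptom"])
_MASK_N = _MAPPING["nausea"].to_numpy(bool)
_MASK_O = _MAPPING["oculomotor"].to_numpy(bool)
_MASK_D = _MAPPING["disorientation"].to_numpy(bool)


def ssq_mapping() -> pd.DataFrame:
    """The 16-symptom-to-subscale membership table (one row per symptom)."""
    return _MAPPING.copy()


@dataclass(frozen=True)
class SSQResponse:
    """One questionnaire administration: 16 symptom levels, each in 0..3."""

    items: tuple
    timepoint: str = "rest"

    def __post_init__(self) -> None:
        if len(self.items) != 16:
            raise ValueError(f"SSQ requires 16 items, got {len(self.items)}")
        for i, level in enumerate(self.items):
            if int(level) != level or not 0 <= level <= 3:
                raise ValueError(
                    f"item {i + 1} ({SSQ_SYMPTOMS[i]}): level {level!r} not in 0..3"
                )
        if self.timepoint not in SSQ_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


@dataclass(frozen=True)
class SSQScores:
    sN: float
    sO: float
    sD: float
    sT: float


@dataclass(frozen=True)
class MSSQScores:
    s_A: float
    s_B: float
    s_total: float


def score_ssq(response: SSQResponse) -> SSQScores:
    """Score one SSQ response into the three weighted subscales and total."""
    levels = np.asarray(response.items, dtype=float)
    raw_n = float(levels[_MASK_N].sum())
    raw_o = float(levels[_MASK_O].sum())
    raw_d = float(levels[_MASK_D].sum())
    return SSQScores(
        sN=raw_n * _WEIGHT_N,
        sO=raw_o * _WEIGHT_O,
        sD=raw_d * _WEIGHT_D,
        sT=(raw_n + raw_o + raw_d) * _WEIGHT_T,
    )


def score_mssq(s_A: float, s_B: float) -> MSSQScores:
    """Combine the two MSSQ section scores into the overall susceptibility score."""
    if s_A < 0 or s_B < 0:
        raise ValueError("MSSQ section scores must be nonnegative")
    return MSSQScores(s_A=float(s_A), s_B=float(s_B), s_total=float(s_A) + float(s_B))


def tertile_groups(values) -> list:
    """Split scores into lower/middle/upper thirds by rank.

    The split is rank-based with ties broken by input order (stable), so
    group sizes differ by at most one.  With ``n = 3q + r`` the lower group
    receives the extra member first, then the middle one — e.g. n=154 gives
    sizes (52, 51, 51).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("tertile grouping requires at least 3 values")
    order = np.argsort(values, kind="stable")
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, ("lower", "middle", "upper")):
        labels[order[start:start + size]] = name
        start += size
    return list(labels)
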