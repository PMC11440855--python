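"""Semiquantitative 17-segment perfusion scoring and territory aggregation.

Relative uptake polar maps (17 AHA segments, percent of maximal myocardial
uptake) are banded into 5-point segment scores (0 = normal uptake ...
4 = absent tracer), summed into SSS/SRS/SDS, and mapped onto the three
coronary vessel territories (LAD, LCx, RCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarMap",
    "SegmentScores",
    "SummedScores",
    "TerritoryMap",
    "DEFAULT_THRESHOLDS",
    "score_segments",
    "summed_scores",
    "classify_abnormal",
    "aggregate_territory",
]

N_SEGMENTS = 17

#: Descending uptake cut-points (% of max) between scores 0|1, 1|2, 2|3, 3|4.
DEFAULT_THRESHOLDS = (70.0, 50.0, 30.0, 10.0)

#: Standard AHA segment -> coronary territory assignment (1-based segments).
#: The apex (segment 17) is assigned to the LAD.
_DEFAULT_ASSIGNMENT = {
    1: "LAD", 2: "LAD", 7: "LAD", 8: "LAD", 13: "LAD", 14: "LAD", 17: "LAD",
    3: "RCA", 4: "RCA", 9: "RCA", 10: "RCA", 15: "RCA",
    5: "LCx", 6: "LCx", 11: "LCx", 12: "LCx", 16: "LCx",
}

TERRITORIES = ("LAD", "LCx", "RCA")


@dataclass
class PolarMap:
    """17-segment relative uptake (percent of maximal uptake) at one state."""

    uptake: np.ndarray
    state: str  # "stress" | "rest"

    def __post_init__(self) -> None:
        self.uptake = np.asarray(self.uptake, dtype=float)
        if self.uptake.shape != (N_SEGMENTS,):
            raise ValueError(f"polar map needs exactly {N_SEGMENTS} segments")
        if np.any(self.uptake < 0) or np.any(self.uptake > 100):
            raise ValueError("uptake values must be in [0, 100] percent")
        if self.state not in ("stress", "rest"):
            raise ValueError("state must be 'stress' or 'rest'")


@dataclass
class SegmentScores:
    """Per-segment 5-point scores (0 normal ... 4 absent uptake)."""

    scores: np.ndarray
    state: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (N_SEGMENTS,):
            raise ValueError(f"expected {N_SEGMENTS} segment scores")
        if np.any(self.scores < 0) or np.any(self.scores > 4):
            raise ValueError("segment scores must be in 0..4")


@dataclass(frozen=True)
class SummedScores:
    sss: int
    srs: int
    sds: int

    def __post_init__(self) -> None:
        if not (0 <= self.sss <= 68 and 0 <= self.srs <= 68):
            raise ValueError("summed scores must be in 0..68")
        if self.sds != self.sss - self.srs:
            raise ValueError("SDS must equal SSS - SRS")


@dataclass(frozen=True)
class TerritoryMap:
    """Total assignment of the 17 segments to LAD / LCx / RCA."""

    assignment: dict[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_ASSIGNMENT)
    )

    def __post_init__(self) -> None:
        if sorted(self.assignment) != list(range(1, N_SEGMENTS + 1)):
            raise ValueError("assignment must cover segments 1..17 exactly")
        bad = {t for t in self.assignment.values() if t not in TERRITORIES}
        if bad:
            raise ValueError(f"unknown territories: {sorted(bad)}")

    def segments(self, territory: str) -> list[int]:
        return [s for s, t in sorted(self.assignment.items()) if t == territory]


def score_segments(
    pmap: PolarMap, thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS
) -> SegmentScores:
    """Band relative uptake into 5-point scores.

    Score 0 for uptake >= t1, 1 in [t2, t1), 2 in [t3, t2), 3 in [t4, t3)
    and 4 below t4, with strictly descending thresholds in (0, 100).
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (4,) or np.any(np.diff(t) >= 0):
        raise ValueError("thresholds must be 4 strictly descending cut-points")
    if t[0] >= 100 or t[-1] <= 0:
        raise ValueError("thresholds must lie strictly inside (0, 100)")
    # score = number of cut-points strictly above the uptake value
    scores = np.searchsorted(-t, -pmap.uptake, side="left")
    return SegmentScores(scores, pmap.state)


def summed_scores(stress: SegmentScores, rest: SegmentScores) -> SummedScores:
    """SSS, SRS and their difference SDS = SSS - SRS."""
    if stress.state != "stress" or rest.state != "rest":
        raise ValueError("pass stress scores first, rest scores second")
    sss = int(stress.scores.sum())
    srs = int(rest.scores.sum())
    return SummedScores(sss=sss, srs=srs, sds=sss - srs)


def classify_abnormal(s: SummedScores) -> bool:
    """Abnormal perfusion iff SSS > 3 (strict)."""
    return s.sss > 3


def aggregate_territory(
    values: np.ndarray,
    tmap: TerritoryMap | None = None,
    reducer: str = "mean",
) -> dict[str, float]:
    """Reduce 17 per-segment values to one number per coronary territory."""
    values = np.asarray(values, dtype=float)
    if values.shape != (N_SEGMENTS,):
        raise ValueError(f"expected {N_SEGMENTS} per-segment values")
    if tmap is None:
        tmap = TerritoryMap()
    reducers = {"mean": np.mean, "median": np.median, "sum": np.sum}
    if reducer not in reducers:
        raise ValueError(f"unknown reducer {reducer!r}; use mean|median|sum")
    fn = reducers[reducer]
    return {
        terr: float(fn(values[[s - 1 for s in tmap.segments(terr)]]))
        for terr in TERRITORIES
    }
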