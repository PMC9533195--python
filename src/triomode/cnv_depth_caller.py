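"""Exome CNV detection from capture-interval depth ratios.

Copy-number events are detected by comparing the proband's mean coverage
depth on each captured interval to the mean of the parents' depths, after
normalizing each sample by its genome-wide median depth. Runs of consecutive
intervals whose ratio crosses a deletion or duplication threshold are merged
into calls. Threshold defaults come from half-copy arithmetic: 0.7 and 1.25
sit near the geometric midpoints between the neutral ratio 1 and the
single-copy loss (0.5) and gain (1.5) ratios, hom deletion at 0.15, with at
least 3 consecutive intervals required; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CnvThresholds:
    het_del: float = 0.7
    hom_del: float = 0.15
    dup: float = 1.25
    min_consecutive: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.hom_del < self.het_del < 1 < self.dup:
            raise ValueError("thresholds must satisfy 0 <= hom_del < het_del < 1 < dup")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


@dataclass(frozen=True)
class CnvCall:
    """A merged run of consecutive same-state intervals in one trio."""

    trio_id: str
    chrom: str
    start: int
    end: int
    first_interval: int
    last_interval: int
    state: str  # het_del | hom_del | dup
    ratio: float  # median depth ratio over the run
    n_intervals: int


def normalize_depths(depth: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by that sample's median interval depth."""
    med = depth.median(axis=0)
    if (med <= 0).any():
        bad = med.index[med <= 0].tolist()
        raise ValueError(f"non-positive median depth for samples: {bad}")
    return depth / med


def depth_ratio(
    depth: pd.DataFrame,
    proband: str,
    father: str,
    mother: str,
    normalized: bool = False,
) -> pd.Series:
    """Per-interval proband/parental depth ratio for one trio.

    Each sample is first normalized by its genome-wide median depth; the
    ratio is the normalized proband depth over the mean of the two
    normalized parental depths. Intervals with zero parental depth are
    masked (NaN) rather than called.
    """
    sub = depth[[proband, father, mother]]
    if not normalized:
        sub = normalize_depths(sub)
    parental = (sub[father] + sub[mother]) / 2.0
    ratio = sub[proband] / parental.where(parental > 0)
    return ratio


def _state(ratio: float, thresholds: CnvThresholds) -> str:
    if np.isnan(ratio):
        return "masked"
    if ratio <= thresholds.hom_del:
        return "hom_del"
    if ratio <= thresholds.het_del:
        return "het_del"
    if ratio >= thresholds.dup:
        return "dup"
    return "neutral"


def call_cnvs(
    intervals: pd.DataFrame,
    ratios: pd.Series,
    trio_id: str,
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[CnvCall]:
    """Merge threshold-crossing interval runs into CNV calls.

    ``intervals`` must be sorted by (chrom, start) and aligned with
    ``ratios``. A run needs at least ``min_consecutive`` same-state
    intervals; masked intervals break runs; calls never overlap.
    """
    df = intervals.copy()
    df["ratio"] = np.asarray(ratios, dtype=float)
    calls: list[CnvCall] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        states = [_state(r, thresholds) for r in sub.ratio]
        i = 0
        n = len(sub)
        while i < n:
            s = states[i]
            j = i
            while j < n and states[j] == s:
                j += 1
            if s in ("het_del", "hom_del", "dup") and j - i >= thresholds.min_consecutive:
                run = sub.iloc[i:j]
                calls.append(
                    CnvCall(
                        trio_id=trio_id,
                        chrom=str(chrom),
                        start=int(run.start.iloc[0]),
                        end=int(run.end.iloc[-1]),
                        first_interval=int(run.interval_id.iloc[0]),
                        last_interval=int(run.interval_id.iloc[-1]),
                        state=s,
                        ratio=float(np.median(run.ratio)),
                        n_intervals=j - i,
                    )
                )
            i = j
    return calls


def call_cohort_cnvs(
    intervals: pd.DataFrame,
    depth: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[CnvCall]:
    """Run the depth-ratio caller for every trio in the sample sheet."""
    norm = normalize_depths(depth)
    calls: list[CnvCall] = []
    for _, row in sample_sheet.iterrows():
        ratios = depth_ratio(norm, row.proband_id, row.father_id, row.mother_id,
                             normalized=True)
        calls.extend(call_cnvs(intervals, ratios, row.trio_id, thresholds))
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    cols = [
        "trio_id", "chrom", "start", "end", "first_interval", "last_interval",
        "state", "ratio", "n_intervals",
    ]
    return pd.DataFrame([vars(c) for c in calls], columns=cols)
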