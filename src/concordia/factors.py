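"""Six categorical covariates of call concordance.

Every merged variant is annotated with one level per factor:

* MAF — population minor allele frequency class: rare (< 0.5 %),
  low (0.5–5 %), common (>= 5 %), or not reported (novel).
* IMPACT — predicted functional-consequence severity (consumed from an
  annotation table; the prediction itself is upstream of this package).
* RMSK — RepeatMasker repeat family at the site, or non-repetitive.
* %GC — local GC content in a window around the site: unbiased (25–60 %)
  vs biased.
* COV — depth of coverage within the per-aligner interquartile range for
  more than 80 % of aligners ("normal") or not.
* MAPQ — mean mapping quality above the per-aligner median for more than
  80 % of aligners ("good") or not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAF_LEVELS = ["common", "low", "rare", "not_reported"]
IMPACT_LEVELS = ["modifier", "low", "moderate", "high"]
REPEAT_LEVELS = [
    "non_repetitive",
    "SINE",
    "LINE",
    "LTR",
    "DNA_repeat",
    "simple_repeat",
    "low_complexity",
    "satellite",
    "RNA_repeat",
    "other_rolling_circle",
    "unknown",
]
GC_LEVELS = ["unbiased", "biased"]
COV_LEVELS = ["normal", "other"]
MAPQ_LEVELS = ["good", "other"]

FACTORS = ["maf", "impact", "repeat", "gc", "cov", "mapq"]
FACTOR_LEVELS: dict[str, list[str]] = {
    "maf": MAF_LEVELS,
    "impact": IMPACT_LEVELS,
    "repeat": REPEAT_LEVELS,
    "gc": GC_LEVELS,
    "cov": COV_LEVELS,
    "mapq": MAPQ_LEVELS,
}
#: reference level of each factor for dummy coding (first of each list)
REFERENCE_LEVELS = {f: levels[0] for f, levels in FACTOR_LEVELS.items()}

MAJORITY_THRESHOLD = 0.8  # "more than 80% of the short-read aligners"


def classify_maf(maf: float | None) -> str:
    """MAF class with closed boundaries at 0.5 % (low) and 5 % (common)."""
    if maf is None or (isinstance(maf, float) and np.isnan(maf)):
        return "not_reported"
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF {maf} outside [0, 1]")
    if maf >= 0.05:
        return "common"
    if maf >= 0.005:
        return "low"
    return "rare"


def gc_fraction(sequence: str, pos: int, window_bp: int) -> float:
    """GC fraction of a window of total width ``window_bp`` centred on a
    1-based position; windows are truncated at contig ends."""
    half = window_bp // 2
    lo = max(0, pos - 1 - half)
    hi = min(len(sequence), lo + window_bp)
    win = sequence[lo:hi].upper()
    if not win:
        raise ValueError(f"empty GC window at position {pos}")
    return (win.count("G") + win.count("C")) / len(win)


def classify_gc(
    sequence: str, pos: int, window_bp: int = 1000,
    lo: float = 0.25, hi: float = 0.60,
) -> str:
    """"unbiased" iff GC fraction lies in [lo, hi] (defaults 25–60 %)."""
    frac = gc_fraction(sequence, pos, window_bp)
    return "unbiased" if lo <= frac <= hi else "biased"


def gc_window_from_library(insert_size: int, read_length: int) -> int:
    """Window-width heuristic ~2 x (insert size + 2 x read length)."""
    return 2 * (insert_size + 2 * read_length)


def classify_repeat(
    pos: int, intervals: Sequence[tuple[int, int, str]]
) -> str:
    """Repeat class of a 1-based position from (start0, end0, class) rows.

    Intervals are 0-based half-open.  When several repeat annotations
    overlap the site, the smallest interval wins; exact ties resolve to the
    lexicographically smallest class name.
    """
    hits = []
    for start, end, cls in intervals:
        if cls not in REPEAT_LEVELS or cls == "non_repetitive":
            raise ValueError(f"unknown repeat class {cls!r}")
        if start <= pos - 1 < end:
            hits.append((end - start, cls))
    if not hits:
        return "non_repetitive"
    return min(hits)[1]


def _majority_vote(in_range: Sequence[bool]) -> bool:
    arr = np.asarray(in_range, dtype=bool)
    if arr.size == 0:
        raise ValueError("at least one aligner track is required")
    return arr.mean() > MAJORITY_THRESHOLD


def classify_coverage(
    depths: Sequence[float | None], quartiles: Sequence[tuple[float, float]]
) -> str:
    """"normal" iff depth lies in the closed [Q1, Q3] for > 80 % of aligners.

    A missing depth counts as out of range for that aligner.
    """
    in_iqr = [
        d is not None and not np.isnan(d) and q1 <= d <= q3
        for d, (q1, q3) in zip(depths, quartiles, strict=True)
    ]
    return "normal" if _majority_vote(in_iqr) else "other"


def classify_mapq(
    mean_mapqs: Sequence[float | None], medians: Sequence[float]
) -> str:
    """"good" iff mean MAPQ strictly exceeds the aligner's median for > 80 %
    of aligners."""
    above = [
        m is not None and not np.isnan(m) and m > med
        for m, med in zip(mean_mapqs, medians, strict=True)
    ]
    return "good" if _majority_vote(above) else "other"


@dataclass
class AlignerTracks:
    """Per-aligner depth and mean-MAPQ at each variant locus.

    ``depth`` and ``mapq`` are (n_variants x n_aligners) arrays (NaN for
    missing).  Quartiles/medians default to being computed over the loci in
    the tracks themselves; genome-wide values may be supplied instead.
    """

    aligners: list[str]
    depth: np.ndarray
    mapq: np.ndarray
    depth_quartiles: list[tuple[float, float]] | None = None
    mapq_medians: list[float] | None = None

    def __post_init__(self) -> None:
        if self.depth_quartiles is None:
            self.depth_quartiles = [
                (
                    float(np.nanpercentile(self.depth[:, j], 25)),
                    float(np.nanpercentile(self.depth[:, j], 75)),
                )
                for j in range(self.depth.shape[1])
            ]
        if self.mapq_medians is None:
            self.mapq_medians = [
                float(np.nanmedian(self.mapq[:, j]))
                for j in range(self.mapq.shape[1])
            ]


def build_profiles(
    positions: Sequence[int],
    chroms: Sequence[str],
    maf: Sequence[float | None],
    impact: Sequence[str],
    repeat_track: Mapping[str, Sequence[tuple[int, int, str]]],
    sequences: Mapping[str, str],
    tracks: AlignerTracks,
    gc_window_bp: int = 1000,
) -> pd.DataFrame:
    """Assemble the per-variant FactorProfile table (one level per factor)."""
    n = len(positions)
    rows = {f: [] for f in FACTORS}
    for i in range(n):
        rows["maf"].append(classify_maf(maf[i]))
        imp = impact[i]
        if imp not in IMPACT_LEVELS:
            raise ValueError(f"unknown impact class {imp!r}")
        rows["impact"].append(imp)
        rows["repeat"].append(
            classify_repeat(positions[i], repeat_track.get(chroms[i], ()))
        )
        rows["gc"].append(
            classify_gc(sequences[chroms[i]], positions[i], gc_window_bp)
        )
        rows["cov"].append(
            classify_coverage(tracks.depth[i], tracks.depth_quartiles)
        )
        rows["mapq"].append(classify_mapq(tracks.mapq[i], tracks.mapq_medians))
    return as_profile_frame(pd.DataFrame(rows))


def as_profile_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce factor columns to fixed-level categoricals, validating levels."""
    out = pd.DataFrame(index=df.index)
    for f in FACTORS:
        cat = pd.Categorical(df[f], categories=FACTOR_LEVELS[f])
        if cat.isna().any() and not pd.isna(df[f]).any():
            bad = set(df[f]) - set(FACTOR_LEVELS[f])
            raise ValueError(f"unknown level(s) {bad} for factor {f!r}")
        out[f] = cat
    return out
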