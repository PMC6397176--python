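"""Benchmarking call sets against a gold standard within callable regions.

Matching is exact key equality (chrom, pos, ref, alt) after left
normalization; genotype agreement is not required for a true positive by
default (a strict-genotype mode is available where genotypes are supplied).
Both aPPV = TP/(TP+FP) and analytical sensitivity = TP/(TP+FN) are
upper-bound estimates: the gold standard does not enumerate every variant
in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .callset_io import RegionSet, VariantKey


@dataclass
class GoldStandard:
    """Gold-standard variant keys, pre-restricted to callable regions."""

    variants: frozenset[VariantKey]
    callable: RegionSet | None = None
    genotypes: Mapping[VariantKey, int] | None = None

    @classmethod
    def from_keys(
        cls,
        keys: Iterable[VariantKey],
        callable_regions: RegionSet | None = None,
        genotypes: Mapping[VariantKey, int] | None = None,
    ) -> "GoldStandard":
        keys = set(keys)
        if callable_regions is not None:
            keys = {
                k
                for k in keys
                if callable_regions.contains(k.chrom, k.pos)
            }
        return cls(
            variants=frozenset(keys),
            callable=callable_regions,
            genotypes=genotypes,
        )

    def restrict_calls(self, calls: set[VariantKey]) -> set[VariantKey]:
        if self.callable is None:
            return set(calls)
        return {k for k in calls if self.callable.contains(k.chrom, k.pos)}


@dataclass
class PerformancePoint:
    cutoff: float
    tp: int
    fp: int
    fn: int

    @property
    def appv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def score_callset(
    calls: set[VariantKey],
    gold: GoldStandard,
    cutoff: float = 0.0,
    strict_genotype: bool = False,
    call_genotypes: Mapping[VariantKey, int] | None = None,
) -> PerformancePoint:
    """TP/FP/FN of a call-key set against the gold standard.

    In strict-genotype mode a key match with a genotype mismatch counts as
    both a false positive and a false negative.
    """
    calls = gold.restrict_calls(calls)
    matched = calls & gold.variants
    if strict_genotype:
        if gold.genotypes is None or call_genotypes is None:
            raise ValueError("strict_genotype requires genotypes on both sides")
        matched = {
            k for k in matched if call_genotypes.get(k) == gold.genotypes.get(k)
        }
    tp = len(matched)
    fp = len(calls) - tp
    fn = len(gold.variants) - tp
    assert tp + fp == len(calls) and tp + fn == len(gold.variants)
    return PerformancePoint(cutoff=cutoff, tp=tp, fp=fp, fn=fn)


def performance_curve(
    scores: Mapping[VariantKey, float],
    gold: GoldStandard,
    cutoff_grid: Sequence[float],
) -> list[PerformancePoint]:
    """One PerformancePoint per cutoff, keeping variants with score >= cutoff."""
    points = []
    for c in cutoff_grid:
        kept = {k for k, s in scores.items() if s >= c}
        points.append(score_callset(kept, gold, cutoff=float(c)))
    return points


def curve_frame(points: Sequence[PerformancePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cutoff": [p.cutoff for p in points],
            "tp": [p.tp for p in points],
            "fp": [p.fp for p in points],
            "fn": [p.fn for p in points],
            "appv": [p.appv for p in points],
            "sensitivity": [p.sensitivity for p in points],
        }
    )


def curve_area(points: Sequence[PerformancePoint]) -> float:
    """Trapezoidal area under the aPPV vs sensitivity curve.

    Points are sorted by sensitivity, points tied on sensitivity collapse
    to their best aPPV, and the curve is extended to sensitivity 0 at the
    aPPV of its most stringent point (constant interpolation, as in
    precision-recall areas), so sweeps whose smallest kept sets differ
    remain comparable.
    """
    best: dict[float, float] = {}
    for p in points:
        if np.isfinite(p.sensitivity) and np.isfinite(p.appv):
            best[p.sensitivity] = max(best.get(p.sensitivity, 0.0), p.appv)
    pts = sorted(best.items())
    if not pts:
        return 0.0
    pts.insert(0, (0.0, pts[0][1]))
    x = np.array([s for s, _ in pts])
    y = np.array([a for _, a in pts])
    return float(np.trapezoid(y, x))


def union_recovery(
    callsets_keys: Sequence[set[VariantKey]], gold: GoldStandard
) -> float:
    """Fraction of gold variants called by at least one pipeline."""
    if not gold.variants:
        return float("nan")
    union: set[VariantKey] = set()
    for ks in callsets_keys:
        union |= ks
    union = gold.restrict_calls(union)
    return len(union & gold.variants) / len(gold.variants)
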