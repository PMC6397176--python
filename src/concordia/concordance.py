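"""Per-variant call concordance and inter-pipeline similarity.

Call concordance (CC) of a variant is the number of pipelines that called
it — genotype code 0 (hom variant) or 1 (het); explicit hom-ref and no-call
both count as "not called".  The concordance rate divides CC by the number
of pipelines compared for that variant type (pipelines that do not support
a type are excluded from its denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .callset_io import HET, HOM_VAR, CallSet, MergedMatrix, VariantKey

CONCORDANT_HOM = "concordant_hom"
CONCORDANT_HET = "concordant_het"
DISCORDANT = "discordant"


@dataclass
class ConcordanceResult:
    """CC counts and rates for every variant of one type."""

    variant_type: str
    n_pipelines: int
    cc: np.ndarray  # int, per variant
    keys: list[VariantKey]

    @property
    def rate(self) -> np.ndarray:
        return self.cc / self.n_pipelines

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [k.chrom for k in self.keys],
                "pos": [k.pos for k in self.keys],
                "ref": [k.ref for k in self.keys],
                "alt": [k.alt for k in self.keys],
                "cc": self.cc,
                "rate": self.rate,
            }
        )


def call_concordance(matrix: MergedMatrix, variant_type: str) -> ConcordanceResult:
    """CC per variant of ``variant_type`` over the supporting pipelines."""
    sub = matrix.by_type(variant_type)
    supporting = sub.pipelines_supporting(variant_type)
    cols = [sub.pipelines.index(p) for p in supporting]
    called = sub.called()[:, cols]
    cc = called.sum(axis=1).astype(int)
    if sub.n_variants and cc.min() < 1:
        raise ValueError(
            "variant with zero calling pipelines violates the merge invariant"
        )
    return ConcordanceResult(
        variant_type=variant_type,
        n_pipelines=len(cols),
        cc=cc,
        keys=sub.keys(),
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    @property
    def scaled_values(self) -> np.ndarray:
        """Off-diagonal min-max rescaling into [0, 1]; diagonal stays 0."""
        off = ~np.eye(len(self.labels), dtype=bool)
        vals = self.values[off]
        lo, hi = vals.min(), vals.max()
        scaled = np.zeros_like(self.values)
        if hi > lo:
            scaled[off] = (self.values[off] - lo) / (hi - lo)
        return scaled

    def to_frame(self, scaled: bool = False) -> pd.DataFrame:
        v = self.scaled_values if scaled else self.values
        return pd.DataFrame(v, index=self.labels, columns=self.labels)


def jaccard_distance(a: set, b: set) -> float:
    """1 - |A∩B|/|A∪B|; two empty sets are at distance 0."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def jaccard_distances(
    matrix: MergedMatrix, extra_sets: list[CallSet] | None = None
) -> DistanceMatrix:
    """Pairwise Jaccard distances between called-key sets.

    Each pipeline column is reduced to its set of called keys; extra call
    sets (e.g. reference catalogues) are appended as additional labels.
    """
    keys = matrix.keys()
    called = matrix.called()
    sets: list[set[VariantKey]] = [
        {keys[i] for i in np.flatnonzero(called[:, j])}
        for j in range(len(matrix.pipelines))
    ]
    labels = list(matrix.pipelines)
    for cs in extra_sets or []:
        labels.append(cs.pipeline_id)
        sets.append(cs.called_keys())
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(sets[i], sets[j])
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# Hierarchical clustering of pipelines on the genotype matrix


@dataclass
class Dendrogram:
    """UPGMA merge tree: (left, right, height) over nested label tuples."""

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def newick(self) -> str:
        node: dict[tuple[str, ...], str] = {(lab,): lab for lab in self.labels}
        height: dict[tuple[str, ...], float] = {(lab,): 0.0 for lab in self.labels}
        for left, right, h in self.merges:
            bl_l = h / 2 - height[left]
            bl_r = h / 2 - height[right]
            merged = tuple(sorted(left + right))
            node[merged] = f"({node[left]}:{bl_l:.6g},{node[right]}:{bl_r:.6g})"
            height[merged] = h / 2
        root = tuple(sorted(self.labels))
        return node[root] + ";"

    def merge_order(self) -> list[frozenset[str]]:
        return [frozenset(left + right) for left, right, _ in self.merges]


def upgma(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Among minimum-distance cluster pairs, the pair whose sorted member-label
    tuples are lexicographically smallest is merged first.
    """
    if len(labels) < 2:
        raise ValueError("clustering requires at least two items")
    clusters: dict[tuple[str, ...], int] = {(lab,): 1 for lab in labels}
    d: dict[frozenset, float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d[frozenset([(labels[i],), (labels[j],)])] = float(dist[i, j])
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        pair, h = best
        a, b = sorted(pair)
        na, nb = clusters.pop(a), clusters.pop(b)
        merged = tuple(sorted(a + b))
        for other in list(clusters):
            da = d.pop(frozenset([a, other]))
            db = d.pop(frozenset([b, other]))
            d[frozenset([merged, other])] = (na * da + nb * db) / (na + nb)
        del d[pair]
        clusters[merged] = na + nb
        merges.append((a, b, h))
    return Dendrogram(labels=list(labels), merges=merges)


def cluster_pipelines(matrix: MergedMatrix) -> Dendrogram:
    """UPGMA on Euclidean distances between pipeline genotype-code columns."""
    if len(matrix.pipelines) < 2:
        raise ValueError("clustering requires at least two pipelines")
    codes = matrix.codes.astype(float)
    gram = codes.T @ codes
    sq = np.diag(gram)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0)
    return upgma(np.sqrt(d2), list(matrix.pipelines))


# ---------------------------------------------------------------------------
# Concordant vs discordant loci


def classify_loci(matrix: MergedMatrix) -> np.ndarray:
    """Label each row concordant_hom / concordant_het / discordant.

    Concordant requires the identical non-reference genotype from *all*
    compared pipelines (those supporting the row's variant type); a single
    no-call, hom-ref, or genotype disagreement makes the locus discordant.
    """
    labels = np.empty(matrix.n_variants, dtype=object)
    vt = matrix.variants["variant_type"].to_numpy()
    support_cols = {
        t: [matrix.pipelines.index(p) for p in matrix.pipelines_supporting(t)]
        for t in np.unique(vt)
    }
    for i in range(matrix.n_variants):
        cells = matrix.codes[i, support_cols[vt[i]]]
        if (cells == HET).all():
            labels[i] = CONCORDANT_HET
        elif (cells == HOM_VAR).all():
            labels[i] = CONCORDANT_HOM
        else:
            labels[i] = DISCORDANT
    return labels


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t-test; (nan, nan) if a group < 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return (float("nan"), float("nan"))
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def compare_groups(matrix: MergedMatrix, classes: np.ndarray) -> pd.DataFrame:
    """Depth and alt allelic-fraction contrasts, concordant vs discordant.

    Per-locus depth is the mean DP over pipelines reporting one; the alt
    allelic fraction is AD[alt]/DP averaged over heterozygous cells with
    both fields.  Rows: one per (metric, comparison) with group means,
    variances, sizes, Welch t and p.
    """
    import warnings

    classes = np.asarray(classes)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        mean_depth = np.nanmean(matrix.depth, axis=1)
        af_cell = np.where(
            (matrix.codes == HET) & np.isfinite(matrix.depth) & (matrix.depth > 0),
            matrix.alt_depth / matrix.depth,
            np.nan,
        )
        mean_af = np.nanmean(af_cell, axis=1)

    conc = (classes == CONCORDANT_HOM) | (classes == CONCORDANT_HET)
    rows = []
    contrasts = [
        ("depth", mean_depth, conc, classes == DISCORDANT, "concordant_vs_discordant"),
        (
            "depth",
            mean_depth,
            classes == CONCORDANT_HOM,
            classes == DISCORDANT,
            "concordant_hom_vs_discordant",
        ),
        (
            "depth",
            mean_depth,
            classes == CONCORDANT_HET,
            classes == DISCORDANT,
            "concordant_het_vs_discordant",
        ),
        (
            "alt_fraction",
            mean_af,
            classes == CONCORDANT_HET,
            classes == DISCORDANT,
            "concordant_het_vs_discordant",
        ),
    ]
    for metric, values, g1, g2, name in contrasts:
        x = values[g1 & np.isfinite(values)]
        y = values[g2 & np.isfinite(values)]
        t, p = welch_t(x, y)
        rows.append(
            {
                "metric": metric,
                "comparison": name,
                "mean_concordant": x.mean() if len(x) else np.nan,
                "mean_discordant": y.mean() if len(y) else np.nan,
                "var_concordant": x.var(ddof=1) if len(x) > 1 else np.nan,
                "var_discordant": y.var(ddof=1) if len(y) > 1 else np.nan,
                "n_concordant": len(x),
                "n_discordant": len(y),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
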