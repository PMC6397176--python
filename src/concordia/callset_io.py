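"""Reading, normalizing, and merging per-pipeline variant call sets.

Variants are identified by ``(chrom, pos, ref, alt)`` after biallelic
splitting and indel left-normalization, so that the same event reported by
different pipelines collapses to a single key.  Genotypes are recoded to the
reference-allele-count convention used throughout the package:

======  ==========================
code    meaning
======  ==========================
0       homozygous variant
1       heterozygous variant
2       homozygous reference
3       no-call / not reported
======  ==========================

A variant is "called" by a pipeline iff its code is 0 or 1.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SNP = "SNP"
INDEL = "indel"

HOM_VAR, HET, HOM_REF, NO_CALL = 0, 1, 2, 3

_ACGT = re.compile(r"^[ACGT]+$")


class VariantKey(NamedTuple):
    """Biallelic variant identity: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def variant_type(self) -> str:
        return SNP if len(self.ref) == 1 and len(self.alt) == 1 else INDEL


@dataclass(frozen=True)
class CallRecord:
    key: VariantKey
    genotype_code: int
    depth: int | None = None
    allele_depths: tuple[int, int] | None = None  # (ref depth, alt depth)

    @property
    def alt_fraction(self) -> float | None:
        """AD[alt]/DP; None unless both DP and AD are present and DP > 0."""
        if self.depth is None or self.allele_depths is None or self.depth <= 0:
            return None
        return self.allele_depths[1] / self.depth


@dataclass
class CallSet:
    """All calls from one aligner+caller pipeline, unique per VariantKey."""

    pipeline_id: str
    records: dict[VariantKey, CallRecord] = field(default_factory=dict)
    supports: frozenset[str] = frozenset({SNP, INDEL})

    def called_keys(self) -> set[VariantKey]:
        return {
            k
            for k, r in self.records.items()
            if r.genotype_code in (HOM_VAR, HET)
        }

    def add(self, record: CallRecord) -> None:
        self.records[record.key] = record


class VcfParseError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


def _is_bgzf(path: str) -> bool:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    return magic == b"\x1f\x8b\x08\x04"


def _code_from_gt(alleles: tuple, alt_index: int) -> int:
    """Recode a GT tuple against one specific alt allele.

    Half-calls (any missing allele) are treated as no-call.  Haploid calls
    (e.g. hemizygous X) map to the homozygous codes.  A genotype carrying a
    *different* alt allele but not this one is a no-call for this key.
    """
    if len(alleles) == 0 or any(a is None for a in alleles):
        return NO_CALL
    n_alt = sum(a == alt_index for a in alleles)
    if n_alt == len(alleles):
        return HOM_VAR
    if n_alt >= 1:
        return HET
    if all(a == 0 for a in alleles):
        return HOM_REF
    return NO_CALL


def read_callset(
    vcf_source: str,
    pipeline_id: str,
    supports: Iterable[str] = (SNP, INDEL),
) -> CallSet:
    """Read a single-sample VCF (v4.2, optionally gzipped) into a CallSet.

    Multiallelic records are split into one biallelic key per ALT allele,
    with the genotype code recomputed per alt.  Missing DP/AD stay missing.
    Symbolic or non-ACGT alleles are skipped (counted in the log).
    """
    cs = CallSet(pipeline_id=pipeline_id, supports=frozenset(supports))
    n_skipped_alleles = 0
    n_split = 0
    n_missing_gt = 0
    tmp = None
    path = str(vcf_source)
    if path.endswith(".gz") and not _is_bgzf(path):
        # htslib cannot seek in plain gzip; stream-decompress first
        import tempfile

        tmp = tempfile.NamedTemporaryFile(
            mode="wt", suffix=".vcf", delete=False
        )
        with gzip.open(path, "rt") as fh:
            tmp.write(fh.read())
        tmp.close()
        path = tmp.name
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_source!r}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise VcfParseError(
                f"{vcf_source!r}: expected one sample column, found {len(samples)}"
            )
        sample = samples[0]
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                n_split += 1
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in (gt or (None,))):
                if gt is None:
                    n_missing_gt += 1
            dp = call.get("DP")
            ad = call.get("AD")
            for ai, alt in enumerate(alts, start=1):
                if alt is None or not _ACGT.match(str(alt)):
                    n_skipped_alleles += 1
                    continue
                ref = str(rec.ref).upper()
                if not _ACGT.match(ref):
                    n_skipped_alleles += 1
                    continue
                if ref == str(alt).upper():
                    n_skipped_alleles += 1
                    continue
                key = VariantKey(str(rec.chrom), int(rec.pos), ref, str(alt).upper())
                code = NO_CALL if gt is None else _code_from_gt(tuple(gt), ai)
                depths = None
                if ad is not None and len(ad) > ai and ad[0] is not None and ad[ai] is not None:
                    depths = (int(ad[0]), int(ad[ai]))
                cs.add(
                    CallRecord(
                        key=key,
                        genotype_code=code,
                        depth=int(dp) if dp is not None else None,
                        allele_depths=depths,
                    )
                )
    if tmp is not None:
        import os

        os.unlink(tmp.name)
    if n_missing_gt:
        logger.warning(
            "%s: %d records lacked GT; treated as no-call", pipeline_id, n_missing_gt
        )
    if n_skipped_alleles or n_split:
        logger.info(
            "%s: split %d multiallelic records, skipped %d non-ACGT/degenerate alleles",
            pipeline_id,
            n_split,
            n_skipped_alleles,
        )
    return cs


def left_normalize(
    key: VariantKey, fetch_base: Callable[[str, int], str]
) -> VariantKey:
    """Shift an indel to its leftmost parsimonious representation.

    ``fetch_base(chrom, pos)`` must return the uppercase reference base at a
    1-based position.  SNPs are returned unchanged.  The algorithm is the
    standard one: truncate shared trailing bases (extending left from the
    reference when an allele would empty), then trim shared leading bases.
    """
    if key.variant_type == SNP:
        _check_reference(key, fetch_base)
        return key
    _check_reference(key, fetch_base)
    chrom, pos = key.chrom, key.pos
    ref, alt = key.ref, key.alt
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos <= 1:
                raise ReferenceMismatchError(
                    f"cannot left-extend {key} past the contig start"
                )
            pos -= 1
            base = fetch_base(chrom, pos).upper()
            ref, alt = base + ref, base + alt
            changed = True
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def _check_reference(key: VariantKey, fetch_base: Callable[[str, int], str]) -> None:
    for i, base in enumerate(key.ref):
        got = fetch_base(key.chrom, key.pos + i).upper()
        if got != base:
            raise ReferenceMismatchError(
                f"{key}: ref allele base {base!r} at {key.chrom}:{key.pos + i} "
                f"disagrees with reference base {got!r}"
            )


def fasta_fetcher(sequences: Mapping[str, str]) -> Callable[[str, int], str]:
    """Adapt a {contig: sequence} mapping to a 1-based base fetcher."""

    def fetch(chrom: str, pos: int) -> str:
        return sequences[chrom][pos - 1]

    return fetch


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA into memory as {name: uppercase sequence}."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


# ---------------------------------------------------------------------------
# Regions


class RegionSet:
    """Per-chromosome sorted, non-overlapping half-open 0-based intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._ivs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in intervals.items():
            arr = sorted((int(s), int(e)) for s, e in pairs if int(e) > int(s))
            merged: list[list[int]] = []
            for s, e in arr:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            if merged:
                m = np.asarray(merged)
                self._ivs[chrom] = (m[:, 0], m[:, 1])

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#", dtype={0: str},
        )
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            out[str(chrom)] = list(zip(sub["start"], sub["end"]))
        return cls(out)

    def contains(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based position (converted to 0-based internally)."""
        return bool(self.contains_many(np.asarray([chrom]), np.asarray([pos1]))[0])

    def contains_many(self, chroms: np.ndarray, pos1: np.ndarray) -> np.ndarray:
        res = np.zeros(len(pos1), dtype=bool)
        p0 = np.asarray(pos1, dtype=np.int64) - 1
        for chrom in np.unique(chroms):
            starts_ends = self._ivs.get(str(chrom))
            mask = chroms == chrom
            if starts_ends is None:
                continue
            starts, ends = starts_ends
            idx = np.searchsorted(starts, p0[mask], side="right") - 1
            ok = (idx >= 0) & (p0[mask] < ends[np.clip(idx, 0, None)])
            res[mask] = ok
        return res

    def total_length(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self._ivs.values())
        )

    def chroms(self) -> list[str]:
        return list(self._ivs)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._ivs:
            return []
        starts, ends = self._ivs[chrom]
        return [(int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Merged matrix


@dataclass
class MergedMatrix:
    """Variants x pipelines genotype-code matrix with per-cell DP/AD."""

    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, variant_type
    pipelines: list[str]
    codes: np.ndarray  # (n_variants, n_pipelines) int8
    depth: np.ndarray  # float, NaN = missing
    alt_depth: np.ndarray  # float, NaN = missing
    support: dict[str, frozenset[str]]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(
                self.variants["chrom"],
                self.variants["pos"],
                self.variants["ref"],
                self.variants["alt"],
            )
        ]

    def called(self) -> np.ndarray:
        """Boolean (variants x pipelines) mask of code in {0, 1}."""
        return (self.codes == HOM_VAR) | (self.codes == HET)

    def pipelines_supporting(self, variant_type: str) -> list[str]:
        return [p for p in self.pipelines if variant_type in self.support[p]]

    def subset_rows(self, mask: np.ndarray) -> "MergedMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MergedMatrix(
            variants=self.variants.loc[mask].reset_index(drop=True),
            pipelines=list(self.pipelines),
            codes=self.codes[mask],
            depth=self.depth[mask],
            alt_depth=self.alt_depth[mask],
            support=dict(self.support),
        )

    def by_type(self, variant_type: str) -> "MergedMatrix":
        return self.subset_rows(
            (self.variants["variant_type"] == variant_type).to_numpy()
        )


def merge_callsets(callsets: Sequence[CallSet]) -> MergedMatrix:
    """Union per-pipeline call sets into one matrix keyed by VariantKey.

    Rows are the keys called (code 0/1) by at least one pipeline; cells with
    no record at the key are no-call (3); explicit hom-ref records (2) are
    retained where a pipeline reported them.
    """
    if len(callsets) < 2:
        raise ValueError("merge requires at least two call sets")
    ids = [cs.pipeline_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate pipeline_id among {ids}")

    union: set[VariantKey] = set()
    for cs in callsets:
        union |= cs.called_keys()
    keys = sorted(union, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))
    index = {k: i for i, k in enumerate(keys)}

    n, p = len(keys), len(callsets)
    codes = np.full((n, p), NO_CALL, dtype=np.int8)
    depth = np.full((n, p), np.nan)
    alt_depth = np.full((n, p), np.nan)
    for j, cs in enumerate(callsets):
        for key, rec in cs.records.items():
            i = index.get(key)
            if i is None:
                continue
            codes[i, j] = rec.genotype_code
            if rec.depth is not None:
                depth[i, j] = rec.depth
            if rec.allele_depths is not None:
                alt_depth[i, j] = rec.allele_depths[1]

    variants = pd.DataFrame(
        {
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "ref": [k.ref for k in keys],
            "alt": [k.alt for k in keys],
            "variant_type": [k.variant_type for k in keys],
        }
    )
    return MergedMatrix(
        variants=variants,
        pipelines=ids,
        codes=codes,
        depth=depth,
        alt_depth=alt_depth,
        support={cs.pipeline_id: cs.supports for cs in callsets},
    )


def merged_to_tsv(matrix: MergedMatrix, path: str) -> None:
    """Serialize a MergedMatrix to TSV (one code/depth/altdp column per
    pipeline; variant-type support flags on a leading ## header line)."""
    import json as _json

    df = matrix.variants.copy()
    for j, pid in enumerate(matrix.pipelines):
        df[f"code:{pid}"] = matrix.codes[:, j]
        df[f"depth:{pid}"] = matrix.depth[:, j]
        df[f"altdp:{pid}"] = matrix.alt_depth[:, j]
    support = {p: sorted(matrix.support[p]) for p in matrix.pipelines}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        out.write("##support=" + _json.dumps(support) + "\n")
        df.to_csv(out, sep="\t", index=False)


def merged_from_tsv(path: str) -> MergedMatrix:
    import json as _json

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##support="):
            raise VcfParseError(f"{path!r}: missing ##support header line")
        support = {
            p: frozenset(v) for p, v in _json.loads(first[len("##support=") :]).items()
        }
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    pipelines = [c[len("code:") :] for c in df.columns if c.startswith("code:")]
    codes = np.column_stack(
        [df[f"code:{p}"].to_numpy(dtype=np.int8) for p in pipelines]
    )
    depth = np.column_stack([df[f"depth:{p}"].to_numpy(float) for p in pipelines])
    alt_depth = np.column_stack([df[f"altdp:{p}"].to_numpy(float) for p in pipelines])
    return MergedMatrix(
        variants=df[["chrom", "pos", "ref", "alt", "variant_type"]].copy(),
        pipelines=pipelines,
        codes=codes,
        depth=depth,
        alt_depth=alt_depth,
        support=support,
    )


def restrict_to_regions(matrix: MergedMatrix, regions: RegionSet) -> MergedMatrix:
    """Keep rows whose (1-based) position falls inside the region set."""
    mask = regions.contains_many(
        matrix.variants["chrom"].to_numpy(), matrix.variants["pos"].to_numpy()
    )
    return matrix.subset_rows(mask)


def _chrom_sort_key(chrom: str):
    """Natural chromosome ordering: numeric first, then X, Y, MT, others."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (0, special[c], "")
    return (1, 0, chrom)


def write_filtered_vcf(
    matrix: MergedMatrix,
    keep: set[VariantKey],
    sink: str,
    scores: Mapping[VariantKey, float] | None = None,
    source: str = "concordia",
) -> None:
    """Write the kept keys as a minimal single-sample VCF v4.2.

    The consensus genotype is the majority code among calling pipelines
    (ties go to heterozygous); the per-variant score, when given, is stored
    in INFO/SCORE.  Records are sorted by chromosome (natural order, falling
    back to lexicographic) then position.
    """
    keys = matrix.keys()
    unknown = keep - set(keys)
    if unknown:
        raise ValueError(f"{len(unknown)} keys to keep are not in the matrix")
    called = matrix.called()
    rows = []
    for i, key in enumerate(keys):
        if key not in keep:
            continue
        cells = matrix.codes[i][called[i]]
        gt = "1/1" if (cells == HOM_VAR).sum() > (cells == HET).sum() else "0/1"
        info = "."
        if scores is not None and key in scores:
            info = f"SCORE={scores[key]:.6g}"
        rows.append((key, info, gt))
    rows.sort(key=lambda r: (_chrom_sort_key(r[0].chrom), r[0].pos, r[0].ref, r[0].alt))

    opener = gzip.open if str(sink).endswith(".gz") else open
    with opener(sink, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source={source}\n")
        out.write(
            '##INFO=<ID=SCORE,Number=1,Type=Float,'
            'Description="Ensemble filtering score">\n'
        )
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r[0].chrom for r in rows):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tENSEMBLE\n")
        for key, info, gt in rows:
            out.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )
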