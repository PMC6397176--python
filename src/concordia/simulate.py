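"""Synthetic truth sets, pipeline call sets, and covariates.

The generator emulates the statistical structure the analysis assumes,
without simulating reads:

* a random reference contig, with GC-rich windows planted around loci
  labelled GC-biased;
* candidate loci split into true variants and error-prone (false-positive)
  loci, each with six factor covariates whose distributions differ between
  the two classes (errors skew toward rare/novel MAF, repeats, biased GC,
  abnormal coverage, and poor MAPQ);
* per-pipeline call sets: a pipeline calls a locus with a probability that
  multiplies a base rate (high for truth, low for errors) by per-factor
  concordance rate ratios, plus shared caller-family and aligner random
  effects on the logit scale.  The caller effect dominates, so call sets
  sharing a caller resemble each other more than call sets sharing an
  aligner, and the resulting call-concordance histogram is bimodal;
* per-aligner depth and mean-MAPQ tracks consistent with the sampled
  coverage/MAPQ classes, and a callable BED covering a configured fraction
  of the contig.

Three entry points serve different tests: :func:`simulate_bundle` (the full
pipeline emulation), :func:`simulate_regression_data` (counts drawn exactly
from the log-link count model with known rate ratios), and
:func:`sample_mixture` (draws from a known two-component CC + factors
mixture).  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .callset_io import (
    HET,
    HOM_VAR,
    INDEL,
    SNP,
    CallRecord,
    CallSet,
    RegionSet,
    VariantKey,
    fasta_fetcher,
    left_normalize,
)
from .evaluation import GoldStandard
from .factors import FACTOR_LEVELS, FACTORS, AlignerTracks

_BASES = np.array(list("ACGT"))


def _default_truth_freqs() -> dict[str, dict[str, float]]:
    return {
        "maf": {"common": 0.65, "low": 0.20, "rare": 0.10, "not_reported": 0.05},
        "impact": {"modifier": 0.90, "low": 0.05, "moderate": 0.04, "high": 0.01},
        "repeat": {
            "non_repetitive": 0.72,
            "SINE": 0.10,
            "LINE": 0.06,
            "LTR": 0.02,
            "DNA_repeat": 0.01,
            "simple_repeat": 0.04,
            "low_complexity": 0.03,
            "satellite": 0.005,
            "RNA_repeat": 0.002,
            "other_rolling_circle": 0.002,
            "unknown": 0.001,
        },
        "gc": {"unbiased": 0.85, "biased": 0.15},
        "cov": {"normal": 0.80, "other": 0.20},
        "mapq": {"good": 0.80, "other": 0.20},
    }


def _default_error_freqs() -> dict[str, dict[str, float]]:
    freqs = _default_truth_freqs()
    freqs["maf"] = {"common": 0.15, "low": 0.10, "rare": 0.30, "not_reported": 0.45}
    # impact is left identical to the truth class on purpose: it carries no
    # information about calling errors, mirroring its non-association for
    # indels, and lets variable selection drop it.
    freqs["repeat"] = {
        "non_repetitive": 0.40,
        "SINE": 0.12,
        "LINE": 0.08,
        "LTR": 0.03,
        "DNA_repeat": 0.02,
        "simple_repeat": 0.15,
        "low_complexity": 0.10,
        "satellite": 0.06,
        "RNA_repeat": 0.015,
        "other_rolling_circle": 0.015,
        "unknown": 0.01,
    }
    freqs["gc"] = {"unbiased": 0.60, "biased": 0.40}
    freqs["cov"] = {"normal": 0.45, "other": 0.55}
    freqs["mapq"] = {"good": 0.40, "other": 0.60}
    return freqs


def _default_rate_ratios() -> dict[str, dict[str, float]]:
    """Per-level multipliers on the call probability (reference level 1.0)."""
    return {
        "maf": {"low": 0.90, "rare": 0.40, "not_reported": 0.15},
        "impact": {"low": 0.97, "moderate": 0.92, "high": 0.70},
        "repeat": {
            "SINE": 0.90,
            "LINE": 0.92,
            "LTR": 0.92,
            "DNA_repeat": 0.92,
            "simple_repeat": 0.75,
            "low_complexity": 0.80,
            "satellite": 0.55,
            "RNA_repeat": 0.90,
            "other_rolling_circle": 0.85,
            "unknown": 0.90,
        },
        "gc": {"biased": 0.85},
        "cov": {"other": 0.85},
        "mapq": {"other": 0.60},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle (defaults are the
    desk-scale conditions every test runs under)."""

    n_variants: int = 2000  # candidate loci (truth + error-prone)
    true_fraction: float = 0.7
    snp_fraction: float = 0.8
    n_aligners: int = 3
    n_callers: int = 2
    genome_length: int = 1_000_000
    contig: str = "chr1"
    callable_fraction: float = 0.93
    callable_window: int = 5000
    base_sensitivity: float = 0.95  # truth call prob at reference levels
    fp_call_prob: float = 0.18  # error-locus call prob at reference levels
    caller_sd: float = 1.8  # shared per-variant caller-family logit effect
    aligner_sd: float = 0.7
    truth_effect_scale: float = 0.35  # attenuation of shared effects on truth
    genotype_error_rate: float = 0.02
    het_fraction: float = 0.6
    depth_mean_true: float = 40.0
    depth_mean_error: float = 22.0
    gc_window_bp: int = 1000
    noindel_callers: tuple[str, ...] = ()
    truth_freqs: dict = field(default_factory=_default_truth_freqs)
    error_freqs: dict = field(default_factory=_default_error_freqs)
    rate_ratios: dict = field(default_factory=_default_rate_ratios)

    def pipeline_ids(self) -> list[tuple[str, str, str]]:
        """(pipeline_id, aligner, caller) triples."""
        out = []
        for a in self.aligners():
            for c in self.callers():
                out.append((f"{a}+{c}", a, c))
        return out

    def aligners(self) -> list[str]:
        return [f"ALN{i + 1}" for i in range(self.n_aligners)]

    def callers(self) -> list[str]:
        return [f"VCA{i + 1}" for i in range(self.n_callers)]


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    seed: int
    sequences: dict[str, str]
    candidates: pd.DataFrame  # key fields, is_true, genotype, maf, factors
    truth: GoldStandard
    callsets: list[CallSet]
    tracks: AlignerTracks
    callable: RegionSet

    def profiles(self) -> pd.DataFrame:
        from .factors import as_profile_frame

        return as_profile_frame(self.candidates[FACTORS])


def _sample_levels(rng, n: int, freqs: dict[str, float], levels: list[str]):
    p = np.array([freqs.get(lvl, 0.0) for lvl in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _maf_value(rng, cls: str) -> float:
    if cls == "common":
        return float(rng.uniform(0.05, 0.5))
    if cls == "low":
        return float(rng.uniform(0.005, 0.05))
    if cls == "rare":
        return float(rng.uniform(1e-4, 0.005))
    return float("nan")


def simulate_truth(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Candidate loci (true + error-prone) with covariates, plus reference.

    Returns the candidate table — key fields, ``is_true``, genotype code,
    numeric MAF, and one column per factor — and the synthetic reference
    sequences.  Indel keys are left-normalized against the reference so the
    whole bundle shares one representation.
    """
    rng = np.random.default_rng(seed)
    L = config.genome_length
    n = config.n_variants
    if n * 20 > L:
        raise ValueError("n_variants exceeds genome capacity")
    seq = rng.choice(4, size=L, p=[0.275, 0.225, 0.225, 0.275]).astype(np.uint8)

    pos = np.sort(rng.choice(np.arange(20, L - 20), size=n, replace=False))
    is_true = rng.random(n) < config.true_fraction
    is_snp = rng.random(n) < config.snp_fraction

    levels = {f: np.empty(n, dtype=object) for f in FACTORS}
    for f in FACTORS:
        lv = FACTOR_LEVELS[f]
        t_idx = np.flatnonzero(is_true)
        e_idx = np.flatnonzero(~is_true)
        levels[f][t_idx] = _sample_levels(rng, len(t_idx), config.truth_freqs[f], lv)
        levels[f][e_idx] = _sample_levels(rng, len(e_idx), config.error_freqs[f], lv)

    # plant GC-rich windows around loci labelled biased
    half = config.gc_window_bp // 2
    for i in np.flatnonzero(levels["gc"] == "biased"):
        lo, hi = max(0, pos[i] - half), min(L, pos[i] + half)
        width = hi - lo
        gc_rich = rng.choice(4, size=width, p=[0.10, 0.40, 0.40, 0.10])
        seq[lo:hi] = gc_rich.astype(np.uint8)

    sequence = np.frombuffer(b"ACGT", dtype=np.uint8)[seq].tobytes().decode("ascii")
    sequences = {config.contig: sequence}
    fetch = fasta_fetcher(sequences)

    rows = []
    seen: set[VariantKey] = set()
    for i in range(n):
        p1 = int(pos[i]) + 1  # 1-based
        ref_base = sequence[p1 - 1]
        if is_snp[i]:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            key = VariantKey(config.contig, p1, ref_base, alt)
        else:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                ref = sequence[p1 - 1 : p1 + length]
                key = VariantKey(config.contig, p1, ref, ref_base)
            else:  # insertion
                ins = "".join(rng.choice(_BASES, size=length))
                key = VariantKey(config.contig, p1, ref_base, ref_base + ins)
            key = left_normalize(key, fetch)
        if key in seen:
            continue
        seen.add(key)
        geno = HET if rng.random() < config.het_fraction else HOM_VAR
        rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "variant_type": key.variant_type,
                "is_true": bool(is_true[i]),
                "genotype": geno,
                "maf_value": _maf_value(rng, levels["maf"][i]),
                **{f: levels[f][i] for f in FACTORS},
            }
        )
    return pd.DataFrame(rows), sequences


def _call_probability(
    cand: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Per-locus call probability before the shared random effects.

    Factor rate ratios act additively on the log-odds of a call, so a mild
    multiplier barely moves an easy (p near 1) true variant but pushes an
    already-unlikely error locus further down — pooled over both classes
    this reproduces the compositional concordance effects (rare/novel
    variants are mostly errors and land at low CC).
    """
    base = np.where(cand["is_true"], config.base_sensitivity, config.fp_call_prob)
    with np.errstate(divide="ignore"):
        logit = np.log(base) - np.log1p(-base)  # +-inf at the 0/1 limits
        for f in FACTORS:
            rr = config.rate_ratios.get(f, {})
            logit += np.log(np.array([rr.get(lvl, 1.0) for lvl in cand[f]]))
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-logit))


def simulate_pipeline_calls(
    candidates: pd.DataFrame, config: SimulationConfig, seed: int
) -> list[CallSet]:
    """Per-pipeline call sets with caller-dominant correlation.

    The call probability of pipeline (aligner a, caller c) at locus v is
    ``sigmoid(logit(p_v) + eps_cv + eps_av)`` with eps_cv ~ N(0, caller_sd)
    shared by all pipelines using caller c, and eps_av ~ N(0, aligner_sd)
    shared within an aligner; both effects are attenuated by
    ``truth_effect_scale`` on true variants, since pipelines agree on easy
    true calls and diverge mostly at difficult/error loci.  DP is Poisson,
    AD binomial around 0.5 for hets; genotypes are flipped het<->hom at the
    configured error rate.
    """
    rng = np.random.default_rng(seed)
    n = len(candidates)
    p_v = _call_probability(candidates, config)
    with np.errstate(divide="ignore"):
        logit = np.log(p_v) - np.log1p(-p_v)
    w = np.where(candidates["is_true"], config.truth_effect_scale, 1.0)
    eps_caller = {
        c: rng.normal(0.0, config.caller_sd, size=n) * w for c in config.callers()
    }
    eps_aligner = {
        a: rng.normal(0.0, config.aligner_sd, size=n) * w for a in config.aligners()
    }
    keys = [
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        for r in candidates.itertuples()
    ]
    geno = candidates["genotype"].to_numpy()
    is_true = candidates["is_true"].to_numpy()
    depth_mean = np.where(
        is_true, config.depth_mean_true, config.depth_mean_error
    )
    is_indel = candidates["variant_type"].to_numpy() == INDEL

    callsets = []
    for pid, aligner, caller in config.pipeline_ids():
        supports = (
            frozenset({SNP})
            if caller in config.noindel_callers
            else frozenset({SNP, INDEL})
        )
        with np.errstate(over="ignore"):
            prob = 1.0 / (
                1.0 + np.exp(-(logit + eps_caller[caller] + eps_aligner[aligner]))
            )
        called = rng.random(n) < prob
        if caller in config.noindel_callers:
            called &= ~is_indel
        cs = CallSet(pipeline_id=pid, supports=supports)
        for i in np.flatnonzero(called):
            g = int(geno[i])
            if rng.random() < config.genotype_error_rate:
                g = HOM_VAR if g == HET else HET
            dp = max(1, int(rng.poisson(depth_mean[i])))
            if g == HET:
                alt_d = int(rng.binomial(dp, 0.5))
            else:
                alt_d = dp
            cs.add(
                CallRecord(
                    key=keys[i],
                    genotype_code=g,
                    depth=dp,
                    allele_depths=(dp - alt_d, alt_d),
                )
            )
        callsets.append(cs)
    return callsets


def simulate_tracks(
    candidates: pd.DataFrame, config: SimulationConfig, seed: int
) -> AlignerTracks:
    """Per-aligner depth / mean-MAPQ consistent with the sampled classes."""
    rng = np.random.default_rng(seed)
    n = len(candidates)
    k = config.n_aligners
    normal_cov = (candidates["cov"] == "normal").to_numpy()
    good_mapq = (candidates["mapq"] == "good").to_numpy()
    depth = np.where(
        normal_cov[:, None],
        rng.normal(40.0, 2.0, size=(n, k)),
        40.0 + rng.choice([-1, 1], size=(n, k)) * rng.uniform(12, 25, size=(n, k)),
    )
    depth = np.clip(np.round(depth), 0, None)
    mapq = np.where(
        good_mapq[:, None],
        50.0 + rng.uniform(2, 8, size=(n, k)),
        50.0 - rng.uniform(2, 8, size=(n, k)),
    )
    return AlignerTracks(
        aligners=config.aligners(),
        depth=depth,
        mapq=mapq,
        depth_quartiles=[(30.0, 50.0)] * k,
        mapq_medians=[50.0] * k,
    )


def simulate_callable(config: SimulationConfig, seed: int) -> RegionSet:
    """Callable BED covering ~``callable_fraction`` of the contig, built by
    keeping a fixed number of fixed-width windows."""
    rng = np.random.default_rng(seed)
    n_windows = config.genome_length // config.callable_window
    n_keep = int(round(config.callable_fraction * n_windows))
    keep = np.sort(rng.choice(n_windows, size=n_keep, replace=False))
    w = config.callable_window
    return RegionSet({config.contig: [(int(i) * w, (int(i) + 1) * w) for i in keep]})


def simulate_bundle(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedBundle:
    """Full synthetic study: truth, call sets, tracks, callable regions."""
    config = config or SimulationConfig()
    candidates, sequences = simulate_truth(config, seed)
    callsets = simulate_pipeline_calls(candidates, config, seed + 1)
    tracks = simulate_tracks(candidates, config, seed + 2)
    callable_regions = simulate_callable(config, seed + 3)
    truth_keys = [
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        for r in candidates.itertuples()
        if r.is_true
    ]
    truth = GoldStandard.from_keys(truth_keys, callable_regions)
    return SimulatedBundle(
        config=config,
        seed=seed,
        sequences=sequences,
        candidates=candidates,
        truth=truth,
        callsets=callsets,
        tracks=tracks,
        callable=callable_regions,
    )


# ---------------------------------------------------------------------------
# Exact-model generators for parameter-recovery experiments


def simulate_regression_data(
    n: int,
    seed: int,
    rate_ratios: dict[str, dict[str, float]] | None = None,
    intercept_mean: float = 40.0,
    theta: float | None = 4.0,
    level_freqs: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Profiles plus CC counts drawn from the log-link count model itself.

    mu = intercept_mean * prod(rate ratio of each sampled level); CC is
    negative binomial with dispersion ``theta`` (Poisson when theta is
    None).  Zero counts are lifted to 1, matching the merge invariant that
    every variant was called at least once.
    """
    rng = np.random.default_rng(seed)
    rate_ratios = rate_ratios or _default_rate_ratios()
    freqs = level_freqs or _default_truth_freqs()
    profiles = pd.DataFrame(
        {
            f: _sample_levels(rng, n, freqs[f], FACTOR_LEVELS[f])
            for f in FACTORS
        }
    )
    mu = np.full(n, intercept_mean)
    for f in FACTORS:
        rr = rate_ratios.get(f, {})
        mu *= np.array([rr.get(lvl, 1.0) for lvl in profiles[f]])
    if theta is None:
        cc = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=theta, scale=mu / theta)
        cc = rng.poisson(lam)
    return profiles, np.maximum(cc, 1)


DEFAULT_MIXTURE_TABLES: dict[str, np.ndarray] = {
    # rows: (true component, error component); columns follow FACTOR_LEVELS
    "maf": np.array(
        [[0.65, 0.20, 0.10, 0.05], [0.15, 0.10, 0.30, 0.45]]
    ),
    "repeat": np.array(
        [
            [0.72, 0.10, 0.06, 0.02, 0.01, 0.04, 0.03, 0.005, 0.002, 0.002, 0.001],
            [0.40, 0.12, 0.08, 0.03, 0.02, 0.15, 0.10, 0.06, 0.015, 0.015, 0.01],
        ]
    ),
    "gc": np.array([[0.85, 0.15], [0.60, 0.40]]),
    "cov": np.array([[0.80, 0.20], [0.45, 0.55]]),
    "mapq": np.array([[0.80, 0.20], [0.40, 0.60]]),
}


def sample_mixture(
    n: int,
    seed: int,
    weights: tuple[float, float] = (0.65, 0.35),
    means: tuple[float, float] = (60.0, 6.0),
    sds: tuple[float, float] = (6.0, 4.0),
    tables: dict[str, np.ndarray] | None = None,
    cc_max: int = 70,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw features from a known two-component mixture.

    CC is Gaussian per component, rounded to an integer and clipped into
    [1, cc_max] (a 70-pipeline panel by default); categorical factors are
    drawn from per-component tables.  Returns (features, component labels);
    component 0 is the true-variant component.
    """
    rng = np.random.default_rng(seed)
    if tables is None:
        tables = DEFAULT_MIXTURE_TABLES
    z = (rng.random(n) >= weights[0]).astype(int)  # 0 = true component
    cc = rng.normal(np.take(means, z), np.take(sds, z))
    cc = np.clip(np.round(cc), 1, cc_max)
    data: dict[str, np.ndarray] = {"cc": cc}
    for f, tab in tables.items():
        lv = FACTOR_LEVELS[f]
        vals = np.empty(n, dtype=object)
        for comp in (0, 1):
            idx = np.flatnonzero(z == comp)
            p = np.asarray(tab[comp], dtype=float)
            vals[idx] = rng.choice(lv, size=len(idx), p=p / p.sum())
        data[f] = vals
    return pd.DataFrame(data), z


# ---------------------------------------------------------------------------
# Bundle serialization


def write_bundle(bundle: SimulatedBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures (VCFs, BED, FASTA, TSVs).

    Re-reading the per-pipeline VCFs through callset_io reproduces the
    in-memory call sets on keys and genotype codes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fa = directory / "reference.fa"
    with open(fa, "w") as out:
        for name, seq in bundle.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
    paths["reference"] = fa

    bed = directory / "callable.bed"
    with open(bed, "w") as out:
        for chrom in bundle.callable.chroms():
            for s, e in bundle.callable.intervals(chrom):
                out.write(f"{chrom}\t{s}\t{e}\n")
    paths["callable"] = bed

    contig_lines = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n"
        for name, seq in bundle.sequences.items()
    )
    for cs in bundle.callsets:
        path = directory / f"{cs.pipeline_id.replace('+', '_')}.vcf"
        _write_callset_vcf(cs, path, contig_lines)
        paths[cs.pipeline_id] = path

    truth_path = directory / "truth.vcf"
    truth_cs = CallSet(pipeline_id="truth")
    for r in bundle.candidates.itertuples():
        if r.is_true:
            truth_cs.add(
                CallRecord(
                    key=VariantKey(r.chrom, int(r.pos), r.ref, r.alt),
                    genotype_code=int(r.genotype),
                )
            )
    _write_callset_vcf(truth_cs, truth_path, contig_lines)
    paths["truth"] = truth_path

    prof = directory / "profiles.tsv"
    bundle.candidates.to_csv(prof, sep="\t", index=False)
    paths["profiles"] = prof

    tracks = directory / "tracks.tsv"
    tdf = pd.DataFrame(
        {
            **{
                f"depth_{a}": bundle.tracks.depth[:, j]
                for j, a in enumerate(bundle.tracks.aligners)
            },
            **{
                f"mapq_{a}": bundle.tracks.mapq[:, j]
                for j, a in enumerate(bundle.tracks.aligners)
            },
        }
    )
    tdf.to_csv(tracks, sep="\t", index=False)
    paths["tracks"] = tracks

    cfg = directory / "config.yaml"
    with open(cfg, "w") as out:
        yaml.safe_dump(
            {"seed": bundle.seed, **asdict(bundle.config)},
            out,
            default_flow_style=False,
        )
    paths["config"] = cfg
    return paths


_GT = {HOM_VAR: "1/1", HET: "0/1", 2: "0/0", 3: "./."}


def _write_callset_vcf(cs: CallSet, path: Path, contig_lines: str) -> None:
    records = sorted(cs.records.values(), key=lambda r: (r.key.chrom, r.key.pos, r.key.ref, r.key.alt))
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(contig_lines)
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        sample = cs.pipeline_id.replace("+", "_")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in records:
            fmt = ["GT"]
            vals = [_GT[r.genotype_code]]
            if r.depth is not None:
                fmt.append("DP")
                vals.append(str(r.depth))
            if r.allele_depths is not None:
                fmt.append("AD")
                vals.append(f"{r.allele_depths[0]},{r.allele_depths[1]}")
            out.write(
                f"{r.key.chrom}\t{r.key.pos}\t.\t{r.key.ref}\t{r.key.alt}\t.\t.\t.\t"
                + ":".join(fmt)
                + "\t"
                + ":".join(vals)
                + "\n"
            )
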