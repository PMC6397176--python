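import gzip

import numpy as np
import pytest

from concordia.callset_io import (
    HET,
    HOM_REF,
    HOM_VAR,
    NO_CALL,
    RegionSet,
    ReferenceMismatchError,
    VariantKey,
    fasta_fetcher,
    left_normalize,
    merge_callsets,
    merged_from_tsv,
    merged_to_tsv,
    read_callset,
    restrict_to_regions,
    write_filtered_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(path, body, gz=False):
    text = VCF_HEADER + body
    if gz:
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return str(path)


class TestReadCallset:
    def test_genotype_codes_and_fields(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:AD\t0/1:30:15,15\n"
            "1\t200\t.\tC\tT\t.\t.\t.\tGT:DP\t1/1:25\n"
            "1\t300\t.\tG\tA\t.\t.\t.\tGT\t./.\n"
            "1\t400\t.\tT\tC\t.\t.\t.\tGT\t0/0\n"
            "1\t500\t.\tA\tC\t.\t.\t.\tGT\t0/.\n"
        )
        cs = read_callset(write_vcf(tmp_path / "a.vcf", body), "p1")
        recs = cs.records
        r = recs[VariantKey("1", 100, "A", "G")]
        assert r.genotype_code == HET
        assert r.depth == 30
        assert r.allele_depths == (15, 15)
        assert r.alt_fraction == pytest.approx(0.5)
        hom = recs[VariantKey("1", 200, "C", "T")]
        assert hom.genotype_code == HOM_VAR
        assert hom.depth == 25 and hom.allele_depths is None
        assert recs[VariantKey("1", 300, "G", "A")].genotype_code == NO_CALL
        assert recs[VariantKey("1", 400, "T", "C")].genotype_code == HOM_REF
        # half-calls are treated as no-call
        assert recs[VariantKey("1", 500, "A", "C")].genotype_code == NO_CALL

    def test_multiallelic_split_per_alt(self, tmp_path):
        body = "1\t100\t.\tA\tG,T\t.\t.\t.\tGT:DP:AD\t1/2:40:10,15,15\n"
        cs = read_callset(write_vcf(tmp_path / "m.vcf", body), "p1")
        g = cs.records[VariantKey("1", 100, "A", "G")]
        t = cs.records[VariantKey("1", 100, "A", "T")]
        assert g.genotype_code == HET and t.genotype_code == HET
        assert g.allele_depths == (10, 15) and t.allele_depths == (10, 15)

    def test_gzip_input(self, tmp_path):
        body = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        cs = read_callset(write_vcf(tmp_path / "a.vcf.gz", body, gz=True), "p1")
        assert VariantKey("1", 100, "A", "G") in cs.records

    def test_called_keys_exclude_homref_and_nocall(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
            "1\t200\t.\tC\tT\t.\t.\t.\tGT\t0/0\n"
            "1\t300\t.\tG\tA\t.\t.\t.\tGT\t./.\n"
        )
        cs = read_callset(write_vcf(tmp_path / "a.vcf", body), "p1")
        assert cs.called_keys() == {VariantKey("1", 100, "A", "G")}


def apply_variant(seq: str, key: VariantKey) -> str:
    """Haplotype produced by applying the variant (independent oracle)."""
    i = key.pos - 1
    assert seq[i : i + len(key.ref)] == key.ref
    return seq[:i] + key.alt + seq[i + len(key.ref) :]


def brute_force_leftmost(seq: str, key: VariantKey) -> VariantKey:
    """Exhaustive leftmost parsimonious equivalent representation."""
    target = apply_variant(seq, key)
    best = None
    max_len = len(key.ref) + len(key.alt) + key.pos
    for pos in range(1, key.pos + 1):
        for rl in range(0, max_len):
            ref = seq[pos - 1 : pos - 1 + rl]
            if len(ref) < rl:
                continue
            # alt is forced by haplotype identity
            alt_len = rl + len(target) - len(seq)
            if alt_len < 0:
                continue
            alt = target[pos - 1 : pos - 1 + alt_len]
            cand = seq[: pos - 1] + alt + seq[pos - 1 + rl :]
            if cand != target or ref == alt:
                continue
            if not ref or not alt:
                continue
            # parsimony: no shared leading/trailing base removable
            if len(ref) > 1 and len(alt) > 1 and (
                ref[0] == alt[0] or ref[-1] == alt[-1]
            ):
                continue
            k = VariantKey(key.chrom, pos, ref, alt)
            if best is None or (k.pos, len(k.ref)) < (best.pos, len(best.ref)):
                best = k
    return best


class TestLeftNormalize:
    SEQ = "GGGGCACACACTGGGG"  # repeat CAC starting at 1-based 5

    def fetch(self, chrom, pos):
        return self.SEQ[pos - 1]

    def test_snp_unchanged(self):
        key = VariantKey("1", 6, "A", "G")
        assert left_normalize(key, self.fetch) == key

    def test_deletion_in_repeat_shifts_left(self):
        # CAC deletion inside the CACACAC tract must shift to the tract start
        key = VariantKey("1", 7, "CAC", "C")
        norm = left_normalize(key, self.fetch)
        assert norm == brute_force_leftmost(self.SEQ, key)
        assert norm.pos < key.pos

    def test_idempotence_and_oracle_on_random_indels(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=60)) + "ACACACACAC" + "".join(
            rng.choice(list("ACGT"), size=30)
        )

        def fetch(chrom, pos):
            return seq[pos - 1]

        for _ in range(150):
            pos = int(rng.integers(20, len(seq) - 10))
            if rng.random() < 0.5:
                ln = int(rng.integers(1, 4))
                key = VariantKey("1", pos, seq[pos - 1 : pos + ln], seq[pos - 1])
            else:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                key = VariantKey("1", pos, seq[pos - 1], seq[pos - 1] + ins)
            if key.ref == key.alt:
                continue
            norm = left_normalize(key, fetch)
            assert apply_variant(seq, norm) == apply_variant(seq, key)
            assert left_normalize(norm, fetch) == norm
            assert norm == brute_force_leftmost(seq, key)

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            left_normalize(VariantKey("1", 1, "TTT", "T"), self.fetch)


class TestMerge:
    def build(self, tmp_path, bodies):
        return [
            read_callset(write_vcf(tmp_path / f"p{i}.vcf", b), f"p{i}")
            for i, b in enumerate(bodies)
        ]

    def test_matching_and_fill(self, tmp_path):
        b0 = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n1\t200\t.\tC\tT\t.\t.\t.\tGT\t0/1\n"
        b1 = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n1\t100\t.\tA\tT\t.\t.\t.\tGT\t1/1\n"
        m = merge_callsets(self.build(tmp_path, [b0, b1]))
        keys = m.keys()
        # same alt collapses, different alt is a distinct row
        assert VariantKey("1", 100, "A", "G") in keys
        assert VariantKey("1", 100, "A", "T") in keys
        assert m.n_variants == 3
        i = keys.index(VariantKey("1", 200, "C", "T"))
        assert m.codes[i, 0] == HET and m.codes[i, 1] == NO_CALL

    def test_duplicate_pipeline_id_rejected(self, tmp_path):
        b = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        cs = self.build(tmp_path, [b, b])
        cs[1].pipeline_id = cs[0].pipeline_id
        with pytest.raises(ValueError, match="duplicate"):
            merge_callsets(cs)

    def test_union_row_count_oracle(self):
        from concordia.callset_io import CallRecord, CallSet
        from conftest import random_key

        rng = np.random.default_rng(3)
        for _ in range(30):
            callsets = []
            all_called = set()
            for j in range(int(rng.integers(2, 6))):
                cs = CallSet(pipeline_id=f"p{j}")
                for _ in range(int(rng.integers(1, 40))):
                    k = random_key(rng, hi=60)
                    code = int(rng.choice([HOM_VAR, HET, HOM_REF]))
                    cs.add(CallRecord(key=k, genotype_code=code))
                callsets.append(cs)
                all_called |= cs.called_keys()
            m = merge_callsets(callsets)
            assert m.n_variants == len(all_called)
            assert set(m.keys()) == all_called

    def test_merge_order_insensitive(self, tmp_path):
        b0 = "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        b1 = "1\t200\t.\tC\tT\t.\t.\t.\tGT\t1/1\n"
        cs = self.build(tmp_path, [b0, b1])
        m1 = merge_callsets(cs)
        m2 = merge_callsets(cs[::-1])
        assert m1.keys() == m2.keys()
        assert np.array_equal(m1.codes, m2.codes[:, ::-1])


class TestRegions:
    def test_boundary_conversion(self, matrix_factory):
        m = matrix_factory(np.array([[1, 1]]))
        m.variants.loc[0, "pos"] = 100
        # BED 99-100 covers 1-based position 100; BED 100-200 does not
        assert restrict_to_regions(m, RegionSet({"1": [(99, 100)]})).n_variants == 1
        assert restrict_to_regions(m, RegionSet({"1": [(100, 200)]})).n_variants == 0

    def test_whole_genome_identity_and_empty(self, matrix_factory):
        m = matrix_factory(np.array([[1, 1], [0, 3]]))
        whole = RegionSet({"1": [(0, 10_000_000)]})
        assert restrict_to_regions(m, whole).n_variants == m.n_variants
        assert restrict_to_regions(m, RegionSet({})).n_variants == 0

    def test_overlapping_intervals_merge(self):
        rs = RegionSet({"1": [(10, 20), (15, 30), (40, 50)]})
        assert rs.intervals("1") == [(10, 30), (40, 50)]
        assert rs.total_length() == 30

    def test_from_bed(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("1\t0\t100\n1\t200\t300\n2\t0\t50\n")
        rs = RegionSet.from_bed(str(p))
        assert rs.contains("1", 100) and not rs.contains("1", 150)
        assert rs.contains("2", 1)


class TestWriteFilteredVcf:
    def test_round_trip_and_empty(self, tmp_path, matrix_factory):
        m = matrix_factory(np.array([[1, 1], [0, 3], [1, 2]]))
        keys = set(m.keys())
        out = tmp_path / "f.vcf"
        write_filtered_vcf(m, keys, str(out), scores={k: 0.9 for k in keys})
        back = read_callset(str(out), "ens")
        assert set(back.records) == keys
        write_filtered_vcf(m, set(), str(tmp_path / "e.vcf"))
        text = (tmp_path / "e.vcf").read_text()
        assert all(line.startswith("#") for line in text.strip().splitlines())

    def test_unknown_keep_key_rejected(self, tmp_path, matrix_factory):
        m = matrix_factory(np.array([[1, 1]]))
        with pytest.raises(ValueError):
            write_filtered_vcf(
                m, {VariantKey("9", 1, "A", "C")}, str(tmp_path / "x.vcf")
            )


def test_merged_tsv_round_trip(tmp_path, small_bundle):
    m = merge_callsets(small_bundle.callsets)
    path = tmp_path / "m.tsv.gz"
    merged_to_tsv(m, str(path))
    back = merged_from_tsv(str(path))
    assert back.pipelines == m.pipelines
    assert np.array_equal(back.codes, m.codes)
    assert np.allclose(back.depth, m.depth, equal_nan=True)
    assert back.support == m.support
    assert back.keys() == m.keys()
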