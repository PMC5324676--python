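"""Variant extraction, normalization, HGVS, zygosity and VCF round-trips."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplistar.sequences import homopolymer_runs
from amplistar.variants import (
    NormalizedVariant,
    align_to_reference,
    class_counts,
    classify_zygosity,
    extract_and_normalize,
    left_normalize,
    parse_hgvs,
    read_vcf,
    to_hgvs,
    write_vcf,
)

# ---------------------------------------------------------------------------
# alignment


def _gotoh_score(a: str, b: str, match=2, mismatch=-4, gap_open=-6, gap_extend=-1) -> float:
    """Brute-force affine-gap global DP; a gap of length L scores gap_open + L*gap_extend."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open + gap_extend, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open + gap_extend, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestAlignToReference:
    def test_identity_has_no_mismatches_or_gaps(self, reference):
        aln = align_to_reference(reference, reference)
        assert aln.reference_row == aln.query_row == reference

    def test_single_deletion_gives_one_gap_run(self, reference):
        consensus = reference[:3000] + reference[3003:]
        aln = align_to_reference(consensus, reference)
        variants = extract_and_normalize(aln, reference)
        assert len(variants) == 1
        assert variants[0].vclass == "deletion"
        assert len(variants[0].ref) == 3

    @pytest.mark.parametrize("trial", range(15))
    def test_score_matches_bruteforce_dp_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = _random_seq(rng, 60)
        # derive b by mutating a so the pair is alignable
        b = list(a)
        for _ in range(rng.integers(1, 8)):
            op = rng.integers(0, 3)
            pos = int(rng.integers(0, len(b)))
            if op == 0:
                b[pos] = "ACGT"[rng.integers(0, 4)]
            elif op == 1 and len(b) > 40:
                del b[pos]
            else:
                b.insert(pos, "ACGT"[rng.integers(0, 4)])
        b = "".join(b)
        aln = align_to_reference(b, a)
        assert aln.score == _gotoh_score(a, b)

    def test_length_precondition(self, reference):
        with pytest.raises(ValueError, match="within 50%"):
            align_to_reference(reference[: len(reference) // 3], reference)


# ---------------------------------------------------------------------------
# normalization


def _equivalent_deletion_positions(reference: str, pos: int, length: int) -> list[int]:
    """All 1-based positions whose deletion of `length` bases yields the same
    edited sequence (brute force oracle)."""
    target = reference[: pos - 1] + reference[pos - 1 + length :]
    return [
        p
        for p in range(1, len(reference) - length + 2)
        if reference[: p - 1] + reference[p - 1 + length :] == target
    ]


def _equivalent_insertion_positions(reference: str, pos: int, ins: str) -> list[tuple[int, str]]:
    target = reference[:pos] + ins + reference[pos:]
    out = []
    for p in range(1, len(reference) + 1):
        for cand in {ins, *(target[p : p + len(ins)],)}:
            if len(cand) == len(ins) and reference[:p] + cand + reference[p:] == target:
                out.append((p, cand))
    return out


class TestLeftNormalize:
    def test_deletion_in_t_run_normalizes_to_run_start(self, reference):
        """A one-base deletion anywhere in the 22-bp T-homopolymer collapses
        to the run's leftmost coordinate and is flagged low-confidence."""
        runs = [r for r in homopolymer_runs(reference, 22) if r[2] == "T"]
        start0, end0, _ = runs[0]
        for offset in (0, 5, 21):
            v = NormalizedVariant(start0 + 1 + offset, "T", "")
            norm = left_normalize(v, reference)
            assert norm.position == start0 + 1
        cons = reference[: start0 + 5] + reference[start0 + 6 :]
        aln = align_to_reference(cons, reference)
        (var,) = extract_and_normalize(aln, reference)
        assert var.position == start0 + 1
        assert var.low_confidence

    def test_idempotent_on_already_minimal_variant(self, reference):
        v = NormalizedVariant(1000, reference[999], "A" if reference[999] != "A" else "C")
        assert left_normalize(v, reference) == v
        d = left_normalize(NormalizedVariant(2000, reference[1999:2002], ""), reference)
        assert left_normalize(d, reference) == d

    @pytest.mark.parametrize("trial", range(30))
    def test_random_indels_match_bruteforce_minimal_position(self, reference, trial):
        rng = np.random.default_rng(500 + trial)
        length = int(rng.integers(1, 4))
        pos = int(rng.integers(30, len(reference) - 30))
        dele = NormalizedVariant(pos, reference[pos - 1 : pos - 1 + length], "")
        norm = left_normalize(dele, reference)
        assert norm.position == min(_equivalent_deletion_positions(reference, pos, length))
        ins_seq = _random_seq(rng, int(rng.integers(1, 4)))
        ins = NormalizedVariant(pos, "", ins_seq)
        normi = left_normalize(ins, reference)
        assert normi.position == min(
            p for p, _ in _equivalent_insertion_positions(reference, pos, ins_seq)
        )

    def test_matches_bcftools_norm_oracle(self, tmp_path, reference):
        """Independent oracle: bcftools norm left-aligns the same way."""
        ref = reference[:400]
        fa = tmp_path / "ref.fa"
        fa.write_text(">locus\n" + ref + "\n")
        subprocess.run(["samtools", "faidx", str(fa)], check=True)
        rng = np.random.default_rng(9)
        rows, ours = [], []
        for _ in range(25):
            length = int(rng.integers(1, 4))
            pos = int(rng.integers(20, 380 - length))
            v = left_normalize(NormalizedVariant(pos, ref[pos - 1 : pos - 1 + length], ""), ref)
            ours.append(v)
            # present the *denormalized* right-shifted placement to bcftools
            vcf_pos = pos - 1
            rows.append(f"locus\t{vcf_pos}\t.\t{ref[vcf_pos - 1:vcf_pos + length]}\t{ref[vcf_pos - 1]}\t.\t.\t.")
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=locus,length=400>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + "\n".join(rows) + "\n"
        )
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(fa), "-m", "-both", str(vcf)],
            capture_output=True, text=True, check=True,
        ).stdout
        norm_pos = [int(line.split("\t")[1]) for line in out.splitlines() if not line.startswith("#")]
        # bcftools anchors the base before the deletion; ours is the first
        # deleted base.  bcftools also re-sorts its output.
        expected = [v.position - 1 if v.position > 1 else v.position for v in ours]
        assert sorted(norm_pos) == sorted(expected)


class TestExtractAndNormalize:
    def test_mnp_split_into_atomic_snvs(self, reference):
        cons = reference[:2999] + "ACG" if reference[2999:3002] != "ACG" else reference[:2999] + "TGA"
        cons = cons + reference[3002:]
        aln = align_to_reference(cons, reference)
        variants = extract_and_normalize(aln, reference)
        assert all(v.vclass == "substitution" for v in variants)
        assert 1 <= len(variants) <= 3
        assert all(len(v.ref) == len(v.alt) == 1 for v in variants)

    def test_end_masking_suppresses_terminal_variants(self, reference):
        cons = "A" + reference[1:]  # variant at position 1
        if cons == reference:
            cons = "C" + reference[1:]
        aln = align_to_reference(cons, reference)
        assert extract_and_normalize(aln, reference, masked_ends=21) == []
        assert len(extract_and_normalize(aln, reference, masked_ends=0)) == 1

    def test_counts_tally_by_class(self, reference, table):
        variants = table["*2A"].variants
        sub, ins, dele = class_counts(variants)
        assert (sub, ins, dele) == (12, 1, 1)
        assert sub + ins + dele == 14


# ---------------------------------------------------------------------------
# HGVS


class TestHgvs:
    def test_multibase_deletion_with_genomic_offset(self):
        v = NormalizedVariant(100, "TGT", "")
        assert to_hgvs(v, offset=42126033) == "g.42126133_42126135delTGT"

    def test_substitution_with_genomic_offset(self):
        v = NormalizedVariant(10, "G", "C")
        assert to_hgvs(v, offset=42131600) == "g.42131610G>C"

    def test_single_base_deletion_and_insertion_forms(self):
        assert to_hgvs(NormalizedVariant(42132029, "T", "")) == "g.42132029delT"
        assert to_hgvs(NormalizedVariant(50, "", "ACT")) == "g.50_51insACT"

    @given(
        pos=st.integers(1, 10**8),
        kind=st.sampled_from(["sub", "del", "ins"]),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=500, deadline=None)
    def test_roundtrip_through_parser(self, pos, kind, seq, alt):
        if kind == "sub":
            v = NormalizedVariant(pos, seq[0], alt)
        elif kind == "del":
            v = NormalizedVariant(pos, seq, "")
        else:
            v = NormalizedVariant(pos, "", seq)
        assert parse_hgvs(to_hgvs(v)) == v

    @pytest.mark.parametrize(
        "bad", ["g.10_12insAC", "g.5_9delAC", "x.10G>C", "g.10G>", "g.delT"]
    )
    def test_malformed_descriptions_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_hgvs(bad)


# ---------------------------------------------------------------------------
# zygosity


def _subs(reference, positions):
    return {
        NormalizedVariant(p, reference[p - 1], "A" if reference[p - 1] != "A" else "C")
        for p in positions
    }


class TestZygosity:
    def test_partial_overlap_pattern(self, reference):
        """Sets of 25 and 26 sharing 23 -> het 5 / hom 23."""
        shared = _subs(reference, range(100, 100 + 23 * 7, 7))
        only1 = _subs(reference, (3000, 3010))
        only2 = _subs(reference, (4000, 4010, 4020))
        z = classify_zygosity(shared | only1, shared | only2)
        assert (z.n_het, z.n_hom) == (5, 23)

    def test_identical_sets_all_homozygous(self, reference):
        s = _subs(reference, range(200, 200 + 15 * 11, 11))
        z = classify_zygosity(s, set(s))
        assert (z.n_het, z.n_hom) == (0, 15)

    def test_disjoint_sets_all_heterozygous(self, reference):
        s1 = _subs(reference, (500,))
        s2 = _subs(reference, range(1000, 1000 + 26 * 13, 13))
        z = classify_zygosity(s1, s2)
        assert (z.n_het, z.n_hom) == (27, 0)

    def test_single_haplogroup_all_homozygous(self, reference):
        s = _subs(reference, (100, 200, 300))
        z = classify_zygosity(s, None)
        assert (z.n_het, z.n_hom) == (0, 3)

    def test_counts_cover_union(self, reference):
        s1 = _subs(reference, (100, 200))
        s2 = _subs(reference, (200, 300))
        z = classify_zygosity(s1, s2)
        assert z.n_het + z.n_hom == len(s1 | s2)


# ---------------------------------------------------------------------------
# VCF


class TestVcf:
    def test_roundtrip_two_haplogroups(self, tmp_path, reference, table):
        h1 = set(table["*35A"].variants)
        h2 = set(table["*2A"].variants) | {
            NormalizedVariant(601, "T", "", low_confidence=True)
        }
        path = str(tmp_path / "s.vcf")
        write_vcf(path, "sample1", reference, [h1, h2])
        sample, sets = read_vcf(path)
        assert sample == "sample1"
        assert sets[0] == h1 and sets[1] == h2
        assert any(v.low_confidence for v in sets[1])

    def test_het_only_sample_has_phased_het_genotypes(self, tmp_path, reference, table):
        path = str(tmp_path / "het.vcf")
        write_vcf(path, "s", reference, [set(table["*35A"].variants), set()])
        lines = [l for l in open(path) if not l.startswith("#")]
        assert lines and all(l.rstrip().endswith("1|0") for l in lines)

    def test_no_multiallelic_records(self, tmp_path, reference, table):
        path = str(tmp_path / "m.vcf")
        write_vcf(path, "s", reference, [set(table["*2A"].variants), set(table["*4A"].variants)])
        for line in open(path):
            if not line.startswith("#"):
                assert "," not in line.split("\t")[4]

    def test_single_haplogroup_roundtrip(self, tmp_path, reference, table):
        path = str(tmp_path / "one.vcf")
        write_vcf(path, "s", reference, [set(table["*4A"].variants)])
        _, sets = read_vcf(path)
        assert len(sets) == 1
        assert sets[0] == set(table["*4A"].variants)

    def test_malformed_vcf_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(ValueError):
            read_vcf(str(path))
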