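"""Variant extraction, normalization, HGVS description, zygosity and VCF I/O.

Each haplogroup consensus is aligned globally (affine gaps) against the locus
reference; differences are atomized into single-base substitutions and
left-normalized insertions/deletions.  Left normalization shifts an indel to
the smallest coordinate at which it produces the same edited sequence, so
equivalent placements inside repeats collapse to one canonical description.
Edits lying wholly inside long homopolymer runs are flagged low-confidence:
one-base length wobble in such runs is the dominant residual error mode of
long-read amplicon consensus sequences.

Coordinates are 1-based in variant objects, HGVS strings and VCF output
(0-based half-open only transiently inside alignment walking).  For
insertions ``position`` is the reference base *after which* the new bases sit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import Align

from amplistar.sequences import homopolymer_runs


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """An atomic, left-normalized difference against the locus reference.

    ``ref``/``alt`` hold reference and alternate bases without anchor bases:
    a substitution has one of each, a deletion has ``alt == ""`` and a
    insertion has ``ref == ""``.  ``low_confidence`` marks homopolymer-context
    edits; it does not take part in equality, so an observed variant matches
    its translation-table counterpart regardless of the flag.
    """

    position: int
    ref: str
    alt: str
    low_confidence: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.ref == "" and self.alt == "":
            raise ValueError("variant must change at least one base")
        if self.ref and self.alt and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("substitutions must be single-base; split MNPs upstream")
        if self.position < 0:
            raise ValueError("position must be non-negative")

    @property
    def vclass(self) -> str:
        if self.ref and self.alt:
            return "substitution"
        return "deletion" if self.ref else "insertion"

    def hgvs(self, offset: int = 0) -> str:
        return to_hgvs(self, offset)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hgvs()


class LocusAlignment(NamedTuple):
    """A global pairwise alignment of consensus against reference."""

    score: float
    reference_row: str
    query_row: str


#: default scoring: match / mismatch / gap-open / gap-extend.
#: A gap of length L scores -(open + L * extend) = -(6 + L).
DEFAULT_SCORING = (2, -4, -6, -1)


def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gap base
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference(
    consensus: str,
    reference: str,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
) -> LocusAlignment:
    """Global affine-gap alignment of a haplogroup consensus to the reference.

    The amplicon spans the full locus, so a global alignment replaces read
    mapping.  Raises ``ValueError`` when the consensus length is not within
    50% of the reference length (a full-length consensus never is).
    """
    if not reference:
        raise ValueError("empty reference")
    if abs(len(consensus) - len(reference)) > 0.5 * len(reference):
        raise ValueError(
            f"consensus length {len(consensus)} not within 50% of reference "
            f"length {len(reference)}"
        )
    aligner = _aligner(*scoring)
    alignments = aligner.align(reference, consensus)
    best = alignments[0]
    return LocusAlignment(float(best.score), str(best[0]), str(best[1]))


def left_normalize(variant: NormalizedVariant, reference: str) -> NormalizedVariant:
    """Shift an indel to its minimal equivalent position within repeats.

    Substitutions are returned unchanged.  Deletions shift while the base
    before the deleted block equals its last base; insertions rotate while
    the last inserted base equals the reference base at the insertion point.
    Idempotent.
    """
    pos, ref, alt = variant.position, variant.ref, variant.alt
    if variant.vclass == "substitution":
        return variant
    if variant.vclass == "deletion":
        length = len(ref)
        while pos > 1 and reference[pos - 2] == reference[pos + length - 2]:
            pos -= 1
        ref = reference[pos - 1 : pos - 1 + length]
        return NormalizedVariant(pos, ref, "", variant.low_confidence)
    # insertion after `pos`
    ins = alt
    while pos >= 1 and ins[-1] == reference[pos - 1]:
        ins = reference[pos - 1] + ins[:-1]
        pos -= 1
    return NormalizedVariant(pos, "", ins, variant.low_confidence)


def _flag_homopolymer(
    variant: NormalizedVariant, runs: Sequence[tuple[int, int, str]]
) -> NormalizedVariant:
    """Set ``low_confidence`` when the edit lies wholly inside a long run."""
    p0 = variant.position - 1  # 0-based
    flagged = False
    for start, end, base in runs:
        if variant.vclass == "substitution" and start <= p0 < end:
            flagged = True
        elif variant.vclass == "deletion":
            if start <= p0 and p0 + len(variant.ref) <= end:
                flagged = True
        else:  # insertion after position p0+1 (1-based), junction p0|p0+1
            if set(variant.alt) == {base} and (start <= p0 < end or start <= p0 + 1 < end):
                flagged = True
        if flagged:
            return NormalizedVariant(variant.position, variant.ref, variant.alt, True)
    return variant


def extract_and_normalize(
    alignment: LocusAlignment,
    reference: str,
    masked_ends: int = 0,
    homopolymer_min: int = 8,
) -> list[NormalizedVariant]:
    """Atomic, left-normalized variants from a consensus/reference alignment.

    Consecutive mismatch columns become separate single-base substitutions
    (MNP splitting); runs of gap columns merge into one indel each, then
    left-align.  Variants whose reference footprint lies within
    ``masked_ends`` bases of either locus end are suppressed (the terminal
    windows are treated as unreliable for variant support).
    """
    ref_row, qry_row = alignment.reference_row, alignment.query_row
    if len(ref_row) != len(qry_row):
        raise ValueError("malformed alignment: row lengths differ")
    raw: list[NormalizedVariant] = []
    rpos = 0  # reference bases consumed (0-based)
    i = 0
    n = len(ref_row)
    while i < n:
        r, q = ref_row[i], qry_row[i]
        if r != "-" and q != "-":
            if r != q:
                raw.append(NormalizedVariant(rpos + 1, r, q))
            rpos += 1
            i += 1
        elif q == "-":  # deletion from consensus: merge the gap run
            j = i
            while j < n and qry_row[j] == "-" and ref_row[j] != "-":
                j += 1
            deleted = ref_row[i:j]
            raw.append(NormalizedVariant(rpos + 1, deleted, ""))
            rpos += j - i
            i = j
        else:  # insertion in consensus
            j = i
            while j < n and ref_row[j] == "-" and qry_row[j] != "-":
                j += 1
            inserted = qry_row[i:j]
            raw.append(NormalizedVariant(rpos, "", inserted))
            i = j
    runs = homopolymer_runs(reference, homopolymer_min)
    out: list[NormalizedVariant] = []
    for v in raw:
        v = left_normalize(v, reference)
        v = _flag_homopolymer(v, runs)
        if masked_ends:
            span_start = v.position if v.vclass != "insertion" else v.position
            span_end = v.position + max(len(v.ref), 1) - 1
            if span_end <= masked_ends or span_start > len(reference) - masked_ends:
                continue
        out.append(v)
    out.sort(key=lambda v: (v.position, v.alt, v.ref))
    return out


# ---------------------------------------------------------------------------
# HGVS g. rendering and parsing


_HGVS_SUB = re.compile(r"^g\.(\d+)([ACGT])>([ACGT])$")
_HGVS_DEL = re.compile(r"^g\.(\d+)(?:_(\d+))?del([ACGT]+)$")
_HGVS_INS = re.compile(r"^g\.(\d+)_(\d+)ins([ACGT]+)$")


def to_hgvs(variant: NormalizedVariant, offset: int = 0) -> str:
    """Render a genomic HGVS description, e.g. ``g.42126133_42126135delTGT``.

    ``offset`` maps locus coordinates onto genomic ones (real-data mode);
    the packaged synthetic fixture uses offset 0.
    """
    p = variant.position + offset
    if variant.vclass == "substitution":
        return f"g.{p}{variant.ref}>{variant.alt}"
    if variant.vclass == "deletion":
        if len(variant.ref) == 1:
            return f"g.{p}del{variant.ref}"
        return f"g.{p}_{p + len(variant.ref) - 1}del{variant.ref}"
    return f"g.{p}_{p + 1}ins{variant.alt}"


def parse_hgvs(text: str, offset: int = 0) -> NormalizedVariant:
    """Inverse of :func:`to_hgvs`; raises ``ValueError`` on malformed input."""
    m = _HGVS_SUB.match(text)
    if m:
        return NormalizedVariant(int(m.group(1)) - offset, m.group(2), m.group(3))
    m = _HGVS_DEL.match(text)
    if m:
        start = int(m.group(1))
        seq = m.group(3)
        if m.group(2) is not None and int(m.group(2)) - start + 1 != len(seq):
            raise ValueError(f"deletion span does not match sequence length: {text!r}")
        if m.group(2) is None and len(seq) != 1:
            raise ValueError(f"multi-base deletion needs a span: {text!r}")
        return NormalizedVariant(start - offset, seq, "")
    m = _HGVS_INS.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise ValueError(f"insertion junction must be adjacent: {text!r}")
        return NormalizedVariant(start - offset, "", m.group(3))
    raise ValueError(f"unrecognized HGVS description: {text!r}")


def class_counts(variants: Iterable[NormalizedVariant]) -> tuple[int, int, int]:
    """(substitutions, insertions, deletions) tally of a variant set."""
    sub = ins = dele = 0
    for v in variants:
        if v.vclass == "substitution":
            sub += 1
        elif v.vclass == "insertion":
            ins += 1
        else:
            dele += 1
    return sub, ins, dele


# ---------------------------------------------------------------------------
# Zygosity


@dataclass
class ZygositySummary:
    """Het/hom classification of the union of two haplogroups' variants."""

    n_het: int
    n_hom: int
    per_variant: dict[NormalizedVariant, str]


def classify_zygosity(
    hap1_variants: Iterable[NormalizedVariant],
    hap2_variants: Optional[Iterable[NormalizedVariant]] = None,
) -> ZygositySummary:
    """Classify each observed variant as heterozygous or homozygous.

    With two observed haplogroups a variant present in both is homozygous and
    one present in a single haplogroup is heterozygous (an empty second set is
    a *1-like chromosome: everything on the other haplogroup is het).  Pass
    ``hap2_variants=None`` for a sample where only one haplogroup sequence was
    observed and a deletion or homozygosity was established: the single
    sequence then represents both gene copies (or the only one), so every
    variant is homozygous.
    """
    s1 = set(hap1_variants)
    if hap2_variants is None:
        per = {v: "hom" for v in s1}
        return ZygositySummary(0, len(s1), per)
    s2 = set(hap2_variants)
    per: dict[NormalizedVariant, str] = {}
    for v in s1 | s2:
        per[v] = "hom" if (v in s1 and v in s2) else "het"
    n_hom = sum(1 for c in per.values() if c == "hom")
    return ZygositySummary(len(per) - n_hom, n_hom, per)


# ---------------------------------------------------------------------------
# VCF 4.2 I/O


def _to_vcf_row(v: NormalizedVariant, reference: str) -> tuple[int, str, str]:
    """(POS, REF, ALT) with the anchor base VCF indel convention."""
    if v.vclass == "substitution":
        return v.position, v.ref, v.alt
    if v.vclass == "deletion":
        if v.position > 1:
            anchor = reference[v.position - 2]
            return v.position - 1, anchor + v.ref, anchor
        anchor = reference[v.position - 1 + len(v.ref)]
        return v.position, v.ref + anchor, anchor
    # insertion after v.position
    if v.position >= 1:
        anchor = reference[v.position - 1]
        return v.position, anchor, anchor + v.alt
    anchor = reference[0]
    return 1, anchor, v.alt + anchor


def _from_vcf_row(pos: int, ref: str, alt: str) -> NormalizedVariant:
    if len(ref) == 1 and len(alt) == 1:
        return NormalizedVariant(pos, ref, alt)
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
        return NormalizedVariant(pos + 1, ref[1:], "")
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref:
        return NormalizedVariant(pos, "", alt[1:])
    if len(ref) > 1 and len(alt) == 1 and ref[-1] == alt:  # trailing-anchor deletion
        return NormalizedVariant(pos, ref[:-1], "")
    raise ValueError(f"unsupported VCF allele pair {ref}>{alt} at {pos}")


HOMOPOLYMER_FILTER = "homopolymer"


def write_vcf(
    path: str,
    sample_id: str,
    reference: str,
    hap_variant_sets: Sequence[Iterable[NormalizedVariant]],
    contig: str = "locus",
) -> None:
    """Write phased per-haplogroup calls as a single-sample VCF 4.2.

    Genotypes encode haplogroup membership (``1|0`` = haplogroup 1 only,
    ``0|1`` = haplogroup 2 only, ``1|1`` = both); a single observed
    haplogroup is written haploid (``1``).  Low-confidence homopolymer
    variants carry the ``homopolymer`` FILTER tag.
    """
    if not 1 <= len(hap_variant_sets) <= 2:
        raise ValueError("expected one or two haplogroup variant sets")
    sets = [set(s) for s in hap_variant_sets]
    union = sorted(set().union(*sets), key=lambda v: (v.position, v.alt, v.ref))
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(reference)}>",
        f"##amplistar_haplogroups={len(sets)}",
        f'##FILTER=<ID={HOMOPOLYMER_FILTER},Description="Edit lies inside a long homopolymer run">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased haplogroup genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    for v in union:
        pos, ref, alt = _to_vcf_row(v, reference)
        filt = HOMOPOLYMER_FILTER if v.low_confidence else "PASS"
        if len(sets) == 1:
            gt = "1"
        else:
            gt = f"{int(v in sets[0])}|{int(v in sets[1])}"
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT\t{gt}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> tuple[str, list[set[NormalizedVariant]]]:
    """Read a VCF written by :func:`write_vcf` back into haplogroup sets."""
    import pysam

    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if len(samples) != 1:
        raise ValueError(f"expected a single-sample VCF, found {samples}")
    sample = samples[0]
    n_haps = 2
    for rec_header in str(vcf.header).splitlines():
        if rec_header.startswith("##amplistar_haplogroups="):
            n_haps = int(rec_header.split("=", 1)[1])
    sets: list[set[NormalizedVariant]] = [set() for _ in range(max(n_haps, 1))]
    for lineno, rec in enumerate(vcf, start=1):
        if len(rec.alts or ()) != 1:
            raise ValueError(f"multiallelic record at line {lineno} of {path}")
        low = HOMOPOLYMER_FILTER in rec.filter
        v = _from_vcf_row(rec.pos, rec.ref, rec.alts[0])
        v = NormalizedVariant(v.position, v.ref, v.alt, low)
        gt = rec.samples[sample]["GT"]
        for hap_idx, allele in enumerate(gt):
            if allele and hap_idx < len(sets):
                sets[hap_idx].add(v)
    vcf.close()
    return sample, sets
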