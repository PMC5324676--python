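"""Synthetic locus, star-allele haplotypes and noisy barcoded read simulator.

The generator emulates the data a full-length pharmacogene amplicon run
produces: a diploid ~6.6-kb locus (with a long T-homopolymer upstream, the
classic consensus trouble spot), star-allele haplotypes built by applying
defining variants to the reference, per-chromosome copy number 0/1/2, and
single-pass long reads with an indel-dominant error profile wrapped in
padding + symmetric barcode + M13 + gene-primer adornments.  Every read's
sample and haplotype of origin is recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from amplistar.layout import AdornmentLayout
from amplistar.demux import Read
from amplistar.sequences import decode, encode, revcomp
from amplistar.variants import NormalizedVariant

#: sentinel allele label for a whole-gene deletion chromosome
DELETED = "DELETED"

#: constant Phred quality assigned to simulated bases
SIMULATED_QUALITY = 12


@dataclass(frozen=True)
class LocusSpec:
    """Recipe for a random reference locus with embedded homopolymer runs."""

    length: int = 6600
    gc_fraction: float = 0.45
    homopolymer_inserts: tuple[tuple[int, str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("locus length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        for pos, base, run in self.homopolymer_inserts:
            if base not in "ACGT":
                raise ValueError(f"invalid homopolymer base {base!r}")
            if not (0 <= pos and pos + run <= self.length):
                raise ValueError("homopolymer insert outside locus")


def build_reference(spec: LocusSpec) -> str:
    """Deterministic random reference with the requested homopolymer runs."""
    intervals = sorted((pos, pos + run, base) for pos, base, run in spec.homopolymer_inserts)
    for (s1, e1, _), (s2, e2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping homopolymer inserts")
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_fraction / 2.0
    p_at = (1.0 - spec.gc_fraction) / 2.0
    codes = rng.choice(4, size=spec.length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    seq = list(decode(codes))
    for start, end, base in intervals:
        seq[start:end] = base * (end - start)
    return "".join(seq)


@dataclass(frozen=True)
class StarAlleleDefinition:
    """A named star allele: its defining variants and enzyme activity.

    ``core`` is the family label (e.g. ``*35`` for suballele ``*35A``);
    ``is_deletion`` marks the whole-gene-deletion allele (*5), which has no
    defining variants and is only ever assigned from orthogonal assay
    evidence, never from sequence matching.
    """

    name: str
    core: str
    variants: tuple[NormalizedVariant, ...]
    activity: float
    is_deletion: bool = False

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be non-negative")
        if self.is_deletion and self.variants:
            raise ValueError("deletion allele cannot carry defining variants")
        spans = []
        for v in self.variants:
            start = v.position
            end = v.position + max(len(v.ref), 1) - 1
            spans.append((start, end, v))
        spans.sort()
        for (s1, e1, v1), (s2, e2, v2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping defining variants in {self.name}: {v1.hgvs()} / {v2.hgvs()}"
                )
        object.__setattr__(self, "variants", tuple(v for _, _, v in spans))


def apply_allele(reference: str, definition: StarAlleleDefinition) -> str:
    """Haplotype sequence implied by a star-allele definition.

    Differs from the reference by exactly the defining variants; an empty
    definition (*1) returns the reference unchanged.  Raises ``ValueError``
    naming the variant when a reference base does not match.
    """
    seq = reference
    for v in sorted(definition.variants, key=lambda v: v.position, reverse=True):
        p0 = v.position - 1
        if v.vclass == "substitution":
            if seq[p0] != v.ref:
                raise ValueError(
                    f"{definition.name} {v.hgvs()}: reference has {seq[p0]!r}, expected {v.ref!r}"
                )
            seq = seq[:p0] + v.alt + seq[p0 + 1 :]
        elif v.vclass == "deletion":
            if seq[p0 : p0 + len(v.ref)] != v.ref:
                raise ValueError(
                    f"{definition.name} {v.hgvs()}: reference slice "
                    f"{seq[p0:p0 + len(v.ref)]!r} != {v.ref!r}"
                )
            seq = seq[:p0] + seq[p0 + len(v.ref) :]
        else:  # insertion after v.position
            seq = seq[: v.position] + v.alt + seq[v.position :]
    return seq


@dataclass(frozen=True)
class ReadErrorModel:
    """Per-base error probabilities of single-pass long reads.

    The default profile is indel-dominant (insertions/deletions above the
    mismatch rate), mimicking raw single-pass long-read error structure.
    """

    mismatch_rate: float = 0.015
    insertion_rate: float = 0.04
    deletion_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 0.2:
                raise ValueError(f"{name} must be in [0, 0.2)")


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated diploid sample."""

    sample_id: str
    hap1_allele: str
    hap2_allele: str
    hap1_copies: int = 1
    hap2_copies: int = 1
    barcode: str = ""
    depth: int = 120

    def __post_init__(self) -> None:
        for allele, copies in ((self.hap1_allele, self.hap1_copies), (self.hap2_allele, self.hap2_copies)):
            if (copies == 0) != (allele == DELETED):
                raise ValueError("copies == 0 iff allele is DELETED")
            if copies < 0:
                raise ValueError("copies must be >= 0")
        if self.hap1_copies + self.hap2_copies < 1:
            raise ValueError("at least one haplotype must have copies >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _apply_errors(codes: np.ndarray, model: ReadErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Vectorized substitution/deletion/single-base-insertion noise."""
    u = rng.random(len(codes))
    del_mask = u < model.deletion_rate
    sub_mask = (~del_mask) & (u < model.deletion_rate + model.mismatch_rate)
    mutated = codes.copy()
    n_sub = int(sub_mask.sum())
    if n_sub:
        mutated[sub_mask] = (mutated[sub_mask] + rng.integers(1, 4, size=n_sub)) % 4
    kept = mutated[~del_mask]
    v = rng.random(len(kept) + 1)
    sites = np.where(v < model.insertion_rate)[0]
    if len(sites):
        kept = np.insert(kept, sites, rng.integers(0, 4, size=len(sites)).astype(np.uint8))
    return kept


def simulate_reads(
    reference: str,
    alleles: Mapping[str, StarAlleleDefinition],
    truths: Sequence[SampleTruth],
    error_model: Optional[ReadErrorModel] = None,
    layout: Optional[AdornmentLayout] = None,
    seed: Optional[int] = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate barcoded noisy reads for a cohort with known truth.

    Per-haplotype read counts are multinomial with weights proportional to
    copy numbers, so the expected support ratio equals the copy-number ratio.
    Errors hit insert and adornments alike; reads are emitted in random order
    on random strands.  Identical seeds reproduce identical output.

    Returns the reads and a truth table with columns
    ``read_id, sample_id, hap_index, haplotype_label, strand``.
    """
    error_model = error_model or ReadErrorModel()
    layout = layout or AdornmentLayout()
    rng = np.random.default_rng(error_model.seed if seed is None else seed)
    barcodes = [t.barcode for t in truths]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes across samples")
    reads: list[Read] = []
    truth_rows: list[dict] = []
    for truth in truths:
        hap_codes: dict[int, np.ndarray] = {}
        for hap_index, allele in ((1, truth.hap1_allele), (2, truth.hap2_allele)):
            if allele == DELETED:
                continue
            if allele not in alleles:
                raise KeyError(f"allele {allele} of {truth.sample_id} not in table")
            molecule = layout.assemble(truth.barcode, apply_allele(reference, alleles[allele]))
            hap_codes[hap_index] = encode(molecule)
        weights = np.array(
            [truth.hap1_copies if 1 in hap_codes else 0, truth.hap2_copies if 2 in hap_codes else 0],
            dtype=float,
        )
        counts = rng.multinomial(truth.depth, weights / weights.sum())
        read_no = 0
        for hap_index, count in zip((1, 2), counts):
            if hap_index not in hap_codes:
                continue
            label = {1: truth.hap1_allele, 2: truth.hap2_allele}[hap_index]
            for _ in range(count):
                noisy = _apply_errors(hap_codes[hap_index], error_model, rng)
                seq = decode(noisy)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    seq = revcomp(seq)
                read_id = f"{truth.sample_id}_r{read_no:05d}"
                read_no += 1
                reads.append(
                    Read(
                        id=read_id,
                        sequence=seq,
                        quality=[SIMULATED_QUALITY] * len(seq),
                    )
                )
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample_id": truth.sample_id,
                        "hap_index": hap_index,
                        "haplotype_label": label,
                        "strand": strand,
                    }
                )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return reads, truth
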