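"""Packaged synthetic fixture: locus, translation table, cohort scenarios.

The fixture is a self-contained stand-in for the real pharmacogene setting:
a deterministic 6.6-kb reference with a 22-bp T-homopolymer in its upstream
region, a translation table of star alleles whose structure mirrors the
well-known CYP2D6 families (*1 default, *2/*2A, *35/*35A, *4/*4A, *3A,
*6/*6A/*6B, *9, *10D, *17, *41, plus the whole-gene deletion *5) at
synthetic coordinates, and a 20-sample packaged diploid cohort spanning
balanced diplotypes, one duplication, one hemizygous deletion and one
homozygote.  Suballeles share their core's diagnostic variants and add
private ones, so subset matching genuinely has to pick the most specific
allele.  Variant counts echo the real table where the literature states
them: *35A has the 5 classic variants (rs769258 plus the rs16947 /
rs1058164 / rs1135840 / rs1080985 backbone), *4A has 7, *2A has 14.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from amplistar.layout import AdornmentLayout
from amplistar.sequences import hamming, run_length_at
from amplistar.starcall import EvidenceFlags, TranslationTable, format_genotype
from amplistar.synthetic import (
    DELETED,
    LocusSpec,
    SampleTruth,
    StarAlleleDefinition,
    build_reference,
)
from amplistar.variants import NormalizedVariant, left_normalize

FIXTURE_SEED = 1166
#: 0-based offset, base, run length of the upstream T-homopolymer
FIXTURE_HOMOPOLYMER = (600, "T", 22)


def fixture_locus_spec() -> LocusSpec:
    return LocusSpec(
        length=6600,
        gc_fraction=0.45,
        homopolymer_inserts=(FIXTURE_HOMOPOLYMER,),
        seed=FIXTURE_SEED,
    )


@lru_cache(maxsize=1)
def fixture_reference() -> str:
    return build_reference(fixture_locus_spec())


_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _sub(ref: str, pos: int) -> NormalizedVariant:
    base = ref[pos - 1]
    return NormalizedVariant(pos, base, _NEXT_BASE[base])


def _pick_del(ref: str, start: int, length: int) -> NormalizedVariant:
    """First deletion at/after ``start`` that is already left-normalized and
    sits clear of homopolymer context (runs < 3 over its footprint)."""
    for pos in range(start, start + 200):
        if ref[pos - 2] == ref[pos + length - 2]:  # would left-shift
            continue
        if any(run_length_at(ref, p0) >= 3 for p0 in range(pos - 2, pos + length)):
            continue
        v = NormalizedVariant(pos, ref[pos - 1 : pos - 1 + length], "")
        if left_normalize(v, ref) == v:
            return v
    raise RuntimeError("no suitable deletion site found")


def _pick_ins(ref: str, start: int, inserted: str = "ACT") -> NormalizedVariant:
    """First insertion junction at/after ``start`` already left-normalized."""
    for pos in range(start, start + 200):
        v = NormalizedVariant(pos, "", inserted)
        if left_normalize(v, ref) == v and run_length_at(ref, pos - 1) < 3:
            return v
    raise RuntimeError("no suitable insertion site found")


@lru_cache(maxsize=1)
def fixture_table() -> TranslationTable:
    ref = fixture_reference()
    # backbone shared by the *2 / *35 / *41 / *17 families
    s1 = _sub(ref, 1200)  # rs16947-like
    s2 = _sub(ref, 1800)  # rs1058164-like
    s3 = _sub(ref, 2400)  # rs1135840-like
    s4 = _sub(ref, 3000)  # rs1080985-like
    m1 = _sub(ref, 900)  # rs769258-like, diagnostic of *35
    b1 = _sub(ref, 4100)  # *1B private upstream substitution
    a_subs = tuple(_sub(ref, p) for p in (1500, 2100, 2700, 3300, 3900, 4500, 5100, 5700))
    a_ins = _pick_ins(ref, 4800)
    a_del = _pick_del(ref, 5400, 3)
    k1 = _sub(ref, 2000)  # rs3892097-like splice defect, diagnostic of *4
    k_subs = tuple(_sub(ref, p) for p in (1400, 2600, 3500, 4200))
    d1 = _pick_del(ref, 3100, 1)  # *3A frameshift deletion
    d2 = _sub(ref, 5200)
    e1 = _pick_del(ref, 1650, 1)  # *6 frameshift deletion
    e2 = _sub(ref, 2250)
    e3 = _sub(ref, 2900)
    e4 = _sub(ref, 3600)
    n1 = _pick_del(ref, 2615, 3)  # *9 in-frame 3-bp deletion
    t1 = _sub(ref, 150)
    t2 = _sub(ref, 4700)
    t3 = _sub(ref, 5500)
    h1 = _sub(ref, 1050)  # *17 diagnostic
    w1 = _sub(ref, 2950)  # *41 diagnostic

    def allele(name, core, variants, activity, is_deletion=False):
        return StarAlleleDefinition(name, core, tuple(variants), activity, is_deletion)

    alleles = [
        allele("*1", "*1", (), 1.0),
        allele("*1B", "*1", (b1,), 1.0),
        allele("*2", "*2", (s1, s3), 1.0),
        allele("*2A", "*2", (s1, s2, s3, s4) + a_subs + (a_ins, a_del), 1.0),
        allele("*35", "*35", (m1,), 1.0),
        allele("*35A", "*35", (m1, s1, s2, s3, s4), 1.0),
        allele("*3A", "*3", (d1, d2), 0.0),
        allele("*4", "*4", (k1,), 0.0),
        allele("*4A", "*4", (k1, s2, s3) + k_subs, 0.0),
        allele("*5", "*5", (), 0.0, is_deletion=True),
        allele("*6", "*6", (e1,), 0.0),
        allele("*6A", "*6", (e1, e2), 0.0),
        allele("*6B", "*6", (e1, e3, e4), 0.0),
        allele("*9", "*9", (n1,), 0.5),
        allele("*10D", "*10", (t1, s3, t2, t3), 0.5),
        allele("*17", "*17", (h1, s1, s3), 0.5),
        allele("*41", "*41", (w1, s1, s3), 0.5),
    ]
    return TranslationTable({a.name: a for a in alleles})


#: the five variants whose joint presence defines the *35A call (fixture
#: stand-ins for rs769258, rs16947, rs1058164, rs1135840, rs1080985)
def star35a_variants() -> tuple[NormalizedVariant, ...]:
    return fixture_table()["*35A"].variants


def fixture_layout() -> AdornmentLayout:
    return AdornmentLayout()


def fixture_barcodes(n: int, min_distance: int = 6, seed: int = FIXTURE_SEED + 1) -> list[str]:
    """Deterministic 16-mer barcodes with pairwise Hamming distance >= 6."""
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    while len(barcodes) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=16))
        if all(hamming(cand, bc) >= min_distance for bc in barcodes):
            barcodes.append(cand)
    return barcodes


#: (hap1, hap2, copies1, copies2, deletion_assay, duplication_assay)
COHORT_SCENARIOS: tuple[tuple[str, str, int, int, str, str], ...] = (
    ("*1", "*35A", 1, 1, "untested", "untested"),
    ("*1", "*2A", 1, 1, "untested", "untested"),
    ("*1B", "*2A", 1, 2, "untested", "untested"),  # *2A duplication
    ("*1", "*41", 1, 1, "untested", "untested"),
    ("*4A", "*35A", 1, 1, "untested", "untested"),
    ("*4A", "*2A", 1, 1, "untested", "untested"),
    ("*41", "*2A", 1, 1, "untested", "untested"),
    ("*4A", DELETED, 1, 0, "positive", "untested"),  # hemizygous *4A/*5
    ("*3A", "*2A", 1, 1, "untested", "untested"),
    ("*10D", "*10D", 1, 1, "negative", "untested"),  # true homozygote
    ("*9", "*35A", 1, 1, "untested", "untested"),
    ("*6B", "*4A", 1, 1, "untested", "untested"),
    ("*1", "*17", 1, 1, "untested", "untested"),
    ("*2A", DELETED, 1, 0, "positive", "untested"),
    ("*2A", "*2A", 2, 1, "untested", "positive"),  # duplicated homozygote
    ("*9", "*41", 1, 1, "untested", "untested"),
    ("*1", "*4A", 1, 1, "untested", "untested"),
    ("*35A", "*41", 1, 1, "untested", "untested"),
    ("*17", "*2A", 1, 1, "untested", "untested"),
    ("*6A", "*35A", 1, 1, "untested", "untested"),
)


def packaged_cohort(
    depth: int = 120,
    scenarios=None,
) -> tuple[list[SampleTruth], dict[str, EvidenceFlags], dict[str, str]]:
    """The packaged 20-sample scenario: truths, assay evidence, expected calls.

    Expected diplotype strings are derived from the truth alleles and copy
    numbers with the same canonical formatting the caller uses.
    """
    if scenarios is None:
        scenarios = COHORT_SCENARIOS
    barcodes = fixture_barcodes(len(scenarios))
    truths, evidence, expected = [], {}, {}
    for i, (h1, h2, c1, c2, del_assay, dup_assay) in enumerate(scenarios):
        sid = f"S{i + 1:02d}"
        truths.append(
            SampleTruth(
                sample_id=sid,
                hap1_allele=h1,
                hap2_allele=h2,
                hap1_copies=c1,
                hap2_copies=c2,
                barcode=barcodes[i],
                depth=depth,
            )
        )
        evidence[sid] = EvidenceFlags(del_assay, dup_assay)
        expected[sid] = format_genotype(
            h1 if h1 != DELETED else "*5", c1, h2 if h2 != DELETED else "*5", c2
        )
    return truths, evidence, expected
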