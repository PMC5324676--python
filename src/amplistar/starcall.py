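"""Star-allele matching, diplotype assembly with copy number, phenotype.

A star allele is a named haplotype defined by a fixed variant set; *1 is the
reference allele with no defining variants.  A haplogroup's observed variant
set is matched against the translation table by subset containment: every
allele whose complete definition is contained in the observed set is a
candidate, and the candidate with the most defining variants wins (the most
specific suballele, e.g. *35A over *35).  Observed variants not used by the
winner are reported as ``extra_variants`` for curation and never veto a
match — full-locus sequencing routinely reveals variants no translation
table lists.

The diplotype combines the per-haplogroup calls with copy-number state: an
unbalanced subread-support ratio marks a duplicated haplogroup (XN), while a
single observed haplogroup is disambiguated by orthogonal deletion /
duplication PCR evidence (hap/*5, hap/hapXN or homozygous hap/hap).  The
metabolizer group follows from the summed activity of all gene copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from amplistar.phasing import CoverageRatio
from amplistar.synthetic import StarAlleleDefinition
from amplistar.variants import NormalizedVariant


@dataclass
class TranslationTable:
    """Star-allele definitions plus a variant -> alleles index."""

    alleles: dict[str, StarAlleleDefinition]
    variant_index: dict[NormalizedVariant, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = [
            a.name for a in self.alleles.values() if not a.variants and not a.is_deletion
        ]
        if len(defaults) != 1:
            raise ValueError(
                f"table must contain exactly one zero-variant default allele, found {defaults}"
            )
        self.default_allele = defaults[0]
        self.variant_index = {}
        for a in self.alleles.values():
            for v in a.variants:
                self.variant_index.setdefault(v, []).append(a.name)

    def __getitem__(self, name: str) -> StarAlleleDefinition:
        return self.alleles[name]

    def activities(self) -> dict[str, float]:
        return {name: a.activity for name, a in self.alleles.items()}


@dataclass
class HaplotypeCall:
    """The star allele matched to one haplogroup's variant set."""

    allele: str
    matched_variants: frozenset[NormalizedVariant]
    extra_variants: frozenset[NormalizedVariant]
    exact: bool
    caveats: list[str] = field(default_factory=list)


_EVIDENCE_VALUES = ("positive", "negative", "untested")


@dataclass(frozen=True)
class EvidenceFlags:
    """Boolean outcomes of the orthogonal deletion/duplication PCR assays."""

    deletion_assay: str = "untested"
    duplication_assay: str = "untested"

    def __post_init__(self) -> None:
        for name in ("deletion_assay", "duplication_assay"):
            if getattr(self, name) not in _EVIDENCE_VALUES:
                raise ValueError(f"{name} must be one of {_EVIDENCE_VALUES}")


@dataclass
class DiplotypeCall:
    """Two allele calls with per-allele copy number, score and phenotype."""

    allele1: str
    allele2: str
    copies1: int
    copies2: int
    genotype_string: str
    activity_score: Optional[float] = None
    phenotype: Optional[str] = None
    caveats: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PhenotypeCutpoints:
    """Activity-score cut-points for the metabolizer groups.

    score == 0 -> poor; 0 < score <= intermediate_max -> intermediate;
    intermediate_max < score < ultrarapid_min -> normal;
    score >= ultrarapid_min -> ultrarapid.
    """

    intermediate_max: float = 1.5
    ultrarapid_min: float = 2.5


DELETION_ALLELE = "*5"


def match_haplotype(
    variants: Iterable[NormalizedVariant],
    table: TranslationTable,
) -> HaplotypeCall:
    """Match an observed (normalized) variant set to the most specific allele.

    Low-confidence homopolymer variants are excluded from matching but kept
    in ``extra_variants``.  An empty observed set, or one containing no
    complete allele definition, yields the default (*1) allele with all
    observations as extras.  Ties between equally specific alleles break by
    fewest extras, then lexicographically with a caveat.
    """
    if not table.alleles:
        raise ValueError("empty translation table")
    observed_all = set(variants)
    low_conf = {v for v in observed_all if v.low_confidence}
    observed = observed_all - low_conf
    candidates = [
        a
        for a in table.alleles.values()
        if not a.is_deletion and set(a.variants) <= observed
    ]
    caveats: list[str] = []

    def extras(a: StarAlleleDefinition) -> int:
        return len(observed - set(a.variants))

    best_key = max((len(a.variants), -extras(a)) for a in candidates)
    tied = sorted(
        a.name for a in candidates if (len(a.variants), -extras(a)) == best_key
    )
    winner = table[tied[0]]
    if len(tied) > 1:
        caveats.append(f"ambiguous match among {'/'.join(tied)}; chose {tied[0]}")
    extra = frozenset((observed - set(winner.variants)) | low_conf)
    return HaplotypeCall(
        allele=winner.name,
        matched_variants=frozenset(winner.variants),
        extra_variants=extra,
        exact=not extra,
        caveats=caveats,
    )


_STAR_RE = re.compile(r"^\*(\d+)([A-Z]*?)(XN)?$")


def _star_sort_key(name: str, copies: int) -> tuple[int, str, int]:
    m = _STAR_RE.match(name)
    if not m:
        return (10**6, name, copies)
    return (int(m.group(1)), m.group(2), copies)


def format_genotype(allele1: str, copies1: int, allele2: str, copies2: int) -> str:
    """Canonical diplotype string, e.g. ``*1B/*2AXN`` or ``*4A/*5``."""
    pair = sorted(
        [(allele1, copies1), (allele2, copies2)],
        key=lambda ac: _star_sort_key(ac[0], ac[1]),
    )
    return "/".join(name + ("XN" if copies > 1 else "") for name, copies in pair)


def call_diplotype(
    hap_calls: Sequence[HaplotypeCall],
    ratio: CoverageRatio,
    evidence: Optional[EvidenceFlags] = None,
    copy_cap: int = 3,
    ratio_band: tuple[float, float] = (1.8, 3.5),
) -> DiplotypeCall:
    """Assemble the diplotype with copy-number state.

    Two balanced haplogroups get one copy each.  With a duplicated ratio the
    higher-support haplogroup (index 1) carries ``round(ratio)`` copies
    (capped; ratios outside ``ratio_band`` add an "ambiguous copy number"
    caveat).  A single haplogroup resolves through the assay evidence:
    deletion positive -> hap/*5; duplication positive -> hap/hapXN; deletion
    negative -> homozygous hap/hap; nothing tested -> homozygous with a
    "deletion not excluded" caveat.
    """
    evidence = evidence or EvidenceFlags()
    if not 1 <= len(hap_calls) <= 2:
        raise ValueError("expected 1 or 2 haplotype calls")
    caveats = [c for hc in hap_calls for c in hc.caveats]
    if len(hap_calls) == 2:
        a1, a2 = hap_calls[0].allele, hap_calls[1].allele
        c1 = c2 = 1
        if ratio.classification == "duplicated":
            copies = min(copy_cap, max(2, round(ratio.ratio)))
            if not ratio_band[0] <= ratio.ratio <= ratio_band[1]:
                caveats.append(f"ambiguous copy number (ratio {ratio.ratio:.2f})")
            # haplogroup calls arrive in haplogroup-index order (1 = higher support)
            if ratio.numerator_index == 1:
                c1 = copies
            else:
                c2 = copies
    else:
        a1 = a2 = hap_calls[0].allele
        c1 = c2 = 1
        if evidence.deletion_assay == "positive":
            a2, c2 = DELETION_ALLELE, 0
            if evidence.duplication_assay == "positive":
                caveats.append("deletion and duplication assays both positive")
        elif evidence.duplication_assay == "positive":
            c2 = 2
        elif evidence.deletion_assay == "untested":
            caveats.append("deletion not excluded")
    return DiplotypeCall(
        allele1=a1,
        allele2=a2,
        copies1=c1,
        copies2=c2,
        genotype_string=format_genotype(a1, c1, a2, c2),
        caveats=caveats,
    )


def _phenotype_from_score(score: float, cutpoints: PhenotypeCutpoints) -> str:
    if score == 0:
        return "poor"
    if score <= cutpoints.intermediate_max:
        return "intermediate"
    if score < cutpoints.ultrarapid_min:
        return "normal"
    return "ultrarapid"


def predict_phenotype(
    diplotype: DiplotypeCall,
    activity_table: Mapping[str, float],
    cutpoints: Optional[PhenotypeCutpoints] = None,
) -> DiplotypeCall:
    """Fill in activity score and metabolizer group of a diplotype call.

    score = sum over both chromosomes of allele activity x copy number.
    Raises ``KeyError`` naming any allele absent from the activity table.
    """
    cutpoints = cutpoints or PhenotypeCutpoints()
    score = 0.0
    for allele, copies in ((diplotype.allele1, diplotype.copies1), (diplotype.allele2, diplotype.copies2)):
        if copies == 0:
            continue
        if allele not in activity_table:
            raise KeyError(f"allele {allele} missing from activity table")
        score += activity_table[allele] * copies
    diplotype.activity_score = score
    diplotype.phenotype = _phenotype_from_score(score, cutpoints)
    return diplotype


def predict_phenotype_from_string(
    genotype: str,
    activity_table: Mapping[str, float],
    cutpoints: Optional[PhenotypeCutpoints] = None,
) -> tuple[str, float]:
    """Phenotype and score straight from a printed diplotype string.

    ``"*9/*41XN"`` parses as one *9 copy plus a duplicated (two-copy) *41;
    the XN suffix counts as two copies.
    """
    parts = genotype.split("/")
    if len(parts) != 2:
        raise ValueError(f"expected two alleles in {genotype!r}")
    alleles: list[tuple[str, int]] = []
    for part in parts:
        m = _STAR_RE.match(part.strip())
        if not m:
            raise ValueError(f"unrecognized allele {part!r} in {genotype!r}")
        name = f"*{m.group(1)}{m.group(2)}"
        alleles.append((name, 2 if m.group(3) else 1))
    (a1, c1), (a2, c2) = alleles
    call = DiplotypeCall(a1, a2, c1, c2, genotype_string=genotype)
    call = predict_phenotype(call, activity_table, cutpoints)
    return call.phenotype, call.activity_score
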