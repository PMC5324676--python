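"""Left-normalize indels in repeat context and render HGVS descriptions.

A deletion inside a homopolymer run has many equivalent placements; left
normalization shifts it to the smallest coordinate so all of them collapse
to one canonical description.  Edits wholly inside runs of eight bases or
more are additionally flagged low-confidence — one-base length wobble in
long runs is the dominant residual error of long-read consensus sequences,
so such calls are excluded from star-allele matching.
"""

from amplistar.fixtures import FIXTURE_HOMOPOLYMER, fixture_reference
from amplistar.variants import (
    NormalizedVariant,
    align_to_reference,
    extract_and_normalize,
    left_normalize,
    parse_hgvs,
)

reference = fixture_reference()
run_start0, base, run_len = FIXTURE_HOMOPOLYMER

print(f"The locus carries a {run_len}-bp {base}-homopolymer at positions "
      f"{run_start0 + 1}-{run_start0 + run_len}.")
for offset in (0, 10, 21):
    raw = NormalizedVariant(run_start0 + 1 + offset, base, "")
    norm = left_normalize(raw, reference)
    print(f"  del{base} placed at {raw.position:>4} -> normalized {norm.hgvs()}")

# the same event seen through alignment of an edited haplotype
haplotype = reference[: run_start0 + 12] + reference[run_start0 + 13 :]
alignment = align_to_reference(haplotype, reference)
(variant,) = extract_and_normalize(alignment, reference)
print(f"\nCalled from an aligned haplotype: {variant.hgvs()} "
      f"(low_confidence={variant.low_confidence})")

# HGVS descriptions round-trip through the parser
for text in ["g.42126133_42126135delTGT", "g.42131610G>C", "g.50_51insACT"]:
    v = parse_hgvs(text)
    assert v.hgvs() == text
    print(f"parsed {text:>28} -> position {v.position}, class {v.vclass}")
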