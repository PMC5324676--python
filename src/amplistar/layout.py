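"""Amplicon adornment layout: padding, symmetric barcodes, M13 tails, primers.

Two-step barcoding builds every sequenced molecule as

    padding + barcode + M13F + gene primer F + insert
            + rc(gene primer R) + rc(M13R) + rc(barcode) + rc(padding)

with the *same* barcode at both ends (symmetric scheme).  The 5' padding
gives all fragments identical terminal sequence so adapter ligation is
unbiased; its length/content is a free design choice here (a fixed 5-mer).
The direct-barcoding scheme is the same layout with empty M13 tails, so it
is a preset rather than a separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from amplistar.sequences import revcomp


@dataclass(frozen=True)
class AdornmentLayout:
    padding: str = "GGTAG"
    barcode_length: int = 16
    m13_forward: str = "TGTAAAACGACGGCCAGT"
    m13_reverse: str = "CAGGAAACAGCTATGACC"
    primer_forward: str = "ACGAGCTTGGCATTCGACTTAGCC"
    primer_reverse: str = "TGGACCTAGCGAACGTTCATCAGG"

    @classmethod
    def direct(cls) -> "AdornmentLayout":
        """Direct-barcoding preset: barcode fused to the gene primer."""
        return cls(m13_forward="", m13_reverse="")

    @property
    def anchor_forward(self) -> str:
        """Sequence immediately following the barcode on the plus strand."""
        return self.m13_forward or self.primer_forward

    @property
    def anchor_reverse(self) -> str:
        """Sequence immediately following the barcode on the minus strand."""
        return self.m13_reverse or self.primer_reverse

    def left_adornment(self, barcode: str) -> str:
        return self.padding + barcode + self.m13_forward + self.primer_forward

    def right_adornment(self, barcode: str) -> str:
        return revcomp(self.padding + barcode + self.m13_reverse + self.primer_reverse)

    def assemble(self, barcode: str, insert: str) -> str:
        """Full plus-strand molecule for one insert."""
        if len(barcode) != self.barcode_length:
            raise ValueError(
                f"barcode length {len(barcode)} != layout barcode_length {self.barcode_length}"
            )
        return self.left_adornment(barcode) + insert + self.right_adornment(barcode)
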