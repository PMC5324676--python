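"""Barcode demultiplexing, strand orientation and adornment trimming.

A read is assigned to a sample only when the best-scoring barcode at BOTH
ends is that sample's barcode (within the mismatch budget) and the runner-up
barcode is strictly worse at both ends; anything else lands in the
unassigned pool with a reason.  Barcodes sit at a fixed offset from the M13
anchor by construction, so the anchor is located indel-tolerantly
(semi-global alignment) and the barcode is read off at its offset and
compared by Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import edlib

from amplistar.layout import AdornmentLayout
from amplistar.sequences import revcomp


@dataclass
class Read:
    """A (possibly processed) long read with provenance.

    ``strand`` records the strand the molecule was sequenced on relative to
    the locus plus strand; after orientation the *sequence* is always plus
    strand while the flag keeps the original strand.
    """

    id: str
    sequence: str
    quality: list[int]
    sample_id: Optional[str] = None
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class DemuxConfig:
    max_barcode_mismatches: int = 2
    trim_end_bases: int = 21
    min_read_length: int = 6000

    def __post_init__(self) -> None:
        if min(self.max_barcode_mismatches, self.trim_end_bases, self.min_read_length) < 0:
            raise ValueError("demux parameters must be non-negative")


@dataclass
class DemuxResult:
    assigned: dict[str, list[Read]]
    unassigned: list[tuple[Read, str]]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def _anchor_budget(anchor: str) -> int:
    return max(2, len(anchor) // 4)


def _locate(anchor: str, window: str) -> Optional[tuple[int, int, int]]:
    """Best infix match of anchor in window: (edit_distance, start, end)."""
    if not anchor or not window:
        return None
    res = edlib.align(anchor, window, mode="HW", task="locations", k=_anchor_budget(anchor))
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end


def _end_barcode(read_seq: str, layout: AdornmentLayout, terminal: str) -> tuple[Optional[str], Optional[str]]:
    """Extract the barcode-bearing window at one read end.

    ``terminal`` is "start" or "end".  Returns (window, strand) where strand
    is the molecule strand implied by which anchor (M13F vs M13R) was found.
    On the plus strand the read starts with padding+barcode+M13F and ends
    with rc(M13R)+rc(barcode)+rc(padding); the minus strand swaps F and R.
    The window covers the barcode position by construction plus a few bases
    of slack so indels upstream of the anchor cannot shift the barcode out.
    """
    bc_len = layout.barcode_length
    window_len = len(layout.padding) + bc_len + max(len(layout.anchor_forward), len(layout.anchor_reverse)) + 12
    slack = 4
    hits: list[tuple[int, str, str]] = []  # (distance, barcode window, strand)
    if terminal == "start":
        window = read_seq[:window_len]
        for anchor, strand in ((layout.anchor_forward, "+"), (layout.anchor_reverse, "-")):
            loc = _locate(anchor, window)
            if loc is None:
                continue
            dist, start, _ = loc
            lo = max(0, start - bc_len - slack)
            if start > 0:
                hits.append((dist, window[lo:start], strand))
    else:
        window = read_seq[-window_len:]
        for anchor, strand in ((layout.anchor_reverse, "+"), (layout.anchor_forward, "-")):
            loc = _locate(revcomp(anchor), window)
            if loc is None:
                continue
            dist, _, end = loc
            hi = min(len(window), end + 1 + bc_len + slack)
            if end + 1 < len(window):
                hits.append((dist, revcomp(window[end + 1 : hi]), strand))
    if not hits:
        return None, None
    hits.sort(key=lambda h: h[0])
    return hits[0][1], hits[0][2]


def _match_barcode(
    observed_window: str, barcodes: Mapping[str, str], max_mismatches: int
) -> tuple[Optional[str], bool]:
    """(best sample or None, second_best_strictly_worse).

    Each candidate barcode is scored by its best infix (semi-global) edit
    distance within the barcode window, so indels inside the barcode cost
    one each instead of derailing a fixed-offset comparison.
    """
    scored = []
    for sid, bc in barcodes.items():
        res = edlib.align(bc, observed_window, mode="HW", task="distance")
        scored.append((res["editDistance"], sid))
    scored.sort()
    best_dist, best_sample = scored[0]
    if best_dist > max_mismatches:
        return None, True
    strictly_better = len(scored) == 1 or scored[1][0] > best_dist
    return best_sample, strictly_better


def demultiplex(
    reads: Iterable[Read],
    sample_sheet: Mapping[str, str],
    config: Optional[DemuxConfig] = None,
    layout: Optional[AdornmentLayout] = None,
) -> DemuxResult:
    """Assign reads to samples by their symmetric end barcodes.

    ``sample_sheet`` maps sample_id -> barcode sequence.  Assignment is
    exclusive: the assigned per-sample sets are pairwise disjoint and
    together with the unassigned pool partition the input.
    """
    config = config or DemuxConfig()
    layout = layout or AdornmentLayout()
    if not sample_sheet:
        raise ValueError("empty sample sheet")
    barcodes = dict(sample_sheet)
    lengths = {len(bc) for bc in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcodes in sample sheet")
    (bc_len,) = lengths
    if bc_len != layout.barcode_length:
        raise ValueError("sample sheet barcode length differs from layout")
    assigned: dict[str, list[Read]] = {sid: [] for sid in barcodes}
    unassigned: list[tuple[Read, str]] = []
    for read in reads:
        bc_start, strand_start = _end_barcode(read.sequence, layout, "start")
        bc_end, strand_end = _end_barcode(read.sequence, layout, "end")
        if bc_start is None or bc_end is None:
            unassigned.append((read, "anchor not found"))
            continue
        if strand_start != strand_end:
            unassigned.append((read, "strand conflict between ends"))
            continue
        s1, unique1 = _match_barcode(bc_start, barcodes, config.max_barcode_mismatches)
        s2, unique2 = _match_barcode(bc_end, barcodes, config.max_barcode_mismatches)
        if s1 is None or s2 is None:
            unassigned.append((read, "barcode beyond mismatch budget"))
            continue
        if s1 != s2:
            unassigned.append((read, "end barcodes disagree"))
            continue
        if not (unique1 and unique2):
            unassigned.append((read, "ambiguous barcode"))
            continue
        read.sample_id = s1
        read.strand = strand_start
        assigned[s1].append(read)
    return DemuxResult(assigned, unassigned)


def orient_and_trim(
    read: Read,
    layout: Optional[AdornmentLayout] = None,
    config: Optional[DemuxConfig] = None,
) -> tuple[Optional[Read], str]:
    """Orient a read to the plus strand and strip all adornments.

    Returns ``(trimmed_read, reason)``; the read is ``None`` (dropped) when a
    gene primer cannot be located within the mismatch budget at either end.
    Orienting an already-plus read is a no-op on the sequence.  The
    ``trim_end_bases`` window is *not* removed here: the terminal bases stay
    part of the insert but are treated as unreliable for variant support
    downstream (the variant caller masks them).
    """
    layout = layout or AdornmentLayout()
    config = config or DemuxConfig()
    seq, qual = read.sequence, read.quality
    strand = read.strand
    if strand == "unknown":
        _, strand = _end_barcode(seq, layout, "start")
        if strand is None:
            return None, "orientation anchor not found"
    if strand == "-":
        seq = revcomp(seq)
        qual = qual[::-1]
    prefix_len = len(layout.padding) + layout.barcode_length + len(layout.m13_forward) + len(layout.primer_forward) + 16
    loc_f = _locate(layout.primer_forward, seq[:prefix_len])
    if loc_f is None:
        return None, "forward primer not found"
    insert_start = loc_f[2] + 1
    win_start = max(0, len(seq) - prefix_len)
    loc_r = _locate(revcomp(layout.primer_reverse), seq[win_start:])
    if loc_r is None:
        return None, "reverse primer not found"
    insert_end = win_start + loc_r[1]
    if insert_end <= insert_start:
        return None, "primers overlap"
    trimmed = Read(
        id=read.id,
        sequence=seq[insert_start:insert_end],
        quality=qual[insert_start:insert_end],
        sample_id=read.sample_id,
        strand=strand,
    )
    return trimmed, "ok"


def length_filter(reads: Iterable[Read], config: DemuxConfig) -> tuple[list[Read], list[Read]]:
    """Partition trimmed reads into (usable, too_short) by minimum length."""
    usable, short = [], []
    for r in reads:
        (usable if len(r.sequence) >= config.min_read_length else short).append(r)
    return usable, short
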