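"""Reference-free clustering of a sample's reads into haplogroup consensuses.

This is a desk-scale re-implementation of the long-amplicon-analysis stage:
reads from one sample are clustered by sequence identity, each cluster is
polished into a consensus by iterative realign-and-majority voting, and
clusters are split when a sufficiently large subset of reads consistently
co-votes against the consensus at two or more discriminating columns (the
signature of a second haplotype hiding in the cluster).  Spurious low-support
or off-length consensuses are filtered automatically, replacing manual
inspection of length and subread coverage.

The subread-support ratio between the two retained haplogroups carries the
copy-number signal: ~1 for a balanced diploid, ~2+ when one haplotype is
duplicated.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from amplistar.sequences import decode, encode, homopolymer_runs

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: vote codes: A,C,G,T as 0..3 plus 4 for a deletion vote
_GAP = 4


@dataclass(frozen=True)
class PhasingConfig:
    max_subreads: int = 800
    min_support_fraction: float = 0.1
    length_window: float = 0.2
    max_haplogroups: int = 4
    duplication_threshold: float = 1.8
    seed: int = 0
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support_fraction < 0.5:
            raise ValueError("min_support_fraction must be in (0, 0.5)")
        if self.max_subreads < 10:
            raise ValueError("max_subreads must be >= 10")
        if self.duplication_threshold <= 1.0:
            raise ValueError("duplication_threshold must exceed 1")


@dataclass
class ReadCluster:
    """A set of reads believed to originate from one haplotype."""

    read_ids: list[str]
    consensus: str

    @property
    def support(self) -> int:
        return len(self.read_ids)


@dataclass
class HaplogroupConsensus:
    """One phased consensus sequence with its subread support."""

    sample_id: str
    index: int  # 1-based, ordered by descending support after filtering
    sequence: str
    support: int
    member_reads: list[str]

    def __post_init__(self) -> None:
        if self.support != len(self.member_reads):
            raise ValueError("support must equal the number of member reads")


@dataclass(frozen=True)
class CoverageRatio:
    """Support ratio between the two haplogroups (>= 1 by construction)."""

    numerator_index: int
    denominator_index: int
    ratio: float
    classification: str  # balanced | duplicated | single


# ---------------------------------------------------------------------------
# pileup machinery


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _pileup(
    member_codes: Sequence[np.ndarray],
    consensus_codes: np.ndarray,
    consensus: str,
    want_per_read: bool = False,
) -> tuple[np.ndarray, list[Counter], list[dict[int, int]]]:
    """Column votes of members against the consensus.

    Returns ``(votes, ins_votes, per_read)`` where ``votes`` is an (L, 5)
    count matrix (A,C,G,T,deletion), ``ins_votes[j]`` counts inserted strings
    at the junction before consensus position ``j``, and ``per_read`` (when
    requested) holds each member's deviating columns as {position: vote}.
    """
    L = len(consensus_codes)
    votes = np.zeros((L, 5), dtype=np.int32)
    ins_votes: list[Counter] = [Counter() for _ in range(L + 1)]
    per_read: list[dict[int, int]] = []
    for codes in member_codes:
        res = edlib.align(decode(codes), consensus, task="path")
        qpos = tpos = 0
        devs: dict[int, int] = {}
        for count, op in _parse_cigar(res["cigar"]):
            if op in "=M":
                np.add.at(votes, (np.arange(tpos, tpos + count), codes[qpos : qpos + count]), 1)
                if op == "M" and want_per_read:
                    seg = codes[qpos : qpos + count]
                    mism = np.nonzero(seg != consensus_codes[tpos : tpos + count])[0]
                    for k in mism:
                        devs[tpos + int(k)] = int(seg[k])
                qpos += count
                tpos += count
            elif op == "X":
                seg = codes[qpos : qpos + count]
                np.add.at(votes, (np.arange(tpos, tpos + count), seg), 1)
                if want_per_read:
                    for k in range(count):
                        devs[tpos + k] = int(seg[k])
                qpos += count
                tpos += count
            elif op == "D":  # consensus bases absent from the member
                votes[tpos : tpos + count, _GAP] += 1
                if want_per_read:
                    for k in range(count):
                        devs[tpos + k] = _GAP
                tpos += count
            else:  # I: extra member bases at this junction
                ins = decode(codes[qpos : qpos + count])
                # left-normalize the placement so equivalent insertions in
                # repeat context (where aligners place them inconsistently
                # between reads) pool their votes at one junction
                j = tpos
                while j > 0 and ins[-1] == consensus[j - 1]:
                    ins = consensus[j - 1] + ins[:-1]
                    j -= 1
                ins_votes[j][ins] += 1
                qpos += count
        if want_per_read:
            per_read.append(devs)
    return votes, ins_votes, per_read


def _event_floor(n_members: int) -> int:
    """Minimum vote count for an indel event to change the consensus.

    Under a ~10% single-pass error rate roughly half the members carry a
    local error near any given junction, fragmenting their votes, so a true
    missing base only gathers ~50-60% of members while indel noise stays
    below ~25%; a fractional bar of 35% with an absolute floor of 4 (which
    keeps tiny clusters from amplifying their own noise) separates the two.
    """
    return max(4, math.ceil(0.35 * n_members))


def _majority_consensus(
    votes: np.ndarray,
    ins_votes: list[Counter],
    consensus_codes: np.ndarray,
    n_members: int,
) -> str:
    """Per-column vote resolution; ties prefer the current consensus base.

    Bases win by plurality.  A column is deleted, or a junction gains the
    plurality insertion string, only when the indel votes also reach
    :func:`_event_floor` — plain majorities are too fragile in small
    clusters and at error-fragmented junctions.
    """
    L = len(consensus_codes)
    maxc = votes.max(axis=1)
    winners = votes.argmax(axis=1)
    cons_counts = votes[np.arange(L), consensus_codes]
    keep_cons = cons_counts == maxc
    winners[keep_cons] = consensus_codes[keep_cons]
    floor = _event_floor(n_members)
    weak_gap = (winners == _GAP) & (votes[:, _GAP] < floor)
    if np.any(weak_gap):
        base_winners = votes[:, :4].argmax(axis=1)
        winners[weak_gap] = base_winners[weak_gap]
    pieces: list[str] = []
    for j in range(L + 1):
        if ins_votes[j]:
            total = sum(ins_votes[j].values())
            if total >= floor:
                ins, _ = max(ins_votes[j].items(), key=lambda kv: (kv[1], kv[0]))
                pieces.append(ins)
        if j < L and winners[j] != _GAP:
            pieces.append("ACGT"[winners[j]])
    return "".join(pieces)


def _as_id_seq(reads: Iterable) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"read{i:06d}", r))
        elif isinstance(r, tuple):
            out.append(r)
        else:
            out.append((r.id, r.sequence))
    return out


def _repair_contested_runs(consensus: str, member_codes: list[np.ndarray], floor: int) -> str:
    """Fix substitutions swallowed by homopolymer runs.

    When the consensus erroneously extends a run over a true substitution
    (e.g. truth ``AAAAAGAAA`` polished to nine A's), the members' votes for
    the true base fragment across the run's columns — every equal-cost
    mismatch placement is chosen by some member — so no single column can
    win the vote back.  This pass pools alternative-base votes per run and,
    when they reach the event floor, tries substituting that base at each
    run position, keeping the placement that strictly lowers the summed
    member edit distance (the objective the column votes approximate).
    """
    for _ in range(4):
        cons_codes = encode(consensus)
        votes, _, _ = _pileup(member_codes, cons_codes, consensus)
        best_change = None
        for start, end, base in homopolymer_runs(consensus, 3):
            pooled = votes[start:end, :4].sum(axis=0)
            pooled["ACGT".index(base)] = 0
            alt = int(pooled.argmax())
            if pooled[alt] < floor:
                continue
            base_total = sum(
                _edit_distance(decode(c), consensus) for c in member_codes
            )
            for pos in range(start, end):
                cand = consensus[:pos] + "ACGT"[alt] + consensus[pos + 1 :]
                total = sum(_edit_distance(decode(c), cand) for c in member_codes)
                if total < base_total and (
                    best_change is None or total < best_change[0]
                ):
                    best_change = (total, cand)
        if best_change is None:
            return consensus
        consensus = best_change[1]
    return consensus


def polish_consensus(
    members: Iterable,
    init: Optional[str] = None,
    max_rounds: int = 5,
) -> str:
    """Iterative realign-and-majority consensus of a read cluster.

    Members may be ``Read`` objects, ``(id, sequence)`` tuples or plain
    strings; they are processed in read-id order, so the result is
    deterministic regardless of input order.  Starting from ``init`` (or the
    first member), every round realigns each member to the current consensus
    and replaces each column by its vote winner (indel events gated by the
    event floor), until the sequence is fixed or ``max_rounds`` is reached;
    a final pass repairs substitutions hidden inside homopolymer runs.
    """
    items = sorted(_as_id_seq(members), key=lambda t: t[0])
    if not items:
        raise ValueError("cannot polish an empty cluster")
    codes = [encode(s) for _, s in items]
    consensus = init if init is not None else items[0][1]
    for _ in range(max_rounds):
        cons_codes = encode(consensus)
        votes, ins_votes, _ = _pileup(codes, cons_codes, consensus)
        new = _majority_consensus(votes, ins_votes, cons_codes, len(items))
        if new == consensus:
            break
        consensus = new
    if len(items) > 1:
        consensus = _repair_contested_runs(consensus, codes, _event_floor(len(items)))
    return consensus


# ---------------------------------------------------------------------------
# clustering


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _consensus_run_lengths(consensus: str) -> np.ndarray:
    """Homopolymer run length covering each consensus position."""
    L = len(consensus)
    out = np.empty(L, dtype=np.int32)
    i = 0
    while i < L:
        j = i + 1
        while j < L and consensus[j] == consensus[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def _find_split(
    member_codes: list[np.ndarray],
    consensus: str,
    threshold: int,
    max_candidates: int = 10,
) -> Optional[list[int]]:
    """Indices (local) of a read subset that co-votes >= 2 discriminating columns.

    A column is discriminating when at least ``threshold`` members vote the
    same non-consensus base there.  Deletion votes are noisier than
    substitution votes under an indel-dominant error profile (and pile up at
    the left edge of homopolymer runs), so deletion columns are ignored
    inside runs of length >= 3 and elsewhere need support from a quarter of
    the cluster.  A split requires two columns whose minority supporters
    overlap in >= ``threshold`` reads and cohere (the overlap covers >= 60%
    of the smaller supporter set), at least one of them a substitution
    column: deletion-only pairs are within noise reach even in a pure
    cluster, so two haplotypes distinguished *solely* by indels fold into a
    single haplogroup (a documented limitation).
    """
    cons_codes = encode(consensus)
    votes, _, per_read = _pileup(member_codes, cons_codes, consensus, want_per_read=True)
    runlen = _consensus_run_lengths(consensus)
    del_threshold = max(threshold, math.ceil(0.25 * len(member_codes)))
    candidates: list[tuple[int, int, int]] = []  # (count, pos, code)
    for pos, code in zip(*np.nonzero(votes >= threshold)):
        if code == cons_codes[pos]:
            continue
        if code == _GAP and (runlen[pos] >= 3 or votes[pos, code] < del_threshold):
            continue
        candidates.append((int(votes[pos, code]), int(pos), int(code)))
    if len(candidates) < 2:
        return None
    candidates.sort(reverse=True)
    candidates = candidates[:max_candidates]
    supporters = []
    for _, pos, code in candidates:
        supporters.append({k for k, devs in enumerate(per_read) if devs.get(pos) == code})
    best: Optional[set[int]] = None
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if candidates[i][2] == _GAP and candidates[j][2] == _GAP:
                continue
            inter = supporters[i] & supporters[j]
            if len(inter) < threshold:
                continue
            if len(inter) < 0.6 * min(len(supporters[i]), len(supporters[j])):
                continue
            if best is None or len(inter) > len(best):
                best = inter
    if best is None:
        return None
    # widen the seed to the full co-voting signature: take every candidate
    # column coherent with the pair, then every read supporting at least
    # half of those columns, so the new cluster starts large enough to
    # polish a clean consensus
    sig = [s for s in supporters if len(s & best) >= 0.6 * len(best)]
    members = {
        k
        for k in range(len(member_codes))
        if sum(k in s for s in sig) * 2 >= len(sig)
    }
    if len(members) < threshold or len(members) == len(member_codes):
        return None
    return sorted(members)


def _assign_by_discriminating_columns(
    member_codes: list[np.ndarray],
    consensuses: list[str],
    prev_assign: np.ndarray,
    threshold: int,
) -> np.ndarray:
    """Assign each read to the consensus its bases agree with most.

    Scoring is restricted to *bimodal* columns: positions (in the first
    consensus's coordinates) where the consensuses disagree and where both
    the anchor allele and a rival allele are voted by at least ``threshold``
    reads in the pooled pileup.  Residual consensus errors elsewhere are
    thereby invisible to assignment — whole-read edit distance (or naive
    consensus-vs-consensus differences) would let a freshly split cluster's
    rougher consensus repel its own reads.  Deletion columns inside
    homopolymer runs are excluded as in the split test.  Ties keep the
    previous assignment, then prefer the lower cluster index.
    """
    k = len(consensuses)
    n = len(member_codes)
    if k == 1:
        return np.zeros(n, dtype=np.int64)
    anchor = consensuses[0]
    anchor_codes = encode(anchor)
    votes, _, per_read = _pileup(member_codes, anchor_codes, anchor, want_per_read=True)
    runlen = _consensus_run_lengths(anchor)
    profiles: list[dict[int, int]] = [{}]
    for ci in range(1, k):
        _, _, per = _pileup([encode(consensuses[ci])], anchor_codes, anchor, want_per_read=True)
        profiles.append(per[0])
    disc: list[int] = []
    for pos in sorted(set().union(*(set(p) for p in profiles))):
        alleles = {int(anchor_codes[pos])} | {
            p[pos] for p in profiles if pos in p
        }
        if any(a == _GAP for a in alleles) and runlen[pos] >= 3:
            continue
        supported = [a for a in alleles if votes[pos, a] >= threshold]
        if len(supported) >= 2:
            disc.append(pos)
    if not disc:
        return np.zeros(n, dtype=np.int64)
    vals = np.array(
        [[p.get(pos, int(anchor_codes[pos])) for pos in disc] for p in profiles]
    )
    new_assign = np.empty(n, dtype=np.int64)
    for r in range(n):
        rv = np.array([per_read[r].get(pos, int(anchor_codes[pos])) for pos in disc])
        scores = (vals == rv).sum(axis=1)
        best = scores.max()
        tied = np.nonzero(scores == best)[0]
        if prev_assign[r] in tied:
            new_assign[r] = prev_assign[r]
        else:
            new_assign[r] = int(tied[0])
    return new_assign


def cluster_reads(reads: Iterable, config: Optional[PhasingConfig] = None) -> list[ReadCluster]:
    """Cluster one sample's reads into per-haplotype read sets.

    Procedure: seed a single cluster from the medoid read, polish a
    consensus, then iterate (split test -> reassignment by alignment
    distance -> re-polish) to a fixed point or ``max_rounds`` rounds.  Every
    retained read belongs to exactly one cluster.  Raises ``ValueError``
    ("insufficient coverage") below 3 usable reads; above ``max_subreads``
    reads are uniformly subsampled (seeded).
    """
    config = config or PhasingConfig()
    items = sorted(_as_id_seq(reads), key=lambda t: t[0])
    if len(items) < 3:
        raise ValueError("insufficient coverage: need at least 3 reads")
    rng = np.random.default_rng(config.seed)
    if len(items) > config.max_subreads:
        keep = sorted(rng.choice(len(items), size=config.max_subreads, replace=False))
        items = [items[i] for i in keep]
    ids = [i for i, _ in items]
    seqs = [s for _, s in items]
    codes = [encode(s) for s in seqs]
    n = len(items)

    cand = sorted(rng.choice(n, size=min(20, n), replace=False))
    totals = [sum(_edit_distance(seqs[i], seqs[j]) for j in cand if j != i) for i in cand]
    medoid = cand[int(np.argmin(totals))]

    assign = np.zeros(n, dtype=np.int64)
    consensuses = [polish_consensus(items, init=seqs[medoid])]

    for _ in range(config.max_rounds):
        split_done = False
        if len(consensuses) < config.max_haplogroups:
            for ci in range(len(consensuses)):
                member_idx = np.nonzero(assign == ci)[0]
                if len(member_idx) < 4:
                    continue
                # absolute floor 4: two or three co-voting reads are within
                # indel-noise reach even in a pure cluster
                thr = max(4, math.ceil(config.min_support_fraction * len(member_idx)))
                local = _find_split([codes[k] for k in member_idx], consensuses[ci], thr)
                if local:
                    new_ci = len(consensuses)
                    split_members = member_idx[local]
                    assign[split_members] = new_ci
                    # init from the parent consensus: a raw read is a poor
                    # starting point for a small cluster's polish
                    consensuses.append(
                        polish_consensus(
                            [items[k] for k in split_members], init=consensuses[ci]
                        )
                    )
                    consensuses[ci] = polish_consensus(
                        [items[k] for k in np.nonzero(assign == ci)[0]],
                        init=consensuses[ci],
                    )
                    split_done = True
                    break
        global_thr = max(4, math.ceil(config.min_support_fraction * n))
        new_assign = _assign_by_discriminating_columns(codes, consensuses, assign, global_thr)
        moved = bool(np.any(new_assign != assign))
        # drop empty clusters, keep order
        occupied = [ci for ci in range(len(consensuses)) if np.any(new_assign == ci)]
        remap = {ci: i for i, ci in enumerate(occupied)}
        assign = np.array([remap[a] for a in new_assign], dtype=np.int64)
        consensuses = [
            polish_consensus(
                [items[k] for k in np.nonzero(assign == i)[0]], init=consensuses[ci]
            )
            for i, ci in enumerate(occupied)
        ]
        if not (split_done or moved):
            break
    return [
        ReadCluster(
            read_ids=[ids[k] for k in np.nonzero(assign == ci)[0]],
            consensus=consensuses[ci],
        )
        for ci in range(len(consensuses))
    ]


# ---------------------------------------------------------------------------
# haplogroup filtering and the coverage-ratio CNV signal


def clusters_to_haplogroups(sample_id: str, clusters: Sequence[ReadCluster]) -> list[HaplogroupConsensus]:
    """Wrap raw clusters as (not yet filtered) haplogroup consensuses."""
    return [
        HaplogroupConsensus(
            sample_id=sample_id,
            index=i + 1,
            sequence=c.consensus,
            support=c.support,
            member_reads=list(c.read_ids),
        )
        for i, c in enumerate(clusters)
    ]


def filter_haplogroups(
    consensuses: Sequence[HaplogroupConsensus],
    config: Optional[PhasingConfig] = None,
) -> list[HaplogroupConsensus]:
    """Drop artefact consensuses, merge duplicates, re-index by support.

    A consensus is an artefact when its support is below
    ``min_support_fraction`` of the total or its length falls outside
    ``(1 +/- length_window)`` times the median consensus length.  Surviving
    identical sequences are merged (supports summed).  Raises ``ValueError``
    when nothing survives.
    """
    config = config or PhasingConfig()
    if not consensuses:
        raise ValueError("no consensus sequences provided")
    total = sum(c.support for c in consensuses)
    median_len = float(np.median([len(c.sequence) for c in consensuses]))
    lo = (1.0 - config.length_window) * median_len
    hi = (1.0 + config.length_window) * median_len
    survivors = [
        c
        for c in consensuses
        if c.support >= config.min_support_fraction * total and lo <= len(c.sequence) <= hi
    ]
    if not survivors:
        raise ValueError("no haplogroup passes filters")
    merged: dict[str, HaplogroupConsensus] = {}
    for c in survivors:
        if c.sequence in merged:
            prev = merged[c.sequence]
            merged[c.sequence] = HaplogroupConsensus(
                sample_id=prev.sample_id,
                index=prev.index,
                sequence=prev.sequence,
                support=prev.support + c.support,
                member_reads=prev.member_reads + c.member_reads,
            )
        else:
            merged[c.sequence] = c
    out = sorted(merged.values(), key=lambda c: (-c.support, c.sequence))
    return [
        HaplogroupConsensus(
            sample_id=c.sample_id,
            index=i + 1,
            sequence=c.sequence,
            support=c.support,
            member_reads=c.member_reads,
        )
        for i, c in enumerate(out)
    ]


def coverage_ratio(
    haplogroups: Sequence[HaplogroupConsensus],
    duplication_threshold: float = 1.8,
) -> CoverageRatio:
    """Support ratio of the two haplogroups and its copy-number reading.

    One haplogroup -> "single" (deletion vs homozygosity needs orthogonal
    evidence).  Two -> larger/smaller support; "duplicated" when the ratio
    reaches ``duplication_threshold``, else "balanced".  More than two is an
    unresolved mixture and an error.
    """
    if not 1 <= len(haplogroups) <= 2:
        raise ValueError("unresolved mixture: expected 1 or 2 haplogroups")
    if any(h.support <= 0 for h in haplogroups):
        raise ValueError("haplogroup with zero support")
    if len(haplogroups) == 1:
        return CoverageRatio(1, 1, 1.0, "single")
    a, b = haplogroups
    num, den = (a, b) if a.support >= b.support else (b, a)
    ratio = num.support / den.support
    cls = "duplicated" if ratio >= duplication_threshold else "balanced"
    return CoverageRatio(num.index, den.index, ratio, cls)
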