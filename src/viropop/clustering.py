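"""Dereplication of viral contigs into populations and breakage analysis.

Contigs sharing >= 95% average nucleotide identity (ANI) over >= 85% of the
shorter contig's length are collapsed into one species-rank "viral
population"; the longest member represents the cluster.  Clustering is
greedy longest-first (ClusterGenomes-style), not single-linkage: each
still-unassigned contig, taken in decreasing length order, seeds a
population and absorbs every unassigned shorter contig that passes the
ANI/coverage test against *it*.

Breakage analysis quantifies how much of a (typically long-read) population
representative is recovered by shorter (typically short-read) assemblies:
the union of member alignment footprints on the representative is taken and
each maximal uncovered run — terminal runs included — counts as one
breakage.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from viropop.core_io import AlignmentRecord, ContigRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ViralPopulation",
    "BreakageReport",
    "pairwise_ani",
    "cluster_populations",
    "breakage_analysis",
]


@dataclass
class ViralPopulation:
    """A species-rank cluster of contigs with its longest member as representative."""

    rep_id: str
    rep_length: int
    rep_source: str
    member_ids: list[str]
    mixed_source: bool

    def __post_init__(self) -> None:
        if self.rep_id not in self.member_ids:
            raise ValueError("representative must be a member of its population")


@dataclass
class BreakageReport:
    """Coverage of a representative by member alignments and its gap count."""

    rep_id: str
    covered_intervals: list[tuple[int, int]]
    n_breakages: int
    pct_aligned: float


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping half-open intervals into a sorted disjoint set."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def pairwise_ani(
    alignments: list[AlignmentRecord], query_id: str, target_id: str
) -> tuple[float, float]:
    """ANI and query coverage between two contigs from their alignment blocks.

    ANI is the match-weighted mean over all blocks between the pair
    (sum of matches / sum of aligned lengths); coverage is the fraction of
    ``query_id`` covered by the union of its alignment intervals.  Blocks
    recorded in either orientation are accepted.  With no alignments the
    result is ``(0.0, 0.0)``.
    """
    matches = 0
    aln_len = 0
    q_intervals: list[tuple[int, int]] = []
    query_len: int | None = None
    for rec in alignments:
        if rec.query_id == query_id and rec.target_id == target_id:
            q_intervals.append((rec.query_start, rec.query_end))
            query_len = rec.query_len
        elif rec.query_id == target_id and rec.target_id == query_id:
            q_intervals.append((rec.target_start, rec.target_end))
            query_len = rec.target_len
        else:
            continue
        matches += rec.n_matches
        aln_len += rec.aln_len
    if aln_len == 0 or query_len is None:
        return 0.0, 0.0
    covered = sum(e - s for s, e in _union_intervals(q_intervals))
    return matches / aln_len, covered / query_len


def cluster_populations(
    contigs: list[ContigRecord],
    alignments: list[AlignmentRecord],
    min_ani: float = 0.95,
    min_cov: float = 0.85,
) -> list[ViralPopulation]:
    """Greedy longest-first dereplication into viral populations.

    Contigs are sorted by length descending (ties by id); each unassigned
    contig seeds a population and absorbs every unassigned shorter contig
    whose ANI >= ``min_ani`` and whose coverage — measured on the shorter
    contig — is >= ``min_cov``.  The output partitions the input.
    """
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in input")
    by_pair: dict[frozenset, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_pair[frozenset((rec.query_id, rec.target_id))].append(rec)

    order = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    source = {c.contig_id: c.source_tech for c in contigs}
    assigned: set[str] = set()
    populations: list[ViralPopulation] = []
    for seed in order:
        if seed.contig_id in assigned:
            continue
        members = [seed.contig_id]
        assigned.add(seed.contig_id)
        for cand in order:
            if cand.contig_id in assigned:
                continue
            pair = by_pair.get(frozenset((seed.contig_id, cand.contig_id)))
            if not pair:
                continue
            # coverage denominator: the shorter (candidate) contig
            ani, cov = pairwise_ani(pair, cand.contig_id, seed.contig_id)
            if ani >= min_ani and cov >= min_cov:
                members.append(cand.contig_id)
                assigned.add(cand.contig_id)
        sources = {source[m] for m in members}
        populations.append(
            ViralPopulation(
                rep_id=seed.contig_id,
                rep_length=seed.length,
                rep_source=seed.source_tech,
                member_ids=members,
                mixed_source=len(sources) > 1,
            )
        )
    return populations


def breakage_analysis(
    rep: ContigRecord,
    member_alignments: list[AlignmentRecord],
    min_member_len: int = 0,
) -> BreakageReport:
    """Coverage of a representative by member contigs and the breakage count.

    Alignments whose query is shorter than ``min_member_len`` are ignored
    (the fragmentation survey of all short-read contigs uses 1 kb).  The
    union of target intervals on the representative is computed; every
    maximal uncovered run, including terminal ones, counts as one breakage.
    """
    intervals: list[tuple[int, int]] = []
    for rec in member_alignments:
        if rec.target_id != rep.contig_id:
            continue
        if rec.query_len < min_member_len:
            continue
        if rec.target_end > rep.length:
            raise ValueError(
                f"alignment [{rec.target_start},{rec.target_end}) exceeds "
                f"representative length {rep.length}"
            )
        intervals.append((rec.target_start, rec.target_end))
    covered = _union_intervals(intervals)
    covered_bp = sum(e - s for s, e in covered)
    # uncovered maximal runs, terminal runs included
    n_breakages = 0
    cursor = 0
    for s, e in covered:
        if s > cursor:
            n_breakages += 1
        cursor = e
    if cursor < rep.length:
        n_breakages += 1
    return BreakageReport(
        rep_id=rep.contig_id,
        covered_intervals=covered,
        n_breakages=n_breakages,
        pct_aligned=100.0 * covered_bp / rep.length,
    )
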