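"""Virus--host linkage scoring from prophage-BLAST, tRNA-match and WIsH evidence.

Each evidence kind contributes a tier score per (virus, MAG) pair:

=====================  =================================================
prophage BLAST         4: >=98% id and >=90% cov; 3: >=90% id, >=75% cov;
                       2: >=90% id, >=50% cov; 1: >=90% id, >=30% cov
tRNA match             3: 100% id; 2: >=95%; 1: >=90%
WIsH                   2.5: p <= 1e-10; 2: p <= 1e-5
=====================  =================================================

Tiers are additive across kinds; a pair with a combined score >= 3 is a
putative host assignment.  When several evidence rows of one kind exist for
a pair, only the best tier counts (no double counting).  All thresholds are
inclusive.

MAG bin quality is scored as completeness - 2 x contamination, with a
quality gate of >= 70% completeness and <= 10% contamination.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HostEvidence",
    "HostLinkage",
    "BinQuality",
    "blast_tier",
    "trna_tier",
    "wish_tier",
    "combine_linkages",
    "bin_quality",
    "ASSIGNMENT_THRESHOLD",
]

ASSIGNMENT_THRESHOLD = 3.0

# (min identity, min coverage, tier), scanned best-first
BLAST_TIERS = ((0.98, 0.90, 4), (0.90, 0.75, 3), (0.90, 0.50, 2), (0.90, 0.30, 1))
TRNA_TIERS = ((1.00, 3), (0.95, 2), (0.90, 1))
WISH_TIERS = ((1e-10, 2.5), (1e-5, 2.0))


@dataclass(frozen=True)
class HostEvidence:
    """One evidence row linking a viral contig to a candidate host MAG."""

    virus_id: str
    mag_id: str
    kind: str  # {"prophage_blast", "trna", "wish"}
    pct_identity: float | None = None  # fraction, blast/trna
    coverage: float | None = None  # fraction, blast
    p_value: float | None = None  # wish

    def __post_init__(self) -> None:
        if self.kind == "prophage_blast":
            if self.pct_identity is None or self.coverage is None:
                raise ValueError("prophage_blast evidence needs pct_identity and coverage")
        elif self.kind == "trna":
            if self.pct_identity is None:
                raise ValueError("trna evidence needs pct_identity")
        elif self.kind == "wish":
            if self.p_value is None:
                raise ValueError("wish evidence needs p_value")
            if not 0 < self.p_value <= 1:
                raise ValueError("p_value must be in (0, 1]")
        else:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        for frac in (self.pct_identity, self.coverage):
            if frac is not None and not 0 <= frac <= 1:
                raise ValueError("identity/coverage must be fractions in [0, 1]")


@dataclass(frozen=True)
class HostLinkage:
    """Combined per-pair scores and the >= 3 assignment decision."""

    virus_id: str
    mag_id: str
    blast_score: int
    trna_score: int
    wish_score: float
    total: float
    assigned: bool


@dataclass(frozen=True)
class BinQuality:
    """CheckM-style MAG quality score with the 70/10 gate."""

    bin_id: str
    completeness: float
    contamination: float
    score: float
    passes_gate: bool


def blast_tier(pct_identity: float, coverage: float) -> int:
    """Prophage-BLAST tier: the highest tier whose identity AND coverage thresholds are met."""
    for min_id, min_cov, tier in BLAST_TIERS:
        if pct_identity >= min_id and coverage >= min_cov:
            return tier
    return 0


def trna_tier(pct_identity: float) -> int:
    """tRNA-match tier from percent identity (3 requires a perfect match)."""
    for min_id, tier in TRNA_TIERS:
        if pct_identity >= min_id:
            return tier
    return 0


def wish_tier(p_value: float) -> float:
    """WIsH tier from the reported p-value (2.5 at p <= 1e-10, 2 at p <= 1e-5)."""
    for max_p, tier in WISH_TIERS:
        if p_value <= max_p:
            return tier
    return 0.0


def combine_linkages(evidence: list[HostEvidence]) -> list[HostLinkage]:
    """Combine evidence rows into per-pair linkages with the >= 3 assignment rule.

    Multiple rows of one kind for a pair contribute only their best tier;
    pairs whose combined score is 0 are omitted.  Output is sorted by
    descending total then (virus_id, mag_id).
    """
    best: dict[tuple[str, str], dict[str, float]] = defaultdict(
        lambda: {"blast": 0, "trna": 0, "wish": 0.0}
    )
    for ev in evidence:
        key = (ev.virus_id, ev.mag_id)
        if ev.kind == "prophage_blast":
            tier = blast_tier(ev.pct_identity, ev.coverage)
            if tier > best[key]["blast"]:
                if best[key]["blast"] > 0:
                    logger.info("multiple blast rows for %s; keeping best tier", key)
                best[key]["blast"] = tier
        elif ev.kind == "trna":
            best[key]["trna"] = max(best[key]["trna"], trna_tier(ev.pct_identity))
        else:
            best[key]["wish"] = max(best[key]["wish"], wish_tier(ev.p_value))
    linkages = []
    for (virus, mag), scores in best.items():
        total = scores["blast"] + scores["trna"] + scores["wish"]
        if total == 0:
            continue
        linkages.append(
            HostLinkage(
                virus_id=virus,
                mag_id=mag,
                blast_score=int(scores["blast"]),
                trna_score=int(scores["trna"]),
                wish_score=float(scores["wish"]),
                total=float(total),
                assigned=total >= ASSIGNMENT_THRESHOLD,
            )
        )
    linkages.sort(key=lambda l: (-l.total, l.virus_id, l.mag_id))
    return linkages


def bin_quality(bin_id: str, completeness: float, contamination: float) -> BinQuality:
    """Score a MAG bin: completeness - 2 x contamination, gated at >=70% / <=10%."""
    for value in (completeness, contamination):
        if not 0 <= value <= 100:
            raise ValueError("completeness/contamination must be percentages in [0, 100]")
    return BinQuality(
        bin_id=bin_id,
        completeness=completeness,
        contamination=contamination,
        score=completeness - 2.0 * contamination,
        passes_gate=completeness >= 70.0 and contamination <= 10.0,
    )


def linkages_to_frame(linkages: list[HostLinkage]) -> pd.DataFrame:
    """Tabulate linkages for TSV output."""
    return pd.DataFrame(
        [
            {
                "virus_id": l.virus_id,
                "mag_id": l.mag_id,
                "blast_score": l.blast_score,
                "trna_score": l.trna_score,
                "wish_score": l.wish_score,
                "total": l.total,
                "assigned": l.assigned,
            }
            for l in linkages
        ]
    )
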