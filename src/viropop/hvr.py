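"""Hypervariable-region (HVR) detection from per-base coverage.

HVRs are strain-variable loci (host-recognition modules, DNA
synthesis/packaging genes) that recruit reads poorly because no single
assembled allele matches the read population.  A region is called when all
three criteria hold together: every position is below 20% of the whole-contig
median depth, the run is at least 600 bp long, and it contains at least one
position of exactly zero coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from viropop.core_io import CoverageTrack

__all__ = ["HvrCall", "call_hvrs"]


@dataclass(frozen=True)
class HvrCall:
    """One called hypervariable region (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    length: int
    median_contig_depth: float
    max_region_fraction: float  # max depth within region / contig median
    contains_zero: bool


def call_hvrs(
    track: CoverageTrack, frac_cutoff: float = 0.20, min_len: int = 600
) -> list[HvrCall]:
    """Call hypervariable regions on one contig's coverage track.

    Maximal runs of positions with depth strictly below ``frac_cutoff`` times
    the whole-contig median are candidates; a candidate is emitted iff it is
    at least ``min_len`` bp long and contains a zero-depth position.  The
    median is taken over all contig positions, dips included.  A zero median
    (effectively unmapped contig) is an error — such contigs should not be
    screened.
    """
    depth = track.depth
    median = float(np.median(depth))
    if median == 0:
        raise ValueError(
            f"{track.contig_id}: zero median coverage; contig should be excluded upstream"
        )
    threshold = frac_cutoff * median
    low = depth < threshold
    calls: list[HvrCall] = []
    # maximal low-coverage runs via diff on the padded boolean mask
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_len:
            continue
        region = depth[start:end]
        if not (region == 0).any():
            continue
        calls.append(
            HvrCall(
                contig_id=track.contig_id,
                start=int(start),
                end=int(end),
                length=int(end - start),
                median_contig_depth=median,
                max_region_fraction=float(region.max()) / median,
                contains_zero=True,
            )
        )
    return calls
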