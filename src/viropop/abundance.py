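"""Per-sample viral population abundance from read mappings and depth tracks.

The abundance of a population in a sample is the trimmed mean of its
representative's per-base depth ("tpmean": positions below the 5th or above
the 95th depth percentile are excluded), zeroed when horizontal coverage
(breadth) falls below 70% to suppress false-positive detections, and
normalised per million reads in the metagenome.  RPKM is provided for
screens against reference genome sets, and a seeded read subsampler
implements the fixed-depth (5 million reads) mapping contract that keeps
presence calls comparable across datasets of different sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from viropop.core_io import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "filter_mappings",
    "tpmean",
    "breadth",
    "population_abundance",
    "rpkm",
    "subsample_reads",
    "isolate_presence_screen",
]


@dataclass
class AbundanceMatrix:
    """Populations x samples abundance values plus per-sample metadata.

    ``values`` is a DataFrame with population ids as the index and sample
    ids as columns; ``sample_meta`` (optional) is indexed by sample id and
    typically carries ``fraction`` (cellular/viral), ``depth_m`` and
    ``group`` columns.
    """

    values: pd.DataFrame
    normalization: str = "raw_tpmean"  # {raw_tpmean, per_million_reads, rpkm}
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def population_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="population_id")

    @classmethod
    def from_tsv(cls, path, normalization: str = "per_million_reads") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, normalization=normalization)


def filter_mappings(records: pd.DataFrame) -> pd.DataFrame:
    """Keep read mappings spanning >= 90% of the read at >= 95% identity.

    ``records`` needs columns ``read_len``, ``aligned_len`` and ``identity``
    (fraction).  Both thresholds are inclusive.
    """
    required = {"read_len", "aligned_len", "identity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"mapping table lacks columns: {sorted(missing)}")
    keep = (records["aligned_len"] / records["read_len"] >= 0.90) & (
        records["identity"] >= 0.95
    )
    return records.loc[keep]


def _nearest_rank(sorted_depths: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value."""
    n = sorted_depths.size
    rank = max(1, int(np.ceil(q * n)))
    return float(sorted_depths[rank - 1])


def tpmean(track: CoverageTrack) -> float:
    """Trimmed mean depth, excluding positions outside the 5th–95th percentiles.

    Percentiles are nearest-rank on the sorted per-position depth vector;
    exclusion is strict (depth < p5 or depth > p95), so a constant track
    returns the constant.
    """
    depths = track.depth
    if depths.size == 0:
        raise ValueError("empty coverage track")
    s = np.sort(depths)
    p5 = _nearest_rank(s, 0.05)
    p95 = _nearest_rank(s, 0.95)
    kept = depths[(depths >= p5) & (depths <= p95)]
    return float(kept.mean())


def breadth(track: CoverageTrack) -> float:
    """Horizontal coverage: fraction of positions with depth >= 1."""
    if len(track) == 0:
        return 0.0
    return float((track.depth >= 1).mean())


def population_abundance(
    tracks: Mapping[tuple[str, str], CoverageTrack],
    total_reads: Mapping[str, float],
    min_breadth: float = 0.70,
    sample_meta: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Build the populations x samples abundance matrix.

    ``tracks`` maps ``(population_id, sample_id)`` to the representative's
    depth track in that sample.  A cell is the track's tpmean when breadth
    >= ``min_breadth`` and exactly 0 otherwise, scaled by 1e6/total_reads of
    the sample (per-million-reads normalisation).  Missing tracks yield 0
    with a logged warning.
    """
    pops = sorted({p for p, _ in tracks})
    samples = sorted(total_reads)
    mat = pd.DataFrame(0.0, index=pops, columns=samples)
    for sample in samples:
        n_reads = total_reads[sample]
        if n_reads <= 0:
            raise ValueError(f"total_reads for {sample!r} must be > 0")
        for pop in pops:
            track = tracks.get((pop, sample))
            if track is None:
                logger.warning("no coverage track for (%s, %s); abundance 0", pop, sample)
                continue
            if breadth(track) >= min_breadth:
                mat.at[pop, sample] = tpmean(track) * 1e6 / n_reads
    return AbundanceMatrix(values=mat, normalization="per_million_reads", sample_meta=sample_meta)


def rpkm(read_count: int, contig_len_bp: int, total_reads: int) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_len_bp <= 0 or total_reads <= 0:
        raise ValueError("contig length and total reads must be > 0")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / (contig_len_bp / 1e3) / (total_reads / 1e6)


def subsample_reads(
    read_ids: Sequence[str], n: int = 5_000_000, seed: int | None = None
) -> list[str]:
    """Uniform sample of ``n`` read ids without replacement, seed-deterministic.

    Datasets at or below the target size are returned unchanged; the result
    preserves input order.
    """
    if n <= 0:
        raise ValueError("subsample size must be > 0")
    if len(read_ids) <= n:
        return list(read_ids)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(read_ids), size=n, replace=False)
    idx.sort()
    return [read_ids[i] for i in idx]


def isolate_presence_screen(
    tracks: Mapping[tuple[str, str], CoverageTrack],
    read_counts: Mapping[tuple[str, str], int],
    genome_lens: Mapping[str, int],
    total_reads: Mapping[str, int],
    cutoffs: Sequence[float] = (0.40, 0.70),
) -> pd.DataFrame:
    """Presence/absence of reference (isolate) genomes at breadth cut-offs.

    For every (genome, sample) pair the breadth and RPKM are reported along
    with a ``present@<cutoff>`` call per requested breadth cut-off (the
    standard 70% plus the relaxed 40% screen).  Genomes should first be
    dereplicated with :func:`viropop.clustering.cluster_populations` at the
    standard 95%/85% thresholds.
    """
    rows = []
    for (genome, sample), track in sorted(tracks.items()):
        b = breadth(track)
        reads = read_counts.get((genome, sample), 0)
        row = {
            "genome": genome,
            "sample": sample,
            "breadth": b,
            "rpkm": rpkm(reads, genome_lens[genome], total_reads[sample]),
        }
        for cutoff in cutoffs:
            row[f"present@{int(round(cutoff * 100))}"] = b >= cutoff
        rows.append(row)
    return pd.DataFrame(rows)
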