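"""Synthetic viromes with recorded ground truth.

Every downstream stage is exercised on data from this module, so its
defaults emulate the statistical structure of a stratified marine virome
survey: a few dozen species-rank populations of related contigs (members at
~97% identity to a long-read representative), two depth groups of samples,
per-base coverage tracks with engineered hypervariable-region dips,
biallelic SNVs at chosen allele frequencies, and log-normal community
abundance with a known set of group-discriminating populations.

Alignments between simulated relatives are computed analytically from the
known point-mutation positions (members are gap-free mutated copies, so the
alignment is the identity mapping); no external aligner is involved and the
recorded ANI is exact.  All randomness fans out from one seed through fixed
per-component child streams, so identical configurations give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from viropop.abundance import AbundanceMatrix
from viropop.core_io import AlignmentRecord, ContigRecord, CoverageTrack, SnvRecord

__all__ = [
    "SimulationConfig",
    "simulate_contig_population",
    "simulate_coverage",
    "simulate_snvs",
    "simulate_abundance_matrix",
    "simulate_presence_tracks",
]

_BASES = np.array(list("ACGT"))

# child-stream offsets: one per component, fixed forever
_STREAM_CONTIGS = 1
_STREAM_COVERAGE = 2
_STREAM_SNVS = 3
_STREAM_ABUNDANCE = 4
_STREAM_PRESENCE = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic virome; ``seed`` fixes all randomness.

    ``within_pop_identity`` is each member's nucleotide identity to its
    population representative; two thirds of a member's mutations are drawn
    from a population-shared polymorphic set (so member-member identity
    stays above the 95% clustering threshold, as for real co-circulating
    strains) and one third are private.

    ``hvr_spec`` rows are ``(contig_id, start, end, floor_depth)``: depth
    inside the dip collapses to around ``floor_depth``; a floor of 0 yields
    a genuine hypervariable signature (zero-coverage zone included), a
    positive floor yields a low-coverage decoy with no zero positions.

    ``snv_spec`` rows are ``(contig_id, n_sites, allele_freq)``; alternative
    allele counts are binomial at ``snv_depth``.

    ``effect_size`` is the log2 fold-change applied to the first
    ``n_effect_taxa`` populations in the second sample group (0 = null).
    """

    seed: int = 0
    n_populations: int = 8
    contigs_per_population: int = 3
    contig_len_range: tuple[int, int] = (8_000, 18_000)
    within_pop_identity: float = 0.97
    n_samples: int = 12
    group_labels: tuple[str, ...] = ("80m", "200m")
    mean_depth_range: tuple[float, float] = (20.0, 80.0)
    hvr_spec: tuple[tuple[str, int, int, float], ...] | None = None
    snv_spec: tuple[tuple[str, int, float], ...] | None = None
    snv_depth: int = 50
    subsample_target: int = 10
    n_decoys: int = 0
    decoy_identity: float = 0.90
    effect_size: float = 2.0
    n_effect_taxa: int = 3
    abundance_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.within_pop_identity <= 1.0:
            raise ValueError("within_pop_identity must be in (0, 1]")
        if not 0.0 < self.decoy_identity <= 1.0:
            raise ValueError("decoy_identity must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.snv_depth < 1:
            raise ValueError("snv_depth must be >= 1")
        if self.contig_len_range[0] > self.contig_len_range[1]:
            raise ValueError("bad contig_len_range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _pop_id(p: int) -> str:
    return f"P{p:02d}"


def _member_id(p: int, m: int) -> str:
    return f"P{p:02d}C{m:02d}"


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with a uniformly chosen different base."""
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _pair_alignment(
    id_a: str, seq_a: np.ndarray, id_b: str, seq_b: np.ndarray
) -> AlignmentRecord:
    """Exact gap-free alignment record between two related sequences.

    The shorter sequence is the query and aligns end-to-end at offset 0
    (members are prefixes-with-substitutions of a common seed), so matches
    are counted directly by elementwise comparison.
    """
    if (len(seq_a), id_a) > (len(seq_b), id_b):
        id_a, seq_a, id_b, seq_b = id_b, seq_b, id_a, seq_a
    span = len(seq_a)
    matches = int(np.sum(seq_a[:span] == seq_b[:span]))
    return AlignmentRecord(
        query_id=id_a,
        target_id=id_b,
        query_start=0,
        query_end=span,
        target_start=0,
        target_end=span,
        n_matches=matches,
        aln_len=span,
        pct_identity=matches / span,
        query_len=len(seq_a),
        target_len=len(seq_b),
    )


def simulate_contig_population(
    config: SimulationConfig,
) -> tuple[list[ContigRecord], pd.DataFrame, list[AlignmentRecord]]:
    """Generate populations of related contigs with truth and exact alignments.

    Each population starts from an unrelated random seed sequence; the
    representative (member 00, ``long_read``) is the seed itself, the other
    members (``short_read``) are slightly truncated point-mutated copies at
    ``within_pop_identity``.  Optional decoys are extra contigs mutated down
    to ``decoy_identity`` — below the 95% clustering threshold — recorded as
    their own singleton truth populations, with their representative
    alignment emitted so the clustering stage sees (and must reject) them.

    Returns ``(contigs, truth, alignments)`` where ``truth`` has columns
    ``contig_id, population_id, is_representative, length, source_tech``.
    """
    rng = config.rng(_STREAM_CONTIGS)
    lo, hi = config.contig_len_range
    contigs: list[ContigRecord] = []
    truth_rows = []
    alignments: list[AlignmentRecord] = []
    rep_seqs: dict[int, np.ndarray] = {}
    mut_rate = 1.0 - config.within_pop_identity

    for p in range(config.n_populations):
        length = int(rng.integers(lo, hi + 1))
        seed_seq = rng.choice(_BASES, size=length)
        rep_seqs[p] = seed_seq
        member_seqs: dict[str, np.ndarray] = {_member_id(p, 0): seed_seq}
        # shared polymorphic sites: two thirds of each member's mutations
        n_common = int(round(2.0 / 3.0 * mut_rate * length))
        common_pos = rng.choice(length, size=n_common, replace=False) if n_common else np.array([], dtype=int)
        common_seq = _mutate(seed_seq, common_pos, rng)
        for m in range(1, config.contigs_per_population):
            trim = int(rng.integers(1, max(2, int(0.05 * length))))
            mlen = length - trim
            n_priv = int(round(mut_rate * mlen)) - int(np.sum(common_pos < mlen))
            n_priv = max(n_priv, 0)
            free = np.setdiff1d(np.arange(mlen), common_pos, assume_unique=False)
            priv_pos = rng.choice(free, size=min(n_priv, free.size), replace=False)
            seq = common_seq[:mlen].copy()
            seq = _mutate(seq, priv_pos, rng)
            member_seqs[_member_id(p, m)] = seq
        for mid, seq in member_seqs.items():
            is_rep = mid.endswith("C00")
            contigs.append(
                ContigRecord(
                    contig_id=mid,
                    sequence="".join(seq),
                    length=len(seq),
                    source_tech="long_read" if is_rep else "short_read",
                )
            )
            truth_rows.append(
                {
                    "contig_id": mid,
                    "population_id": _pop_id(p),
                    "is_representative": is_rep,
                    "length": len(seq),
                    "source_tech": "long_read" if is_rep else "short_read",
                }
            )
        ids = sorted(member_seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                alignments.append(_pair_alignment(a, member_seqs[a], b, member_seqs[b]))

    for d in range(config.n_decoys):
        p = d % config.n_populations
        seed_seq = rep_seqs[p]
        length = len(seed_seq)
        trim = int(rng.integers(1, max(2, int(0.05 * length))))
        mlen = length - trim
        n_mut = int(round((1.0 - config.decoy_identity) * mlen))
        pos = rng.choice(mlen, size=n_mut, replace=False)
        seq = _mutate(seed_seq[:mlen].copy(), pos, rng)
        did = f"P{p:02d}D{d:02d}"
        contigs.append(
            ContigRecord(contig_id=did, sequence="".join(seq), length=mlen, source_tech="short_read")
        )
        truth_rows.append(
            {
                "contig_id": did,
                "population_id": f"D{d:02d}",
                "is_representative": True,
                "length": mlen,
                "source_tech": "short_read",
            }
        )
        alignments.append(_pair_alignment(did, seq, _member_id(p, 0), seed_seq))

    truth = pd.DataFrame(truth_rows)
    return contigs, truth, alignments


def _default_hvr_spec(
    lengths: Mapping[str, int]
) -> tuple[tuple[str, int, int, float], ...]:
    """One true 700 bp zero-floor dip, one 500 bp sub-length decoy, one non-zero-floor decoy."""
    ids = sorted(lengths)
    spec = []
    if len(ids) >= 1:
        spec.append((ids[0], 2000, 2700, 0.0))
    if len(ids) >= 2:
        spec.append((ids[1], 3000, 3500, 0.0))
    if len(ids) >= 3:
        spec.append((ids[2], 2500, 3300, 4.0))
    return tuple(spec)


def simulate_coverage(
    config: SimulationConfig,
    lengths: Mapping[str, int] | None = None,
) -> tuple[list[CoverageTrack], pd.DataFrame]:
    """Per-base coverage tracks with engineered low-coverage dips.

    Depth outside dips is Poisson at a contig mean drawn from
    ``mean_depth_range``.  Inside a dip, depth is Poisson around
    ``floor_depth``, capped well below 20% of the contig mean; a zero-floor
    dip always contains exact-zero positions, a positive-floor dip never
    does.  Returns the tracks and a truth table with an ``is_true_hvr``
    column (dips >= 600 bp with a zero floor).
    """
    if lengths is None:
        contigs, _, _ = simulate_contig_population(config)
        lengths = {c.contig_id: c.length for c in contigs if c.contig_id.endswith("C00")}
    spec = config.hvr_spec if config.hvr_spec is not None else _default_hvr_spec(lengths)
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for contig_id, start, end, floor in spec:
        if contig_id not in lengths:
            raise ValueError(f"hvr_spec names unknown contig {contig_id!r}")
        if not 0 <= start < end <= lengths[contig_id]:
            raise ValueError(f"dip [{start},{end}) outside {contig_id!r}")
        by_contig.setdefault(contig_id, []).append((start, end, floor))
    for contig_id, dips in by_contig.items():
        dips.sort()
        for (s1, e1, _), (s2, _e2, _f) in zip(dips, dips[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping dips on {contig_id!r}")

    rng = config.rng(_STREAM_COVERAGE)
    tracks: list[CoverageTrack] = []
    truth_rows = []
    lo, hi = config.mean_depth_range
    for contig_id in sorted(lengths):
        length = lengths[contig_id]
        mean = float(rng.uniform(lo, hi))
        depth = rng.poisson(mean, size=length)
        for start, end, floor in by_contig.get(contig_id, []):
            span = end - start
            cap = max(1, int(0.15 * mean))
            if floor == 0:
                dip = rng.poisson(0.3, size=span)
                dip = np.minimum(dip, cap)
                dip[span // 2] = 0
            else:
                dip = np.maximum(rng.poisson(floor, size=span), 1)
                dip = np.minimum(dip, max(cap, 1))
            depth[start:end] = dip
            truth_rows.append(
                {
                    "contig_id": contig_id,
                    "start": start,
                    "end": end,
                    "floor_depth": floor,
                    "is_true_hvr": span >= 600 and floor == 0,
                }
            )
        tracks.append(CoverageTrack(contig_id, depth))
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "start", "end", "floor_depth", "is_true_hvr"]
    )
    return tracks, truth


def simulate_snvs(
    config: SimulationConfig,
    lengths: Mapping[str, int] | None = None,
) -> tuple[list[SnvRecord], pd.DataFrame]:
    """Biallelic SNV sites at configured allele frequencies.

    Each ``snv_spec`` row ``(contig_id, n_sites, allele_freq)`` yields
    ``n_sites`` records at distinct positions with alternative counts drawn
    Binomial(``snv_depth``, allele_freq) and QUAL fixed at 50 (above the
    retention threshold).  The truth table records each site's frequency and
    the closed-form per-site diversity ``2 f (1-f) n/(n-1)`` at the
    configured subsample target n.
    """
    spec = config.snv_spec
    if spec is None:
        if lengths is None:
            contigs, _, _ = simulate_contig_population(config)
            lengths = {c.contig_id: c.length for c in contigs if c.contig_id.endswith("C00")}
        first = sorted(lengths)[0]
        spec = ((first, 100, 0.5),)
    rng = config.rng(_STREAM_SNVS)
    n_sub = config.subsample_target
    records: list[SnvRecord] = []
    truth_rows = []
    for contig_id, n_sites, f in spec:
        if not 0.0 <= f < 1.0:
            raise ValueError("allele_freq must be in [0, 1)")
        length = lengths[contig_id] if lengths and contig_id in lengths else 10_000
        positions = np.sort(rng.choice(length, size=n_sites, replace=False))
        alts = rng.binomial(config.snv_depth, f, size=n_sites)
        for pos, alt in zip(positions, alts):
            counts = {"A": int(config.snv_depth - alt)}
            if alt > 0:
                counts["C"] = int(alt)
            records.append(
                SnvRecord(
                    contig_id=contig_id,
                    pos=int(pos),
                    ref_allele="A",
                    allele_counts=counts,
                    qual=50.0,
                )
            )
            truth_rows.append(
                {
                    "contig_id": contig_id,
                    "pos": int(pos),
                    "allele_freq": f,
                    "truth_pi_site": 2.0 * f * (1.0 - f) * n_sub / (n_sub - 1),
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "pos", "allele_freq", "truth_pi_site"]
    )
    return records, truth


def _sample_ids_and_groups(config: SimulationConfig) -> tuple[list[str], list[str]]:
    n_groups = len(config.group_labels)
    per_group, rem = divmod(config.n_samples, n_groups)
    if rem:
        raise ValueError("n_samples must divide evenly across groups")
    if per_group < 2:
        raise ValueError("need at least two samples per group")
    sample_ids, groups = [], []
    for g in config.group_labels:
        for i in range(per_group):
            sample_ids.append(f"{g}_s{i:02d}")
            groups.append(g)
    return sample_ids, groups


def simulate_abundance_matrix(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Log-normal community abundance with a known between-group effect.

    Rows are population representatives; the first ``n_effect_taxa``
    populations are shifted by ``2**effect_size`` in the second group's
    samples.  Returns the matrix (with ``group`` sample metadata) and a
    truth table naming the discriminating taxa.
    """
    if len(config.group_labels) < 2:
        raise ValueError("need at least two groups")
    sample_ids, groups = _sample_ids_and_groups(config)
    rng = config.rng(_STREAM_ABUNDANCE)
    pops = [_member_id(p, 0) for p in range(config.n_populations)]
    base = rng.lognormal(mean=np.log(50.0), sigma=config.abundance_sigma, size=config.n_populations)
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(config.n_populations, len(sample_ids)))
    values = base[:, None] * noise
    multiplier = 2.0 ** config.effect_size
    effect_taxa = pops[: config.n_effect_taxa]
    second_group = config.group_labels[1]
    for j, g in enumerate(groups):
        if g == second_group:
            values[: config.n_effect_taxa, j] *= multiplier
    meta = pd.DataFrame({"group": groups}, index=sample_ids)
    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=pops, columns=sample_ids),
        normalization="per_million_reads",
        sample_meta=meta,
    )
    truth = pd.DataFrame({"taxon_id": effect_taxa, "multiplier": multiplier})
    return matrix, truth


def simulate_presence_tracks(
    config: SimulationConfig,
    n_present: int,
    n_decoy: int,
    contig_len: int = 5_000,
    decoy_breadth: float = 0.5,
) -> tuple[dict[tuple[str, str], CoverageTrack], pd.DataFrame]:
    """Per-(population, sample) coverage tracks for the presence-rule test.

    ``n_present`` populations are fully covered (breadth 1.0) in every
    sample; ``n_decoy`` populations have reads over only a ``decoy_breadth``
    fraction of their length.  Returns the track map and a truth table with
    a ``present`` column.
    """
    sample_ids, _ = _sample_ids_and_groups(config)
    rng = config.rng(_STREAM_PRESENCE)
    lo, hi = config.mean_depth_range
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    truth_rows = []
    for i in range(n_present + n_decoy):
        pop = f"pres{i:03d}" if i < n_present else f"decoy{i - n_present:03d}"
        present = i < n_present
        truth_rows.append({"population_id": pop, "present": present})
        for sample in sample_ids:
            mean = float(rng.uniform(lo, hi))
            depth = np.maximum(rng.poisson(mean, size=contig_len), 1)
            if not present:
                cut = int(round(decoy_breadth * contig_len))
                depth[cut:] = 0
            tracks[(pop, sample)] = CoverageTrack(pop, depth)
    return tracks, pd.DataFrame(truth_rows)
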