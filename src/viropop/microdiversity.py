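"""Nucleotide diversity (pi, "microdiversity") from filtered SNV tables.

A contig qualifies for estimation when >= 70% of its positions are covered
and mean depth is >= 10X.  SNV sites are kept when QUAL > 30 (strict) and at
least one non-reference allele has frequency > 1% (strict) with >= 4
supporting reads, both evaluated on the raw counts.  Each retained locus is
then subsampled without replacement to a fixed depth (10X) to equalise the
information content across loci and samples, and per-site diversity is the
unbiased sample heterozygosity

    pi_s = n/(n-1) * (1 - sum_a p_a^2),

with n the subsampled depth and p_a the subsampled allele fractions --
identical to the fraction of mismatching read pairs among the n*(n-1)/2
pairs at the locus.  Contig-level pi averages pi_s over all pi-evaluable
positions (those with depth >= the subsample target); monomorphic covered
sites contribute zero.

Group comparisons follow the resampling protocol of deep-virome surveys:
bootstrap means of 100-value subsamples (1000 replicates) and a two-sided
label-shuffle permutation test on the difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from viropop.core_io import CoverageTrack, SnvRecord
from viropop.abundance import breadth as _breadth

__all__ = [
    "PiEstimate",
    "ResamplingResult",
    "filter_snvs",
    "subsample_locus",
    "pi_contig",
    "estimate_pi",
    "bootstrap_mean_pi",
    "permutation_test_pi",
]


@dataclass(frozen=True)
class PiEstimate:
    """Per-contig nucleotide diversity and its evaluability metadata."""

    contig_id: str
    pi: float
    n_snv_loci: int
    covered_len: int
    breadth: float
    mean_depth: float


@dataclass(frozen=True)
class ResamplingResult:
    """Bootstrap summary of a set of pi values."""

    mean_pi: float
    ci_low: float
    ci_high: float
    n_boot: int
    subsample: int
    seed: int | None


def filter_snvs(
    records: list[SnvRecord],
    min_qual: float = 30.0,
    min_af: float = 0.01,
    min_alt_reads: int = 4,
) -> list[SnvRecord]:
    """Retain SNV loci passing the quality / frequency / support filters.

    A site is kept iff QUAL > ``min_qual`` (strict) and at least one
    non-reference allele has frequency > ``min_af`` (strict) AND count >=
    ``min_alt_reads``.  Frequencies are evaluated on the raw (pre-subsampling)
    counts.
    """
    kept = []
    for rec in records:
        if not rec.qual > min_qual:
            continue
        depth = rec.depth
        if depth == 0:
            continue
        ok = any(
            count / depth > min_af and count >= min_alt_reads
            for allele, count in rec.allele_counts.items()
            if allele != rec.ref_allele
        )
        if ok:
            kept.append(rec)
    return kept


def subsample_locus(
    counts: dict[str, int],
    target: int = 10,
    rng: np.random.Generator | int | None = None,
) -> dict[str, int]:
    """Subsample a locus's allele counts to a fixed depth without replacement.

    A multivariate hypergeometric draw of ``target`` reads from the allele
    pool; loci with fewer than ``target`` reads should be excluded by the
    caller.  Deterministic under a seeded generator.
    """
    if target <= 1:
        raise ValueError("subsample target must be > 1")
    total = sum(counts.values())
    if total < target:
        raise ValueError(f"locus depth {total} below subsample target {target}")
    if total == target:
        return dict(counts)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alleles = sorted(counts)
    pool = np.array([counts[a] for a in alleles])
    draw = rng.multivariate_hypergeometric(pool, target)
    return {a: int(k) for a, k in zip(alleles, draw) if k > 0}


def _site_pi(counts: dict[str, int]) -> float:
    n = sum(counts.values())
    if n < 2:
        return 0.0
    p = np.array(list(counts.values()), dtype=float) / n
    return n / (n - 1) * (1.0 - float(np.sum(p * p)))


def pi_contig(
    snv_loci: list[dict[str, int]], covered_len: int, contig_id: str = ""
) -> PiEstimate:
    """Average nucleotide diversity from subsampled per-locus allele counts.

    ``snv_loci`` are the post-subsampling allele counts of the retained SNV
    loci; ``covered_len`` is the number of pi-evaluable positions, over which
    the per-site values are averaged (monomorphic sites contribute 0).
    """
    if covered_len <= 0:
        raise ValueError("covered_len must be > 0")
    total = sum(_site_pi(c) for c in snv_loci)
    return PiEstimate(
        contig_id=contig_id,
        pi=total / covered_len,
        n_snv_loci=len(snv_loci),
        covered_len=covered_len,
        breadth=float("nan"),
        mean_depth=float("nan"),
    )


def estimate_pi(
    snvs: list[SnvRecord],
    track: CoverageTrack,
    target_depth: int = 10,
    min_qual: float = 30.0,
    min_af: float = 0.01,
    min_alt_reads: int = 4,
    min_breadth: float = 0.70,
    min_mean_depth: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> PiEstimate | None:
    """Full per-contig pi pipeline: inclusion gate, filters, subsampling, averaging.

    Returns ``None`` for contigs failing the inclusion gate (breadth >=
    ``min_breadth`` and mean depth >= ``min_mean_depth``).  ``covered_len``
    counts positions whose raw depth is at least the subsample target.
    """
    b = _breadth(track)
    mean_depth = float(track.depth.mean())
    if b < min_breadth or mean_depth < min_mean_depth:
        return None
    covered_len = int((track.depth >= target_depth).sum())
    if covered_len == 0:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = filter_snvs(
        [r for r in snvs if r.contig_id == track.contig_id],
        min_qual=min_qual,
        min_af=min_af,
        min_alt_reads=min_alt_reads,
    )
    loci = [
        subsample_locus(r.allele_counts, target=target_depth, rng=rng)
        for r in kept
        if r.depth >= target_depth
    ]
    est = pi_contig(loci, covered_len, contig_id=track.contig_id)
    return PiEstimate(
        contig_id=track.contig_id,
        pi=est.pi,
        n_snv_loci=est.n_snv_loci,
        covered_len=covered_len,
        breadth=b,
        mean_depth=mean_depth,
    )


def bootstrap_mean_pi(
    pi_values: list[float] | np.ndarray,
    n_boot: int = 1000,
    subsample: int = 100,
    seed: int | None = None,
) -> ResamplingResult:
    """Bootstrap the mean of a set of pi values.

    Each replicate draws ``subsample`` values with replacement and records
    their mean; the overall mean of replicate means and the 2.5/97.5
    percentile interval are reported.
    """
    values = np.asarray(pi_values, dtype=float)
    if values.size == 0:
        raise ValueError("pi_values must be non-empty")
    rng = np.random.default_rng(seed)
    draws = rng.choice(values, size=(n_boot, subsample), replace=True)
    means = draws.mean(axis=1)
    return ResamplingResult(
        mean_pi=float(means.mean()),
        ci_low=float(np.percentile(means, 2.5)),
        ci_high=float(np.percentile(means, 97.5)),
        n_boot=n_boot,
        subsample=subsample,
        seed=seed if isinstance(seed, int) else None,
    )


def permutation_test_pi(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided label-shuffle test on the difference of group means.

    The null pools both groups, shuffles, and re-splits at the original
    sizes; p = (1 + #{|diff_perm| >= |diff_obs|}) / (n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = a.size
    # vectorised null: one independent shuffle per row
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diffs = np.abs(perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1))
    return float((1 + np.sum(diffs >= obs - 1e-15)) / (n_perm + 1))
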