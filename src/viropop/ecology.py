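"""Community-ecology statistics for population x sample abundance matrices.

The vegan-style toolchain used for virome beta-diversity: cube-root
transformed Bray-Curtis dissimilarities, principal coordinates analysis
(PCoA by Gower double-centring), one-way PERMANOVA (adonis-style pseudo-F
with a label-shuffle null; with 999 permutations the smallest attainable
p is exactly 0.001), pairwise Euclidean distances between group centroids
in ordination space, SIMPER decomposition of between-group dissimilarity
into per-taxon contributions, and a bootstrap of the prevalence median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from viropop.abundance import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "SimperRow",
    "bray_curtis",
    "pcoa",
    "permanova",
    "pairwise_centroid_distance",
    "simper",
    "bootstrap_prevalence_median",
]


@dataclass
class OrdinationResult:
    """PCoA coordinates (positive axes only) plus the full eigenvalue spectrum."""

    sample_ids: list[str]
    coords: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    pct_explained: np.ndarray  # per retained axis, % of positive-eigenvalue sum


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r2: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class SimperRow:
    taxon_id: str
    mean_contribution: float  # fraction of mean between-group dissimilarity
    cumulative: float
    rank: int


def _sample_matrix(matrix: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Samples x taxa orientation from an AbundanceMatrix (taxa x samples) or DataFrame."""
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values.T
    return matrix.T


def bray_curtis(
    matrix: AbundanceMatrix | pd.DataFrame, transform: str = "cube_root"
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, optionally cube-root transformed.

    ``d(u, v) = sum|u_i - v_i| / sum(u_i + v_i)``.  A pair of all-zero
    samples is assigned distance 0 with a warning (they are identical in
    composition, vacuously).
    """
    if transform not in ("none", "cube_root"):
        raise ValueError(f"unknown transform {transform!r}")
    X = _sample_matrix(matrix)
    values = X.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if transform == "cube_root":
        values = np.cbrt(values)
    d = pdist(values, metric="braycurtis")
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s); Bray-Curtis set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=list(X.index))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centring.

    Eigendecomposition of ``-0.5 * J D^2 J``; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues.  Negative
    eigenvalues — Bray-Curtis is semi-metric — are reported in the spectrum
    but contribute no axis.
    """
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 1e-12)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pct = 100.0 * eigvals[positive] / eigvals[positive].sum()
    return OrdinationResult(
        sample_ids=list(d.ids),
        coords=coords,
        eigenvalues=eigvals,
        pct_explained=pct,
    )


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        members = np.flatnonzero(labels == g)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ss += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    return ss


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray, ss_total: float) -> float:
    """One-way PERMANOVA pseudo-F from a squared-distance matrix and labels."""
    n = d2.shape[0]
    g = groups.size
    ss_within = _ss_within(d2, labels, groups)
    denom = ss_within / (n - g)
    if denom == 0:
        raise ValueError("zero within-group dispersion; pseudo-F undefined")
    return ((ss_total - ss_within) / (g - 1)) / denom


def permanova(
    d: DistanceMatrix,
    grouping: list[str] | np.ndarray | pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Adonis-style one-way PERMANOVA with a label-shuffle null.

    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``, so 999 permutations
    bound p below at exactly 0.001.
    """
    labels = np.asarray(grouping)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    if groups.size == labels.size:
        raise ValueError("every sample in its own group; PERMANOVA undefined")
    D = np.asarray(d.data, dtype=float)
    d2 = D * D
    n = labels.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within_obs = _ss_within(d2, labels, groups)
    f_obs = _pseudo_f(d2, labels, groups, ss_total)
    r2 = (ss_total - ss_within_obs) / ss_total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        if _pseudo_f(d2, perm_labels, groups, ss_total) >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r2=float(r2),
        p=float((1 + hits) / (n_perm + 1)),
        n_perm=n_perm,
    )


def pairwise_centroid_distance(
    ordination: OrdinationResult, grouping: list[str] | np.ndarray | pd.Series
) -> pd.DataFrame:
    """Euclidean distances between group centroids over all retained ordination axes."""
    labels = np.asarray(grouping)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    centroids = {}
    for g in groups:
        members = np.flatnonzero(labels == g)
        if members.size == 0:
            raise ValueError(f"empty group {g!r}")
        centroids[g] = ordination.coords[members].mean(axis=0)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "distance": float(np.linalg.norm(centroids[ga] - centroids[gb])),
                }
            )
    return pd.DataFrame(rows)


def simper(
    matrix: AbundanceMatrix | pd.DataFrame,
    grouping: list[str] | np.ndarray | pd.Series,
    transform: str = "cube_root",
) -> pd.DataFrame:
    """SIMPER: per-taxon contributions to mean between-group Bray-Curtis dissimilarity.

    For every between-group sample pair (u, v) the taxon contribution is
    ``|u_i - v_i| / sum_k(u_k + v_k)``; contributions are averaged over pairs
    and normalised to fractions of the mean dissimilarity (they sum to 1).
    Ranking is by descending contribution, ties broken by taxon id.
    """
    X = _sample_matrix(matrix)
    values = X.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if transform == "cube_root":
        values = np.cbrt(values)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    labels = np.asarray(grouping)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("SIMPER compares exactly two groups")
    a_idx = np.flatnonzero(labels == groups[0])
    b_idx = np.flatnonzero(labels == groups[1])
    taxa = list(X.columns)
    contrib = np.zeros(len(taxa))
    n_pairs = 0
    for i in a_idx:
        for j in b_idx:
            u, v = values[i], values[j]
            denom = (u + v).sum()
            if denom == 0:
                continue
            contrib += np.abs(u - v) / denom
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable between-group pairs")
    contrib /= n_pairs
    total = contrib.sum()
    frac = contrib / total if total > 0 else contrib
    df = pd.DataFrame({"taxon_id": taxa, "mean_contribution": frac})
    df = df.sort_values(
        ["mean_contribution", "taxon_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["cumulative"] = df["mean_contribution"].cumsum()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def bootstrap_prevalence_median(
    presence_counts: list[int] | np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Bootstrap the median number of samples in which each population occurs.

    Returns ``(observed_median, ci_low, ci_high)`` where the interval is the
    2.5/97.5 percentile range of the replicate medians.
    """
    counts = np.asarray(presence_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("presence_counts must be non-empty")
    rng = np.random.default_rng(seed)
    draws = rng.choice(counts, size=(n_boot, counts.size), replace=True)
    medians = np.median(draws, axis=1)
    return (
        float(np.median(counts)),
        float(np.percentile(medians, 2.5)),
        float(np.percentile(medians, 97.5)),
    )
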