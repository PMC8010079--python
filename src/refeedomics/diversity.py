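"""Alpha diversity, community distances, PCoA, and donor-stratified PERMANOVA.

Implemented directly from the definitions rather than delegated, because the
donor-stratified permutation scheme (labels shuffled only within each
subject's block of repeated samples) is the part general-purpose tools do
not expose, and the rest is a handful of closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("richness", "shannon", "evenness", "simpson", "inv_simpson", "chao1")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(counts_row, metric: str = "shannon") -> float:
    """Single-sample alpha diversity from a row of non-negative counts.

    shannon uses the natural log; evenness = shannon / ln(richness) (NaN for a
    single taxon); simpson = 1 - sum(p^2); chao1 uses the bias-corrected form
    S_obs + F1(F1-1) / (2(F2+1)), defined even when no doubletons exist.
    """
    counts = np.asarray(counts_row, dtype=float)
    if counts.ndim != 1:
        raise ValueError("alpha_diversity expects a single sample (1-D row)")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined diversity")
    present = counts[counts > 0]
    richness = present.size
    p = present / total
    if metric == "richness":
        return float(richness)
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "evenness":
        if richness == 1:
            return float("nan")
        return float(-(p * np.log(p)).sum() / np.log(richness))
    if metric == "simpson":
        return float(1.0 - (p**2).sum())
    if metric == "inv_simpson":
        return float(1.0 / (p**2).sum())
    if metric == "chao1":
        f1 = float(np.sum(present == 1))
        f2 = float(np.sum(present == 2))
        return richness + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    raise ValueError(f"unknown alpha metric {metric!r}; expected one of {ALPHA_METRICS}")


def alpha_diversity_table(table: FeatureTable, metric: str = "shannon") -> pd.Series:
    """Alpha diversity of every sample in a count table."""
    values = [alpha_diversity(row, metric) for row in table.values]
    return pd.Series(values, index=table.data.index, name=metric)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with a metric tag."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def beta_distance(table: FeatureTable, metric: str = "bray-curtis") -> DistanceMatrix:
    """All-pairs Bray-Curtis (semimetric, in [0, 1]) or Euclidean distances.

    bray_curtis(x, y) = sum|x - y| / sum(x + y); a pair of all-zero samples is
    assigned distance 0 with a warning. No triangle inequality is asserted for
    Bray-Curtis.
    """
    X = table.values.astype(float)
    n = X.shape[0]
    if metric == "euclidean":
        sq = (X**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        D = np.sqrt(np.maximum(d2, 0.0))
    elif metric == "bray-curtis":
        if np.any(X < 0):
            raise ValueError("Bray-Curtis requires non-negative values")
        num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
        zero = den == 0
        if np.any(zero & ~np.eye(n, dtype=bool)):
            logger.warning("all-zero sample pair under Bray-Curtis; distance set to 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(sample_ids=table.sample_ids, values=D, metric=metric)


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """PCoA coordinates, eigenvalues (negatives reported) and axis fractions."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive-eigenvalue axes (up to k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Classical multidimensional scaling (principal coordinates).

    Gower-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues; axes with non-positive
    eigenvalues are reported in ``eigenvalues`` but omitted from the
    coordinates. For a Euclidean-embeddable distance matrix the coordinates
    reproduce all pairwise distances.
    """
    D = dist.values
    n = D.shape[0]
    if k is None:
        k = max(n - 1, 1)
    if k > max(n - 1, 1):
        raise ValueError(f"k={k} exceeds the {n - 1} available axes")
    A = -0.5 * D**2
    row_means = A.mean(axis=1, keepdims=True)
    G = A - row_means - row_means.T + A.mean()
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0.0) * 1e-12 if eigvals.size else eigvals > 0
    n_axes = min(int(positive.sum()), k)
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[positive].sum()
    proportion = np.where(eigvals > 0, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def ordination_deltas(
    result: OrdinationResult,
    metadata: pd.DataFrame,
    from_visit: str,
    to_visit: str,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Per-subject coordinate difference vectors between two visits.

    The machine-readable form of the fasting/refeeding arrow visualization:
    each subject contributes the displacement of its ordination position from
    ``from_visit`` to ``to_visit`` on the first ``n_axes`` axes.
    """
    from .io import sample_id

    pos = {sid: result.coordinates[i, :n_axes] for i, sid in enumerate(result.sample_ids)}
    rows = []
    for subject in metadata["subject_id"].unique():
        a, b = sample_id(subject, from_visit), sample_id(subject, to_visit)
        if a in pos and b in pos:
            delta = pos[b] - pos[a]
            rows.append({"subject_id": subject, **{f"axis{i + 1}": delta[i] for i in range(n_axes)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Donor-stratified PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def _pseudo_f(sq: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from the squared-distance matrix and integer group labels."""
    n = sq.shape[0]
    ss_total = sq.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = labels == g
        n_g = int(mask.sum())
        if n_g > 1:
            ss_within += sq[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova_stratified(
    dist: DistanceMatrix,
    groups,
    strata,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational MANOVA with label permutations restricted to strata.

    Group labels (typically visit) are shuffled only within each stratum
    (typically subject), preserving the repeated-measures structure; the
    p-value includes the observed statistic,
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations). Strata whose samples
    all share one group label contribute no label variation; if every stratum
    is degenerate the test returns p = 1 with a warning.
    """
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    n = dist.values.shape[0]
    if len(groups) != n or len(strata) != n:
        raise ValueError("groups and strata must cover all samples")
    uniq_groups, labels = np.unique(groups, return_inverse=True)
    n_groups = uniq_groups.size
    if n_groups < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    sq = dist.values**2
    f_obs = _pseudo_f(sq, labels, n_groups)

    blocks = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    informative = [b for b in blocks if np.unique(labels[b]).size > 1]
    if not informative:
        logger.warning("all strata are degenerate (single group label); p = 1")
        return PermanovaResult(float(f_obs), 1.0, n_permutations, seed)

    rng = np.random.default_rng(seed)
    R = n_permutations
    perm_labels = np.tile(labels, (R, 1))
    for b in blocks:
        if b.size < 2 or np.unique(labels[b]).size < 2:
            continue  # permuting a degenerate block is the identity
        order = np.argsort(rng.random((R, b.size)), axis=1)
        perm_labels[:, b] = labels[b][order]
    # within-block shuffles preserve every group's size, so the within-group
    # sums of squares can be batched as quadratic forms of group indicators
    counts = np.bincount(labels, minlength=n_groups)
    ss_total = sq.sum() / (2.0 * n)
    ss_within = np.zeros(R)
    for g in range(n_groups):
        if counts[g] > 1:
            M = (perm_labels == g).astype(float)
            ss_within += np.einsum("rn,rn->r", M @ sq, M) / (2.0 * counts[g])
    df_between, df_within = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_within) / df_between) / (ss_within / df_within)
    f_perm = np.where(ss_within <= 0, np.inf, f_perm)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)
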