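"""Cross-space correlation screening and phenotype-immune-microbiome triplets.

Associations between measurement spaces (clinical phenotypes, immune cell
populations, microbiome taxa/modules) are screened in two steps:

1. Spearman correlation over samples pooled across visits, BH-adjusted within
   each unordered space-pair family (default FDR < 0.05);
2. a same-donor post-hoc guarding against pseudo-replication: for each
   surviving pair, two random-intercept models are fitted by maximum
   likelihood on the rank-transformed variables (rank(y) ~ rank(x) and the
   reverse, patient as random effect), each compared to the intercept-plus-
   random-effect null by likelihood ratio. The *larger* of the two p-values
   must fall below 0.05 for the edge to count as robust, so a correlation
   carried purely by between-subject level differences is rejected.

Robust edges are then assembled into (clinical, immune, microbiome) triplets
retained when at least two of the three pairwise edges are robust and at
least one member feature passed the intervention contrast screen.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import bh_fdr
from .io import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pooled Spearman screen
# ---------------------------------------------------------------------------


def _spearman_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho between columns of A and columns of B."""
    ra = stats.rankdata(A, axis=0)
    rb = stats.rankdata(B, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    return rho


def spearman_screen(
    table_a: FeatureTable,
    table_b: FeatureTable,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen every feature pair across two spaces by pooled Spearman rho.

    Average-rank tie handling; p from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)); BH adjustment across all pairs of this
    space pair (one family per unordered pair of spaces). Constant features
    have undefined rho and are skipped with a note. Returns an edge table with
    columns feature_a/space_a/feature_b/space_b/rho/p/q/screen_pass.
    """
    if list(table_a.sample_ids) != list(table_b.sample_ids):
        raise ValueError("tables must share identical sample ids (pooled visits)")
    A = table_a.values.astype(float)
    B = table_b.values.astype(float)
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 pooled samples")
    const_a = np.all(A == A[0], axis=0)
    const_b = np.all(B == B[0], axis=0)
    if const_a.any() or const_b.any():
        skipped = [f for f, c in zip(table_a.feature_ids, const_a) if c]
        skipped += [f for f, c in zip(table_b.feature_ids, const_b) if c]
        logger.info("skipping constant features with undefined rho: %s", skipped)
    rho = _spearman_matrix(A, B)
    ia, ib = np.meshgrid(
        np.flatnonzero(~const_a), np.flatnonzero(~const_b), indexing="ij"
    )
    ia, ib = ia.ravel(), ib.ravel()
    r = np.clip(rho[ia, ib], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.minimum(p, 1.0)
    q = bh_fdr(p)
    feats_a = np.asarray(table_a.feature_ids, dtype=object)
    feats_b = np.asarray(table_b.feature_ids, dtype=object)
    return pd.DataFrame(
        {
            "feature_a": feats_a[ia],
            "space_a": table_a.space,
            "feature_b": feats_b[ib],
            "space_b": table_b.space,
            "rho": r,
            "p": p,
            "q": q,
            "screen_pass": q < q_threshold,
        }
    )


# ---------------------------------------------------------------------------
# Same-donor post-hoc
# ---------------------------------------------------------------------------


def _rank_lmm_lrt_p(ry: np.ndarray, rx: np.ndarray, subjects: np.ndarray) -> float:
    """LRT p for a fixed slope in a random-intercept model fitted by ML."""
    import statsmodels.api as sm

    exog_full = np.column_stack([np.ones_like(rx), rx])
    exog_null = np.ones((len(ry), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(ry, exog_full, groups=subjects).fit(reml=False)
        null = sm.MixedLM(ry, exog_null, groups=subjects).fit(reml=False)
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    return float(stats.chi2.sf(stat, 1))


def same_donor_posthoc(
    x: Sequence[float], y: Sequence[float], subject_ids: Sequence
) -> float:
    """Repeated-measures guard for a pooled correlation.

    Fits rank(y) ~ rank(x) and rank(x) ~ rank(y), each with a per-subject
    random intercept (ML), against the corresponding intercept-only null.
    Returns the larger of the two likelihood-ratio p-values — both directions
    must show a within-subject signal. Variance-estimation failures return
    p = 1 (conservative); boundary fits with zero random-effect variance fall
    back to the effectively-fixed model's likelihood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subject_ids)
    if not (len(x) == len(y) == len(subjects)):
        raise ValueError("x, y, subject_ids must align")
    counts = pd.Series(subjects).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with repeated samples")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ps = []
    for endog, exog in ((ry, rx), (rx, ry)):
        try:
            ps.append(_rank_lmm_lrt_p(endog, exog, subjects))
        except Exception as exc:  # singular fits, non-convergence
            logger.warning("mixed-model post-hoc failed (%s); p = 1", exc)
            ps.append(1.0)
    return max(ps)


def apply_posthoc(
    edges: pd.DataFrame,
    tables: Mapping[str, FeatureTable],
    subject_ids: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the same-donor post-hoc on screen-passing edges; flag robust ones.

    ``tables`` maps space name -> FeatureTable (shared sample order).
    Edges failing the screen keep p_posthoc = NaN and robust = False.
    """
    edges = edges.copy()
    edges["p_posthoc"] = np.nan
    edges["robust"] = False
    for idx in edges.index[edges["screen_pass"]]:
        row = edges.loc[idx]
        xa = tables[row["space_a"]].data[row["feature_a"]].to_numpy(dtype=float)
        xb = tables[row["space_b"]].data[row["feature_b"]].to_numpy(dtype=float)
        p = same_donor_posthoc(xa, xb, subject_ids)
        edges.loc[idx, "p_posthoc"] = p
        edges.loc[idx, "robust"] = bool(p < alpha)
    return edges


# ---------------------------------------------------------------------------
# Triplets
# ---------------------------------------------------------------------------


def build_triplets(
    edges_clin_imm: pd.DataFrame,
    edges_clin_mic: pd.DataFrame,
    edges_imm_mic: pd.DataFrame,
    contrast_hits: Iterable[str],
) -> pd.DataFrame:
    """Assemble clinical-immune-microbiome triplets from robust edges.

    A triplet is retained when at least two of its three pairwise edges are
    robust and at least one member feature is in ``contrast_hits`` (features
    significantly affected by the intervention per the drug-adjusted screen).
    Edge orientation is normalized so feature_a of each edge table is the
    clinical (respectively immune) member. Output rows carry the per-edge
    robust flags, signs, and the intervention-affected members.
    """
    hits = set(contrast_hits)

    def robust_pairs(edges: pd.DataFrame) -> dict[tuple[str, str], float]:
        if edges.empty:
            return {}
        sub = edges[edges["robust"]]
        return {
            (a, b): r
            for a, b, r in zip(sub["feature_a"], sub["feature_b"], sub["rho"])
        }

    ci = robust_pairs(edges_clin_imm)  # (clinical, immune)
    cm = robust_pairs(edges_clin_mic)  # (clinical, microbiome)
    im = robust_pairs(edges_imm_mic)  # (immune, microbiome)

    candidates: set[tuple[str, str, str]] = set()
    ci_by_c: dict[str, list[str]] = {}
    for c, i in ci:
        ci_by_c.setdefault(c, []).append(i)
    cm_by_c: dict[str, list[str]] = {}
    for c, m in cm:
        cm_by_c.setdefault(c, []).append(m)
    for c in set(ci_by_c) & set(cm_by_c):
        for i in ci_by_c[c]:
            for m in cm_by_c[c]:
                candidates.add((c, i, m))
    for (c, i) in ci:
        for (i2, m) in im:
            if i2 == i:
                candidates.add((c, i, m))
    for (c, m) in cm:
        for (i, m2) in im:
            if m2 == m:
                candidates.add((c, i, m))

    rows = []
    for c, i, m in sorted(candidates):
        flags = ((c, i) in ci, (c, m) in cm, (i, m) in im)
        n_sig = sum(flags)
        if n_sig < 2:
            continue
        members_hit = sorted({f for f in (c, i, m) if f in hits})
        if not members_hit:
            continue
        rows.append(
            {
                "clinical_feature": c,
                "immune_feature": i,
                "microbiome_feature": m,
                "edge_clin_imm": flags[0],
                "edge_clin_mic": flags[1],
                "edge_imm_mic": flags[2],
                "rho_clin_imm": ci.get((c, i), np.nan),
                "rho_clin_mic": cm.get((c, m), np.nan),
                "rho_imm_mic": im.get((i, m), np.nan),
                "n_significant_edges": n_sig,
                "intervention_hit": ";".join(members_hit),
            }
        )
    columns = [
        "clinical_feature",
        "immune_feature",
        "microbiome_feature",
        "edge_clin_imm",
        "edge_clin_mic",
        "edge_imm_mic",
        "rho_clin_imm",
        "rho_clin_mic",
        "rho_imm_mic",
        "n_significant_edges",
        "intervention_hit",
    ]
    return pd.DataFrame(rows, columns=columns)
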