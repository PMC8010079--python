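"""Responder stratification and leakage-safe subject-level response prediction.

Subjects are stratified into blood-pressure responders and non-responders
from the change in 24 h ambulatory systolic BP between baseline and follow-up,
adjusted for antihypertensive medication: a BP drop without a medication
increase, or a medication reduction without a BP rise, marks a responder.

Prediction follows a leave-one-subject-out (LOSO) protocol in which every
data-dependent step — z-scoring, forward-stepwise feature selection, and the
final ridge-penalized logistic fit — is carried out on the n-1 training
subjects only, so the held-out subject never leaks into model construction.
Selection greedily adds the candidate feature with the smallest
likelihood-ratio p-value; the final classifier minimizes

    0.5 * ||w||^2 + C * sum_i log(1 + exp(-y_i * x_i . w))

with no intercept (C = 1 by default), solved by damped Newton iterations to a
gradient norm below 1e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


# ---------------------------------------------------------------------------
# Responder stratification
# ---------------------------------------------------------------------------


@dataclass
class ResponderRule:
    """Two-branch reconstruction of the medication-adjusted BP response rule.

    responder iff (delta_sbp <= -sbp_cut and delta_med <= 0)
              or (delta_med < 0 and delta_sbp <= sbp_rise_tolerance)

    i.e. the subject's ambulatory systolic BP dropped by at least ``sbp_cut``
    mmHg without added medication, or medication was reduced while BP did not
    rise. All thresholds are configurable so a different decision tree can be
    transcribed.
    """

    sbp_cut: float = 2.0
    sbp_rise_tolerance: float = 0.0
    med_increase_tolerance: float = 0.0

    def classify(self, delta_sbp: float, delta_med: float) -> str:
        drop_branch = (
            delta_sbp <= -self.sbp_cut and delta_med <= self.med_increase_tolerance
        )
        med_branch = delta_med < 0 and delta_sbp <= self.sbp_rise_tolerance
        return RESPONDER if (drop_branch or med_branch) else NON_RESPONDER


def stratify_responders(
    metadata: pd.DataFrame,
    norm_medication,
    rule: ResponderRule | None = None,
    from_visit: str = "V1",
    to_visit: str = "V3",
) -> pd.DataFrame:
    """Label each subject from its ambulatory SBP and medication trajectory.

    Returns a DataFrame (subject_id, label, delta_sbp, delta_med). Subjects
    missing the follow-up SBP are excluded with a warning.
    """
    rule = rule or ResponderRule()
    rows = []
    for subject, grp in metadata.groupby("subject_id", sort=True):
        by_visit = grp.set_index("visit")["sbp_24h"]
        if from_visit not in by_visit or to_visit not in by_visit:
            logger.warning("subject %s missing a visit; unlabeled", subject)
            continue
        sbp_a, sbp_b = by_visit[from_visit], by_visit[to_visit]
        if pd.isna(sbp_a) or pd.isna(sbp_b):
            logger.warning("subject %s missing ambulatory SBP; unlabeled", subject)
            continue
        delta_sbp = float(sbp_b - sbp_a)
        if norm_medication is not None:
            delta_med = norm_medication.agent_sum_at(
                subject, to_visit
            ) - norm_medication.agent_sum_at(subject, from_visit)
        else:
            delta_med = 0.0
        rows.append(
            {
                "subject_id": subject,
                "label": rule.classify(delta_sbp, delta_med),
                "delta_sbp": delta_sbp,
                "delta_med": delta_med,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "label", "delta_sbp", "delta_med"])


# ---------------------------------------------------------------------------
# Ridge-penalized logistic core (no intercept)
# ---------------------------------------------------------------------------


def _logistic_loss_batch(W: np.ndarray, X: np.ndarray, sy: np.ndarray, alpha: float) -> np.ndarray:
    z = np.einsum("cnd,cd->cn", X, W) * sy
    return np.logaddexp(0.0, -z).sum(axis=1) + 0.5 * alpha * (W**2).sum(axis=1)


def _newton_logistic_batch(
    X: np.ndarray,
    y01: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 60,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton minimization of the L2-penalized logistic loss.

    ``X`` has shape (batch, n, d); all batch problems share the labels
    ``y01`` in {0, 1}. ``alpha`` is the ridge weight on 0.5*||w||^2. Returns
    ``(W, loglik)`` where loglik is the *unpenalized* log-likelihood at the
    solution (used for likelihood-ratio screening).
    """
    C, n, d = X.shape
    sy = np.where(y01 > 0, 1.0, -1.0)[None, :]
    W = np.zeros((C, d)) if w0 is None else w0.copy()
    eye = alpha * np.eye(d)[None, :, :]
    loss = _logistic_loss_batch(W, X, sy, alpha)
    for _ in range(max_iter):
        z = np.einsum("cnd,cd->cn", X, W)
        mu = special.expit(z)
        grad = np.einsum("cnd,cn->cd", X, mu - y01[None, :]) + alpha * W
        gnorm = np.linalg.norm(grad, axis=1)
        if np.all(gnorm <= tol):
            break
        wgt = np.maximum(mu * (1.0 - mu), 1e-12)
        H = np.einsum("cnd,cn,cne->cde", X, wgt, X) + eye
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # backtracking keeps Newton stable under (quasi-)separation
        t = np.ones((C, 1))
        for _ in range(30):
            W_new = W - t * step
            loss_new = _logistic_loss_batch(W_new, X, sy, alpha)
            worse = loss_new > loss + 1e-12
            if not np.any(worse):
                break
            t[worse] *= 0.5
        W = W - t * step
        loss = _logistic_loss_batch(W, X, sy, alpha)
    z = np.einsum("cnd,cd->cn", X, W)
    loglik = -(np.logaddexp(0.0, -z * sy)).sum(axis=1)
    return W, loglik


@dataclass
class RidgeModel:
    """No-intercept ridge-logistic classifier with its training scaler."""

    feature_ids: list
    weights: np.ndarray
    c_penalty: float
    scaler_mean: np.ndarray
    scaler_std: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_std
        return Z @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


def fit_ridge_logistic(
    X: np.ndarray, y: Sequence[int], c_penalty: float = 1.0
) -> np.ndarray:
    """Minimize 0.5*||w||^2 + C * sum log(1 + exp(-y~ x.w)), no intercept.

    The objective is convex with a unique minimizer; the Newton solver is run
    to gradient norm <= 1e-8 (of the equivalent per-C-scaled objective).
    Returns the weight vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if c_penalty <= 0:
        raise ValueError("C must be positive")
    # same minimizer as the stated objective, scaled by 1/C: alpha = 1/C
    W, _ = _newton_logistic_batch(X[None], y.astype(float), alpha=1.0 / c_penalty, tol=1e-9)
    return W[0]


def ridge_logistic_objective(w: np.ndarray, X: np.ndarray, y: Sequence[int], c_penalty: float) -> float:
    """The stated penalized loss; exposed for independent verification."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    sy = np.where(np.asarray(y) > 0, 1.0, -1.0)
    z = X @ w * sy
    return 0.5 * float(w @ w) + c_penalty * float(np.logaddexp(0.0, -z).sum())


# ---------------------------------------------------------------------------
# Forward stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class StepwisePath:
    """Ordered selected features with the LRT p-value at each selection step."""

    features: list
    p_values: list[float]
    flagged: list[bool]  # steps whose best p-value was not < 0.05


def forward_stepwise_select(
    X: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    feature_ids: Sequence | None = None,
    micro_ridge: float = 1e-6,
) -> StepwisePath:
    """Greedy forward selection by likelihood-ratio p-value.

    Starting from the empty (no-intercept) null model, each step adds the
    candidate whose inclusion in the logistic model gives the smallest LRT
    p-value (chi-square, 1 df), ties broken by feature order. A tiny ridge
    (1e-6) stabilizes fitting under separation; the likelihood ratio uses the
    unpenalized log-likelihood at the fitted weights. Runs to ``k`` features
    regardless of significance, flagging steps with p >= 0.05.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds {p} available features")
    if feature_ids is None:
        feature_ids = list(range(p))
    feature_ids = list(feature_ids)
    selected: list[int] = []
    path = StepwisePath(features=[], p_values=[], flagged=[])
    ll_current = -n * np.log(2.0)  # empty no-intercept model: score 0 everywhere
    w_current = np.zeros(0)
    for _ in range(k):
        candidates = [j for j in range(p) if j not in selected]
        d = len(selected) + 1
        Xb = np.empty((len(candidates), n, d))
        if selected:
            Xb[:, :, :-1] = X[:, selected][None, :, :]
        Xb[:, :, -1] = X[:, candidates].T
        w0 = np.zeros((len(candidates), d))
        if selected:
            w0[:, :-1] = w_current
        W, loglik = _newton_logistic_batch(Xb, y, alpha=micro_ridge, tol=1e-8, w0=w0)
        lrt = np.maximum(2.0 * (loglik - ll_current), 0.0)
        pvals = stats.chi2.sf(lrt, 1)
        best = int(np.argmin(pvals))  # argmin takes the first minimum: feature-order ties
        j = candidates[best]
        selected.append(j)
        w_current = W[best]
        ll_current = float(loglik[best])
        path.features.append(feature_ids[j])
        path.p_values.append(float(pvals[best]))
        path.flagged.append(bool(pvals[best] >= 0.05))
    return path


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-fold z-scaler; constant features get unit scale."""
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def classification_metrics(
    true_labels: Sequence, predicted_labels: Sequence, positive_class=1
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 with a designated positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("label vectors must be non-empty and aligned")
    tp = int(np.sum((t == positive_class) & (p == positive_class)))
    fn = int(np.sum((t == positive_class) & (p != positive_class)))
    tn = int(np.sum((t != positive_class) & (p != positive_class)))
    fp = int(np.sum((t != positive_class) & (p == positive_class)))
    return {
        "accuracy": (tp + tn) / t.size,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


@dataclass
class PredictionReport:
    """Per-fold LOSO predictions plus aggregate confusion metrics."""

    folds: pd.DataFrame  # subject_id, true_label, predicted_label, score, selected
    metrics: dict[str, float]


def loso_cv_predict(
    X: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    c_penalty: float = 1.0,
    subject_ids: Sequence | None = None,
    feature_ids: Sequence | None = None,
    selection_ridge: float | None = None,
) -> PredictionReport:
    """Leave-one-subject-out prediction with fold-internal selection.

    For each fold the held-out subject is removed *before* anything is
    estimated: z-scaling statistics, the forward-stepwise path, and the ridge
    fit all use the remaining subjects only. The held-out subject is scored
    at decision threshold 0 (responder iff score > 0). Single-class training
    folds are skipped with a warning.

    By default candidate features are evaluated during selection under the
    same L2 penalty as the final model (``alpha = 1/C``): with a vanishing
    penalty, small training folds become linearly separable after a few
    selections and the saturated likelihood makes all later steps
    uninformative. Pass ``selection_ridge`` explicitly to override.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    if selection_ridge is None:
        selection_ridge = 1.0 / c_penalty
    rows = []
    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        if np.unique(y_train).size < 2:
            logger.warning("fold %s has single-class training labels; skipped", subject_ids[i])
            continue
        mean, std = _fit_scaler(X[train])
        Z_train = (X[train] - mean) / std
        path = forward_stepwise_select(
            Z_train, y_train, k=k, feature_ids=feature_ids, micro_ridge=selection_ridge
        )
        sel_idx = (
            [list(feature_ids).index(f) for f in path.features]
            if feature_ids is not None
            else path.features
        )
        w = fit_ridge_logistic(Z_train[:, sel_idx], y_train, c_penalty)
        z_test = (X[i] - mean) / std
        score = float(z_test[sel_idx] @ w)
        rows.append(
            {
                "subject_id": subject_ids[i],
                "true_label": int(y[i]),
                "predicted_label": int(score > 0),
                "score": score,
                "selected": ";".join(str(f) for f in path.features),
            }
        )
    folds = pd.DataFrame(
        rows, columns=["subject_id", "true_label", "predicted_label", "score", "selected"]
    )
    metrics = classification_metrics(
        folds["true_label"].to_numpy(), folds["predicted_label"].to_numpy(), positive_class=1
    )
    return PredictionReport(folds=folds, metrics=metrics)


# ---------------------------------------------------------------------------
# Cross-cohort transfer
# ---------------------------------------------------------------------------


def transfer_predict(
    train_X: pd.DataFrame,
    train_y: Sequence[int],
    external_X: pd.DataFrame,
    feature_filter: Iterable | None = None,
    k: int = 5,
    c_penalty: float = 1.0,
    external_y: Sequence[int] | None = None,
    selection_ridge: float | None = None,
) -> dict:
    """Train once on the full training cohort, apply to an external cohort.

    ``feature_filter`` restricts the candidate features (e.g. to taxa that
    were responder-specific in the training cohort) before stepwise selection
    of ``k`` features. External features missing from the external table are
    imputed at the training mean, i.e. contribute 0 after scaling (warned).
    Returns predictions, the selected path, and — when external truth is
    given — the correct-classification count and metrics.
    """
    if feature_filter is not None:
        cols = [c for c in feature_filter if c in train_X.columns]
        train_X = train_X[cols]
    if train_X.shape[1] == 0:
        raise ValueError("no candidate features after filtering")
    overlap = [c for c in train_X.columns if c in external_X.columns]
    if not overlap:
        raise ValueError("no overlapping features between cohorts")
    y = np.asarray(train_y).astype(int)
    Xt = train_X.to_numpy(dtype=float)
    mean, std = _fit_scaler(Xt)
    Zt = (Xt - mean) / std
    if selection_ridge is None:
        selection_ridge = 1.0 / c_penalty
    path = forward_stepwise_select(
        Zt, y, k=k, feature_ids=list(train_X.columns), micro_ridge=selection_ridge
    )
    sel = path.features
    missing = [f for f in sel if f not in external_X.columns]
    if missing:
        logger.warning("external table missing selected features %s; imputed as 0", missing)
    sel_idx = [list(train_X.columns).index(f) for f in sel]
    w = fit_ridge_logistic(Zt[:, sel_idx], y, c_penalty)
    Ze = np.zeros((len(external_X), len(sel)))
    for j, f in enumerate(sel):
        if f in external_X.columns:
            Ze[:, j] = (external_X[f].to_numpy(dtype=float) - mean[sel_idx[j]]) / std[sel_idx[j]]
    scores = Ze @ w
    pred = (scores > 0).astype(int)
    out = {
        "predicted": pred,
        "scores": scores,
        "selected": sel,
        "weights": w,
    }
    if external_y is not None:
        ye = np.asarray(external_y).astype(int)
        out["n_correct"] = int(np.sum(pred == ye))
        out["metrics"] = classification_metrics(ye, pred, positive_class=1)
    return out
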