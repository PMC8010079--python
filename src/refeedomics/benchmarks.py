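"""End-to-end validation benchmarks on synthetic cohorts.

Each function generates data with the :mod:`refeedomics.simulate` ground
truth, runs the corresponding analysis stage from scratch, and returns the
measured operating characteristics (calibration, type-I error, sensitivity,
precision/recall, cross-validated accuracy). They are the package's own
evidence that the machinery behaves as designed; tests and the acceptance
script both call them.

All randomness flows from the ``seed`` argument; problem sizes default to the
study-scale conditions described in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import contrasts as _contrasts
from . import diversity as _diversity
from . import io as _io
from . import network as _network
from . import predict as _predict
from . import simulate as _simulate


def _subseeds(seed: int, n: int, tag: int) -> list[int]:
    """Independent child seeds below 2**31, reproducible from (seed, tag)."""
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def _arm_subset(cohort, arm: str = "fasting+DASH"):
    meta = cohort.metadata[cohort.metadata["arm"] == arm].reset_index(drop=True)
    keep = [_io.sample_id(s, v) for s, v in zip(meta["subject_id"], meta["visit"])]
    return meta, keep


# ---------------------------------------------------------------------------
# Cliff's delta calibration of the generator
# ---------------------------------------------------------------------------


def cliffs_delta_calibration(
    target: float = 0.6,
    n_seeds: int = 20,
    n_subjects_per_arm: int = 35,
    seed: int = 0,
) -> float:
    """Mean empirical V2-vs-V1 Cliff's delta of a planted taxon (fasting arm)."""
    deltas = []
    for s in _subseeds(seed, n_seeds, tag=101):
        design = _simulate.CohortDesign(
            n_subjects_per_arm=n_subjects_per_arm,
            n_taxa=100,
            n_modules=5,
            n_immune=5,
            planted_effects=[
                _simulate.PlantedEffect("taxa_000", "taxa", "reversible", target)
            ],
            seed=s,
        )
        cohort = _simulate.simulate_cohort(design)
        subjects = cohort.metadata.loc[
            cohort.metadata["arm"] == "fasting+DASH", "subject_id"
        ].unique()
        col = cohort.taxa_counts.data["taxa_000"]
        v1 = col.loc[[_io.sample_id(s_, "V1") for s_ in subjects]]
        v2 = col.loc[[_io.sample_id(s_, "V2") for s_ in subjects]]
        deltas.append(_contrasts.cliffs_delta(v2, v1))
    return float(np.mean(deltas))


# ---------------------------------------------------------------------------
# Deconfounding (null cohorts with medication-driven features)
# ---------------------------------------------------------------------------


def deconfounding_benchmark(
    n_seeds: int = 25,
    n_subjects_per_arm: int = 35,
    n_taxa: int = 200,
    n_confounded: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Screen null cohorts whose only visit-linked signal is medication.

    Returns the mean fraction of features flagged by the adjusted screen, the
    per-seed flag rate of the confounded features under the adjusted screen,
    and their flag rate under the naive (covariate-free) marginal MWU.
    """
    frac_flagged = []
    confounded_adjusted = []
    confounded_marginal = []
    for s in _subseeds(seed, n_seeds, tag=102):
        design = _simulate.CohortDesign(
            n_subjects_per_arm=n_subjects_per_arm,
            n_taxa=n_taxa,
            n_modules=5,
            n_immune=5,
            med_confounded_features=n_confounded,
            seed=s,
        )
        cohort = _simulate.simulate_cohort(design)
        meta = cohort.metadata.reset_index(drop=True)
        results = _contrasts.run_contrast_screen(
            [cohort.taxa_counts], meta, cohort.norm_medication
        )
        sig = {f for _, f in _contrasts.significant_features(results)}
        frac_flagged.append(len(sig) / n_taxa)
        conf = sorted(cohort.truth.confounded_features)
        confounded_adjusted.append([f in sig for f in conf])
        marginal = _contrasts.marginal_mwu_flags(
            cohort.taxa_counts, meta, contrast=("V1", "V3")
        )
        confounded_marginal.append(marginal[conf].to_numpy())
    adj = np.asarray(confounded_adjusted, dtype=float)
    marg = np.asarray(confounded_marginal, dtype=float)
    return {
        "mean_fraction_flagged": float(np.mean(frac_flagged)),
        "max_confounded_adjusted_rate": float(adj.mean(axis=0).max()),
        "mean_confounded_adjusted_rate": float(adj.mean()),
        "min_confounded_marginal_rate": float(marg.mean(axis=0).min()),
        "mean_confounded_marginal_rate": float(marg.mean()),
    }


# ---------------------------------------------------------------------------
# Screen power and effect-sign direction
# ---------------------------------------------------------------------------


def screen_power_benchmark(
    n_effects: int = 20,
    target: float = 0.6,
    n_seeds: int = 5,
    n_subjects_per_arm: int = 35,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity and sign agreement for planted reversible effects."""
    detected, total, signs_ok, n_detected = 0, 0, 0, 0
    for s in _subseeds(seed, n_seeds, tag=103):
        effects = [
            _simulate.PlantedEffect(
                f"taxa_{i:03d}", "taxa", "reversible", target if i % 2 == 0 else -target
            )
            for i in range(n_effects)
        ]
        design = _simulate.CohortDesign(
            n_subjects_per_arm=n_subjects_per_arm,
            n_taxa=200,
            n_modules=5,
            n_immune=5,
            planted_effects=effects,
            seed=s,
        )
        cohort = _simulate.simulate_cohort(design)
        meta, keep = _arm_subset(cohort)
        table = _io.FeatureTable(
            cohort.taxa_counts.data.loc[keep], space="taxa16S", unit="counts"
        )
        results = _contrasts.run_contrast_screen([table], meta, cohort.norm_medication)
        sig = {f for _, f in _contrasts.significant_features(results)}
        truth_sign = {f: sgn for f, _, _, sgn in cohort.truth.differential_features}
        hits = sig & set(truth_sign)
        detected += len(hits)
        total += n_effects
        v12 = results[results["contrast"] == "V1-V2"].set_index("feature_id")
        for f in hits:
            n_detected += 1
            if np.sign(v12.loc[f, "cliffs_delta"]) == truth_sign[f]:
                signs_ok += 1
    return {
        "sensitivity": detected / total,
        "sign_agreement": signs_ok / max(n_detected, 1),
    }


def bmi_retention_benchmark(
    n_seeds: int = 5, n_subjects_per_arm: int = 35, seed: int = 0
) -> float:
    """Fraction of planted (BMI-independent) hits retained under BMI adjustment."""
    retained, total = 0, 0
    for s in _subseeds(seed, n_seeds, tag=104):
        effects = [
            _simulate.PlantedEffect(f"taxa_{i:03d}", "taxa", "reversible", 0.6)
            for i in range(10)
        ]
        design = _simulate.CohortDesign(
            n_subjects_per_arm=n_subjects_per_arm,
            n_taxa=100,
            n_modules=5,
            n_immune=5,
            planted_effects=effects,
            seed=s,
        )
        cohort = _simulate.simulate_cohort(design)
        meta, keep = _arm_subset(cohort)
        table = _io.FeatureTable(
            cohort.taxa_counts.data.loc[keep], space="taxa16S", unit="counts"
        )
        results = _contrasts.run_contrast_screen([table], meta, cohort.norm_medication)
        orig = _contrasts.significant_features(results)
        if not orig:
            continue
        fraction, _ = _contrasts.bmi_sensitivity(
            results, [table], meta, cohort.norm_medication
        )
        retained += fraction * len(orig)
        total += len(orig)
    return retained / total if total else float("nan")


# ---------------------------------------------------------------------------
# Ordination and PERMANOVA
# ---------------------------------------------------------------------------


def pcoa_recovery_benchmark(
    n_configs: int = 20, n_samples: int = 20, n_dims: int = 5, seed: int = 0
) -> dict[str, float]:
    """Distance reconstruction error of PCoA on Euclidean point clouds."""
    max_err = 0.0
    min_eig = 0.0
    for s in _subseeds(seed, n_configs, tag=105):
        rng = np.random.default_rng(s)
        pts = rng.normal(size=(n_samples, n_dims))
        diff = pts[:, None, :] - pts[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        dist = _diversity.DistanceMatrix([f"s{i}" for i in range(n_samples)], D, "euclidean")
        res = _diversity.pcoa(dist)
        C = res.coordinates
        diff_c = C[:, None, :] - C[None, :, :]
        D_hat = np.sqrt((diff_c**2).sum(axis=2))
        max_err = max(max_err, float(np.abs(D_hat - D).max()))
        min_eig = min(min_eig, float(res.eigenvalues.min()))
    return {"max_reconstruction_error": max_err, "min_eigenvalue": min_eig}


def permanova_type1_benchmark(
    n_replicates: int = 500,
    n_subjects: int = 30,
    n_features: int = 20,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I rate of the stratified test under a within-strata null."""
    rejections = 0
    for s in _subseeds(seed, n_replicates, tag=106):
        rng = np.random.default_rng(s)
        n = n_subjects * 3
        X = rng.normal(size=(n, n_features))
        table = _io.FeatureTable(
            pd.DataFrame(X, index=[f"s{i}" for i in range(n)]),
            space="immune",
            unit="absolute",
        )
        dist = _diversity.beta_distance(table, "euclidean")
        groups = np.tile(["V1", "V2", "V3"], n_subjects)
        strata = np.repeat(np.arange(n_subjects), 3)
        res = _diversity.permanova_stratified(
            dist, groups, strata, n_permutations=n_permutations, seed=s
        )
        rejections += res.p_value <= alpha
    return rejections / n_replicates


def permanova_power_benchmark(
    n_replicates: int = 50,
    n_subjects: int = 30,
    n_features: int = 20,
    shift: float = 1.0,
    seed: int = 0,
) -> float:
    """Rejection rate with a planted multivariate visit shift."""
    hits = 0
    for s in _subseeds(seed, n_replicates, tag=107):
        rng = np.random.default_rng(s)
        n = n_subjects * 3
        X = rng.normal(size=(n, n_features))
        groups = np.tile(["V1", "V2", "V3"], n_subjects)
        X[groups == "V2", : max(n_features // 4, 1)] += shift
        table = _io.FeatureTable(
            pd.DataFrame(X, index=[f"s{i}" for i in range(n)]),
            space="immune",
            unit="absolute",
        )
        dist = _diversity.beta_distance(table, "euclidean")
        strata = np.repeat(np.arange(n_subjects), 3)
        res = _diversity.permanova_stratified(dist, groups, strata, 999, seed=s)
        hits += res.p_value <= 0.01
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Triplet network recovery
# ---------------------------------------------------------------------------


def triplet_recovery_benchmark(
    n_seeds: int = 10,
    n_subjects_per_arm: int = 15,
    rho: float = 0.6,
    seed: int = 0,
) -> dict[str, float]:
    """Precision/recall for 5 planted triplets among >= 12,500 candidates.

    50 immune x 50 taxa x 5 clinical features pooled over 90 samples.
    """
    precisions, recalls = [], []
    clin = ["sbp_24h", "dbp_24h", "bmi", "insulin", "ldl"]
    for s in _subseeds(seed, n_seeds, tag=108):
        design = _simulate.CohortDesign(
            n_subjects_per_arm=n_subjects_per_arm,
            n_taxa=50,
            n_modules=5,
            n_immune=50,
            seed=s,
        )
        cohort = _simulate.simulate_cohort(design)
        planted = [(clin[i], f"imm_{i:03d}", f"taxa_{i:03d}") for i in range(5)]
        for t in planted:
            _simulate.plant_triplet(cohort, rho, t)
        tabs = cohort.tables_by_space()
        e_ci = _network.spearman_screen(tabs["clinical"], tabs["immune"])
        e_cm = _network.spearman_screen(tabs["clinical"], tabs["taxa16S"])
        e_im = _network.spearman_screen(tabs["immune"], tabs["taxa16S"])
        subjects = [sid.rpartition(":")[0] for sid in tabs["clinical"].sample_ids]
        e_ci, e_cm, e_im = (
            _network.apply_posthoc(e, tabs, subjects) for e in (e_ci, e_cm, e_im)
        )
        triplets = _network.build_triplets(e_ci, e_cm, e_im, set(clin))
        found = set(
            zip(
                triplets["clinical_feature"],
                triplets["immune_feature"],
                triplets["microbiome_feature"],
            )
        )
        tp = len(found & set(planted))
        recalls.append(tp / len(planted))
        precisions.append(tp / len(found) if found else 1.0)
    return {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
    }


def pseudoreplication_benchmark(
    n_sims: int = 50, n_subjects: int = 30, seed: int = 0
) -> dict[str, float]:
    """The same-donor post-hoc against between- and within-subject coupling.

    Between-subject coupling (subject means moderately correlated, visits
    independent — classic pseudo-replication) must be rejected; genuine
    within-subject co-movement must be retained. The coupling is set so that
    pooling the three visits per subject inflates the apparent sample size
    (90 samples instead of 30 subjects) past the significance threshold while
    the subject-level evidence alone stays below it — exactly the situation
    the two-step design exists to catch. Returns the rejection rate
    (p > 0.05) for the former, the detection rate (p < 0.05) for the latter,
    and the rate at which the pooled Spearman screen alone flags the
    pseudo-replicated pairs.
    """
    rejected_between, pooled_flagged, detected_within = 0, 0, 0
    r_between = 0.25
    for s in _subseeds(seed, n_sims, tag=109):
        rng = np.random.default_rng(s)
        subjects = np.repeat(np.arange(n_subjects), 3)
        # between-subject only: shared subject level, independent visit noise
        a = rng.normal(size=n_subjects)
        b = r_between * a + np.sqrt(1 - r_between**2) * rng.normal(size=n_subjects)
        x = 2.0 * a[subjects] + rng.normal(size=len(subjects)) * 0.3
        y = 2.0 * b[subjects] + rng.normal(size=len(subjects)) * 0.3
        p_post = _network.same_donor_posthoc(x, y, subjects)
        rejected_between += p_post > 0.05
        from scipy import stats as _st

        rho, p_pool = _st.spearmanr(x, y)
        pooled_flagged += p_pool < 0.05
        # within-subject coupling: shared per-sample factor
        f = rng.normal(size=len(subjects))
        u = rng.normal(size=n_subjects)
        x2 = u[subjects] + 0.8 * f + 0.4 * rng.normal(size=len(subjects))
        y2 = u[subjects] * 0.0 + 0.8 * f + 0.4 * rng.normal(size=len(subjects))
        detected_within += _network.same_donor_posthoc(x2, y2, subjects) < 0.05
    return {
        "between_rejected_rate": rejected_between / n_sims,
        "pooled_flagged_rate": pooled_flagged / n_sims,
        "within_detected_rate": detected_within / n_sims,
    }


# ---------------------------------------------------------------------------
# Prediction benchmarks
# ---------------------------------------------------------------------------


def loso_null_benchmark(
    n_seeds: int = 50, n_subjects: int = 32, n_features: int = 494, k: int = 10, seed: int = 0
) -> float:
    """Mean LOSO accuracy on label-randomized pure-noise features (leakage null)."""
    accs = []
    for s in _subseeds(seed, n_seeds, tag=110):
        X, y, _ = _simulate.simulate_prediction_dataset(
            n_subjects, n_features, n_informative=0, seed=s
        )
        report = _predict.loso_cv_predict(X, y, k=k)
        accs.append(report.metrics["accuracy"])
    return float(np.mean(accs))


def loso_planted_benchmark(
    n_seeds: int = 25,
    n_subjects: int = 32,
    n_features: int = 494,
    n_informative: int = 5,
    separation: float = 1.5,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean LOSO accuracy with planted informative features."""
    accs = []
    for s in _subseeds(seed, n_seeds, tag=111):
        X, y, _ = _simulate.simulate_prediction_dataset(
            n_subjects, n_features, n_informative, separation, seed=s
        )
        report = _predict.loso_cv_predict(X, y, k=k)
        accs.append(report.metrics["accuracy"])
    return float(np.mean(accs))


def transfer_benchmark(
    n_seeds: int = 25,
    n_train: int = 32,
    n_external: int = 15,
    n_features: int = 200,
    n_informative: int = 5,
    separation: float = 1.5,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean correct classifications on an independent same-process cohort."""
    corrects = []
    for s in _subseeds(seed, n_seeds, tag=112):
        X, y, names = _simulate.simulate_prediction_dataset(
            n_train, n_features, n_informative, separation, seed=s
        )
        Xe, ye, _ = _simulate.simulate_prediction_dataset(
            n_external, n_features, n_informative, separation, seed=s + 7_000_001
        )
        out = _predict.transfer_predict(
            pd.DataFrame(X, columns=names),
            y,
            pd.DataFrame(Xe, columns=names),
            k=k,
            external_y=ye,
        )
        corrects.append(out["n_correct"])
    return float(np.mean(corrects))
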