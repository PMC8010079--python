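"""Cliff's delta, MWU, BH, nested LRT, and the two-step screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refeedomics import CohortDesign, simulate_cohort
from refeedomics.contrasts import (
    ContrastConfig,
    bh_fdr,
    bmi_sensitivity,
    build_nested_design,
    cliffs_delta,
    mwu_test,
    nested_lrt,
    run_contrast_screen,
    significant_features,
)
from refeedomics.io import FeatureTable, sample_id


def cliffs_delta_bruteforce(x, y):
    x = np.asarray(x)[:, None]
    y = np.asarray(y)[None, :]
    return float((x > y).sum() - (x < y).sum()) / (x.size * y.size)


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [4, 5, 6], -1.0),
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 3], [2, 2], 0.0),
            ([4, 5, 6], [1, 2, 3], 1.0),
        ],
    )
    def test_hand_examples(self, x, y, expected):
        assert cliffs_delta(x, y) == expected

    def test_matches_pair_enumeration(self, rng):
        for _ in range(50):
            x = rng.integers(0, 10, size=rng.integers(1, 20))
            y = rng.integers(0, 10, size=rng.integers(1, 20))
            assert cliffs_delta(x, y) == pytest.approx(cliffs_delta_bruteforce(x, y))

    @given(
        x=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
        y=st.lists(st.integers(-50, 50), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_monotone_invariance(self, x, y):
        d = cliffs_delta(x, y)
        assert cliffs_delta(y, x) == pytest.approx(-d)
        fx = [v**3 + 2 * v for v in x]  # strictly increasing transform
        fy = [v**3 + 2 * v for v in y]
        assert cliffs_delta(fx, fy) == pytest.approx(d)
        assert -1.0 <= d <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1])


class TestMwu:
    def test_exact_small_sample(self):
        _, p = mwu_test([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_identical_samples(self):
        _, p = mwu_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_constant_pooled_data(self):
        _, p = mwu_test([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_null_uniformity(self, rng):
        # asymptotic branch: p-values roughly uniform under the null
        from scipy import stats

        ps = []
        for _ in range(1000):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps.append(mwu_test(x, y)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        assert np.allclose(bh_fdr([0.05, 1.0]), [0.10, 1.0])
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            mine = bh_fdr(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, theirs)

    def test_q_at_least_p_and_bounded(self, rng):
        p = rng.random(30)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _toy_metadata(n_subjects=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for v in ("V1", "V2", "V3"):
            rows.append(
                {
                    "subject_id": f"p{i:02d}",
                    "arm": "fasting+DASH",
                    "visit": v,
                    "age": 50 + i,
                    "sex": "F" if i % 2 else "M",
                    "bmi": 30 + rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def ols_loglik(X, y):
    """Independent oracle: Gaussian ML log-likelihood via explicit pinv fit."""
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(y)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


class TestNestedLrt:
    def test_constant_feature(self):
        meta = _toy_metadata()
        stat, p = nested_lrt(np.full(len(meta), 3.0), meta)
        assert stat == 0.0 and p == 1.0

    def test_perfect_visit_signal(self, rng):
        meta = _toy_metadata()
        y = (meta["visit"] == "V2").to_numpy(dtype=float) + rng.normal(0, 1e-4, len(meta))
        _, p = nested_lrt(y, meta)
        assert p < 1e-6

    def test_matches_explicit_loglik_oracle(self, rng):
        meta = _toy_metadata()
        design = build_nested_design(meta)
        visit = pd.get_dummies(meta["visit"], drop_first=True, dtype=float).to_numpy()
        ones = np.ones((len(meta), 1))
        age = meta["age"].to_numpy(dtype=float)[:, None]
        sex = (meta["sex"] == "M").to_numpy(dtype=float)[:, None]
        subj = pd.get_dummies(meta["subject_id"], drop_first=True, dtype=float).to_numpy()
        X0 = np.hstack([ones, age, sex, subj])  # age/sex aliased with dummies
        X1 = np.hstack([X0, visit])
        for _ in range(10):
            y = rng.normal(size=len(meta))
            stat, _ = nested_lrt(y, meta)
            oracle = 2.0 * (ols_loglik(X1, y) - ols_loglik(X0, y))
            assert stat == pytest.approx(oracle, abs=1e-8)

    def test_rank_deficiency_does_not_inflate_df(self):
        meta = _toy_metadata()
        design = build_nested_design(meta)
        # visit adds exactly 2 estimable columns despite aliased age/sex
        assert design.df == 2


@pytest.fixture(scope="module")
def planted_screen():
    from refeedomics import PlantedEffect

    effects = [
        PlantedEffect(f"taxa_{i:03d}", "taxa", "reversible", 0.8) for i in range(5)
    ]
    design = CohortDesign(
        n_subjects_per_arm=25,
        n_taxa=60,
        n_modules=5,
        n_immune=5,
        planted_effects=effects,
        seed=77,
    )
    cohort = simulate_cohort(design)
    meta = cohort.metadata[cohort.metadata["arm"] == "fasting+DASH"].reset_index(
        drop=True
    )
    keep = [sample_id(s, v) for s, v in zip(meta["subject_id"], meta["visit"])]
    table = FeatureTable(
        cohort.taxa_counts.data.loc[keep], space="taxa16S", unit="counts"
    )
    results = run_contrast_screen([table], meta, cohort.norm_medication)
    return cohort, meta, table, results


class TestScreen:
    def test_gate_semantics(self, planted_screen):
        _, _, _, results = planted_screen
        failing_gate1 = results[results["q_lrt"] >= 0.1]
        assert not failing_gate1["significant"].any()
        sig = results[results["significant"]]
        assert (sig["q_lrt"] < 0.1).all()
        # every significant feature has some post-hoc q below the gate
        any_q = sig.groupby("feature_id")["q_mwu"].min()
        assert (any_q < 0.05).all()

    def test_planted_effects_recovered(self, planted_screen):
        cohort, _, _, results = planted_screen
        sig = {f for _, f in significant_features(results)}
        planted = {f for f, _, _, _ in cohort.truth.differential_features}
        assert len(sig & planted) >= 4

    def test_bh_family_sizes(self, planted_screen):
        _, _, table, results = planted_screen
        # one LRT family per space: all features share the same family
        assert results["feature_id"].nunique() == len(table.feature_ids)
        # one post-hoc family of size 3 per feature
        per_feature = results.groupby("feature_id")["contrast"].count()
        assert (per_feature == 3).all()
        # within a feature, BH cannot push q below the smallest p * 3 / 3
        for _, grp in results.groupby("feature_id"):
            assert (grp["q_mwu"] >= grp["p_mwu"] - 1e-12).all()

    def test_delta_reported_for_all_contrasts(self, planted_screen):
        _, _, _, results = planted_screen
        assert results["cliffs_delta"].notna().all()

    def test_bmi_sensitivity_na_without_hits(self):
        design = CohortDesign(
            n_subjects_per_arm=8, n_taxa=20, n_modules=5, n_immune=5, seed=5
        )
        cohort = simulate_cohort(design)
        meta = cohort.metadata.reset_index(drop=True)
        results = run_contrast_screen([cohort.taxa_counts], meta, cohort.norm_medication)
        if significant_features(results):
            pytest.skip("rare null cohort with chance hits")
        fraction, _ = bmi_sensitivity(
            results, [cohort.taxa_counts], meta, cohort.norm_medication
        )
        assert np.isnan(fraction)

    def test_bmi_mediated_effect_lost(self):
        """A feature tracking BMI (not the visit) should fail the BMI-adjusted screen."""
        design = CohortDesign(n_subjects_per_arm=25, n_taxa=20, n_modules=5, n_immune=5, seed=9)
        cohort = simulate_cohort(design)
        meta = cohort.metadata[cohort.metadata["arm"] == "fasting+DASH"].reset_index(drop=True)
        rng = np.random.default_rng(0)
        # mediated feature: tracks each subject's BMI excursion from their own
        # mean (equals -5*bmi plus a patient-specific constant, so the BMI
        # covariate absorbs it exactly); the fasting-arm BMI drop makes it
        # visit-associated in the unadjusted screen
        bmi = meta["bmi"].to_numpy()
        subj_mean = meta.groupby("subject_id")["bmi"].transform("mean").to_numpy()
        mediated = -5.0 * (bmi - subj_mean) + rng.normal(0, 0.5, len(meta))
        keep = [sample_id(s, v) for s, v in zip(meta["subject_id"], meta["visit"])]
        data = pd.DataFrame({"mediated": mediated}, index=keep)
        table = FeatureTable(data, space="immune", unit="absolute")
        results = run_contrast_screen([table], meta, cohort.norm_medication)
        assert ("immune", "mediated") in significant_features(results)
        fraction, _ = bmi_sensitivity(results, [table], meta, cohort.norm_medication)
        assert fraction == 0.0
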