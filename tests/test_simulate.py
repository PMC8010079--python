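"""Synthetic cohort generator: determinism, calibration, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refeedomics.contrasts import cliffs_delta, mwu_test
from refeedomics.io import sample_id
from refeedomics.simulate import (
    CohortDesign,
    PlantedEffect,
    export_cohort,
    import_cohort,
    plant_triplet,
    simulate_cohort,
)


def small_design(**kw):
    base = dict(n_subjects_per_arm=8, n_taxa=30, n_modules=8, n_immune=8, seed=1)
    base.update(kw)
    return CohortDesign(**base)


class TestSimulateCohort:
    def test_nothing_planted_means_empty_truth(self):
        cohort = simulate_cohort(small_design())
        assert cohort.truth.differential_features == set()

    def test_determinism_bit_identical(self):
        a = simulate_cohort(small_design(seed=99))
        b = simulate_cohort(small_design(seed=99))
        pd.testing.assert_frame_equal(a.taxa_counts.data, b.taxa_counts.data)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.medication.records, b.medication.records)

    def test_row_sums_are_library_sizes(self):
        cohort = simulate_cohort(small_design())
        sums = cohort.taxa_counts.values.sum(axis=1)
        assert (sums > 0).all()
        assert cohort.taxa_counts.values.dtype.kind == "i"

    def test_one_row_per_subject_visit(self):
        cohort = simulate_cohort(small_design())
        assert len(cohort.metadata) == 8 * 2 * 3
        keys = list(zip(cohort.metadata["subject_id"], cohort.metadata["visit"]))
        assert len(set(keys)) == len(keys)
        expected_ids = [sample_id(s, v) for s, v in keys]
        assert cohort.taxa_counts.sample_ids == expected_ids

    def test_too_many_planted_rejected(self):
        effects = [PlantedEffect(f"taxa_{i:03d}", "taxa") for i in range(5)]
        with pytest.raises(ValueError):
            simulate_cohort(small_design(n_taxa=3, planted_effects=effects))

    def test_unknown_planted_feature_rejected(self):
        with pytest.raises(ValueError, match="does not exist"):
            simulate_cohort(
                small_design(planted_effects=[PlantedEffect("taxa_999", "taxa")])
            )

    def test_confounded_disjoint_from_planted(self):
        effects = [PlantedEffect("taxa_000", "taxa", "reversible", 0.5)]
        cohort = simulate_cohort(
            small_design(planted_effects=effects, med_confounded_features=5)
        )
        planted = {f for f, *_ in cohort.truth.differential_features}
        assert planted.isdisjoint(cohort.truth.confounded_features)

    def test_responder_sbp_drop(self):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=30, seed=3))
        meta = cohort.metadata.set_index(["subject_id", "visit"])
        drops = {
            s: meta.loc[(s, "V1"), "sbp_24h"] - meta.loc[(s, "V3"), "sbp_24h"]
            for s in cohort.metadata["subject_id"].unique()
        }
        resp = [s for s, lab in cohort.truth.responder_labels.items() if lab == "responder"]
        non = [s for s, lab in cohort.truth.responder_labels.items() if lab != "responder"]
        assert np.mean([drops[s] for s in resp]) > np.mean([drops[s] for s in non]) + 4

    def test_sustained_vs_reversible_pattern(self):
        effects = [
            PlantedEffect("taxa_000", "taxa", "reversible", 0.8),
            PlantedEffect("taxa_001", "taxa", "sustained", 0.8),
        ]
        cohort = simulate_cohort(
            small_design(n_subjects_per_arm=30, planted_effects=effects, seed=5)
        )
        subjects = cohort.metadata.loc[
            cohort.metadata["arm"] == "fasting+DASH", "subject_id"
        ].unique()
        counts = cohort.taxa_counts.data

        def delta(feature, va, vb):
            a = counts.loc[[sample_id(s, va) for s in subjects], feature]
            b = counts.loc[[sample_id(s, vb) for s in subjects], feature]
            return cliffs_delta(b, a)

        assert delta("taxa_000", "V1", "V2") > 0.4  # shift present at V2
        assert abs(delta("taxa_000", "V1", "V3")) < 0.3  # reverted by V3
        assert delta("taxa_001", "V1", "V3") > 0.4  # sustained through V3

    def test_null_mwu_p_uniform(self):
        """With nothing planted, V2-vs-V1 per-taxon MWU p-values are uniform."""
        ps = []
        for seed in range(3):
            cohort = simulate_cohort(
                small_design(n_subjects_per_arm=15, n_taxa=60, seed=200 + seed)
            )
            subjects = cohort.metadata["subject_id"].unique()
            counts = cohort.taxa_counts.data
            v1 = counts.loc[[sample_id(s, "V1") for s in subjects]]
            v2 = counts.loc[[sample_id(s, "V2") for s in subjects]]
            for col in counts.columns:
                if v1[col].nunique() > 10:  # skip low-count taxa (tie-discretized p)
                    ps.append(mwu_test(v2[col], v1[col])[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPlantTriplet:
    def test_null_planting_keeps_truth(self):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=15))
        plant_triplet(cohort, 0.0, ("insulin", "imm_000", "taxa_000"))
        assert cohort.truth.planted_triplets == []
        x = cohort.clinical_table.data["insulin"]
        y = cohort.immune_table.data["imm_000"]
        assert abs(stats.spearmanr(x, y).statistic) < 0.2

    def test_positive_target_reached(self):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=15))
        plant_triplet(cohort, 0.9, ("insulin", "imm_000", "taxa_000"))
        x = cohort.clinical_table.data["insulin"]
        y = cohort.immune_table.data["imm_000"]
        z = cohort.taxa_counts.data["taxa_000"]
        assert stats.spearmanr(x, y).statistic >= 0.6
        assert stats.spearmanr(x, z).statistic >= 0.6
        assert stats.spearmanr(y, z).statistic >= 0.6

    def test_negative_target_signs(self):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=15))
        plant_triplet(cohort, -0.9, ("insulin", "imm_000", "taxa_000"))
        x = cohort.clinical_table.data["insulin"]
        y = cohort.immune_table.data["imm_000"]
        z = cohort.taxa_counts.data["taxa_000"]
        assert stats.spearmanr(x, y).statistic < 0
        assert stats.spearmanr(x, z).statistic < 0
        assert stats.spearmanr(y, z).statistic < 0

    def test_depths_preserved_exactly(self):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=10))
        before = cohort.taxa_counts.values.sum(axis=1).copy()
        plant_triplet(cohort, 0.7, ("insulin", "imm_000", "taxa_000"))
        after = cohort.taxa_counts.values.sum(axis=1)
        assert (before == after).all()

    def test_wrong_space_rejected(self):
        cohort = simulate_cohort(small_design())
        with pytest.raises(ValueError):
            plant_triplet(cohort, 0.5, ("imm_000", "insulin", "taxa_000"))


class TestExportImport:
    def test_round_trip(self, tmp_path):
        cohort = simulate_cohort(small_design())
        export_cohort(cohort, tmp_path)
        back = import_cohort(tmp_path)
        pd.testing.assert_frame_equal(back.taxa_counts.data, cohort.taxa_counts.data)
        pd.testing.assert_frame_equal(
            back.clinical_table.data, cohort.clinical_table.data
        )
        pd.testing.assert_frame_equal(
            back.metadata.reset_index(drop=True), cohort.metadata.reset_index(drop=True)
        )
        assert back.truth.responder_labels == cohort.truth.responder_labels

    def test_empty_cohort_exports_headers(self, tmp_path):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=0))
        export_cohort(cohort, tmp_path)
        assert (tmp_path / "metadata.tsv").read_text().startswith("subject_id\t")

    def test_metadata_row_count(self, tmp_path):
        cohort = simulate_cohort(small_design(n_subjects_per_arm=35))
        export_cohort(cohort, tmp_path)
        lines = (tmp_path / "metadata.tsv").read_text().strip().split("\n")
        assert len(lines) == 1 + 70 * 3
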