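"""Synthetic three-visit intervention cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume — not any particular real microbiome. Two arms of subjects are
followed over visits V1 (baseline), V2 (one week post-intervention) and V3
(3-month follow-up). Per feature and subject a latent log-abundance is drawn
with a subject-level random intercept (within-subject correlation), planted
intervention effects enter as latent shifts calibrated to a target Cliff's
delta, taxa counts are drawn compositionally (softmax of the latent field,
then a multinomial at a log-normally distributed library size), and
medication-confounded features track the subject's normalized antihypertensive
dose. Blood-pressure responders receive a sustained ambulatory SBP drop at V3
and, with probability 0.5, a one-agent medication reduction — the
constellation the responder stratification rule is built to recognize.

Every planted signal is recorded in a :class:`GroundTruth` object so
detection performance can be scored exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    FeatureTable,
    MedicationLedger,
    NormalizedMedication,
    normalize_medication,
    read_feature_table,
    read_medication,
    read_metadata,
    sample_id,
    write_feature_table,
    write_medication,
    write_metadata,
)

CLINICAL_FEATURES = (
    "sbp_24h",
    "dbp_24h",
    "map_24h",
    "bmi",
    "weight",
    "insulin",
    "glucose",
    "homa",
    "ldl",
    "crp",
)

#: lab-like clinical features carried by a latent log-normal (plantable)
LATENT_CLINICAL = ("insulin", "glucose", "ldl", "crp")


@dataclass
class PlantedEffect:
    """A deliberate intervention effect on one feature.

    ``pattern="reversible"`` shifts the feature at the onset visit (default
    V2, the post-fasting sample) and reverts afterwards; ``"sustained"``
    keeps the shift through V3. ``target_cliffs_delta`` is the intended
    unpaired V2-vs-V1 effect size in the intervention arm.
    """

    feature_id: str
    space: str  # taxa | module | immune | clinical
    pattern: str = "reversible"
    target_cliffs_delta: float = 0.6
    visit_of_onset: str = "V2"

    def __post_init__(self) -> None:
        if self.space not in ("taxa", "module", "immune", "clinical"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.pattern not in ("reversible", "sustained"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not -1.0 <= self.target_cliffs_delta <= 1.0:
            raise ValueError("target Cliff's delta must lie in [-1, 1]")


@dataclass
class CohortDesign:
    """Knobs of the synthetic cohort; defaults mirror the study's shape.

    Two arms of 35 subjects, three visits, ~200 taxa with log-normal latent
    abundances at a mean library size of 20,000 reads, within-subject latent
    correlation 0.5, and a responder fraction of 22/32 with an 8 mmHg
    sustained ambulatory SBP drop.
    """

    n_subjects_per_arm: int = 35
    visits: tuple[str, str, str] = ("V1", "V2", "V3")
    n_taxa: int = 200
    n_modules: int = 60
    n_immune: int = 50
    sequencing_depth_mean: float = 20_000.0
    depth_sigma: float = 0.3  # log-normal spread of library sizes
    latent_sigma: float = 0.7  # total latent log-abundance SD per feature
    within_subject_corr: float = 0.5
    med_confounded_features: int = 0
    confounder_strength: float = 3.0  # latent shift per unit agent-sum change
    medicated_fraction: float = 0.8
    med_reduction_v2_fraction: float = 0.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    responder_fraction: float = 22 / 32
    responder_sbp_drop_mmhg: float = 8.0
    n_informative_predictors: int = 0
    informative_separation: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.visits) != 3:
            raise ValueError("exactly three visits are required")
        for name in ("n_subjects_per_arm", "n_taxa", "n_modules", "n_immune",
                     "med_confounded_features", "n_informative_predictors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ValueError("within_subject_corr must lie in [0, 1)")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything that was planted, for scoring downstream detection."""

    differential_features: set = field(default_factory=set)  # (feature, space, pattern, sign)
    confounded_features: set = field(default_factory=set)
    planted_triplets: list = field(default_factory=list)  # (clinical, immune, microbe)
    responder_labels: dict = field(default_factory=dict)  # subject -> label
    informative_predictors: set = field(default_factory=set)


@dataclass
class SyntheticCohort:
    design: CohortDesign
    metadata: pd.DataFrame
    taxa_counts: FeatureTable
    module_abundance: FeatureTable
    immune_table: FeatureTable
    clinical_table: FeatureTable
    medication: MedicationLedger
    truth: GroundTruth
    provenance: list = field(default_factory=list)

    @property
    def norm_medication(self) -> NormalizedMedication:
        return normalize_medication(self.medication, visits=self.design.visits)

    def tables_by_space(self) -> dict[str, FeatureTable]:
        return {
            "taxa16S": self.taxa_counts,
            "functionalModule": self.module_abundance,
            "immune": self.immune_table,
            "clinical": self.clinical_table,
        }


def _delta_to_latent_shift(delta: float) -> float:
    """Latent-normal shift (in units of the marginal latent SD) producing an
    unpaired Cliff's delta ``delta``.

    For two unit-variance normal samples whose means differ by D,
    delta = 2*Phi(D / sqrt(2)) - 1, inverted here.
    """
    return float(np.sqrt(2.0) * stats.norm.ppf((delta + 1.0) / 2.0))


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:03d}" for i in range(n)]


def simulate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    visits = list(design.visits)
    n_arm = design.n_subjects_per_arm
    subjects = [f"F{i:03d}" for i in range(n_arm)] + [f"D{i:03d}" for i in range(n_arm)]
    arms = ["fasting+DASH"] * n_arm + ["DASH"] * n_arm
    n_sub = len(subjects)
    n_samples = n_sub * len(visits)

    taxa_ids = _feature_ids("taxa", design.n_taxa)
    module_ids = _feature_ids("mod", design.n_modules)
    immune_ids = _feature_ids("imm", design.n_immune)

    # --- resolve planted effects and confounded features -------------------
    id_pool = {"taxa": taxa_ids, "module": module_ids, "immune": immune_ids,
               "clinical": list(LATENT_CLINICAL)}
    per_space: dict[str, list[PlantedEffect]] = {s: [] for s in id_pool}
    for eff in design.planted_effects:
        if eff.feature_id not in id_pool[eff.space]:
            raise ValueError(
                f"planted feature {eff.feature_id!r} does not exist in space {eff.space!r}"
            )
        if eff.visit_of_onset not in visits:
            raise ValueError(f"unknown onset visit {eff.visit_of_onset!r}")
        per_space[eff.space].append(eff)
    for space, effs in per_space.items():
        if len(effs) > len(id_pool[space]):
            raise ValueError(f"more planted effects than features in space {space!r}")
    planted_taxa = {e.feature_id for e in per_space["taxa"]}
    if design.med_confounded_features > design.n_taxa - len(planted_taxa):
        raise ValueError("more confounded features than available taxa")
    confound_pool = [t for t in taxa_ids if t not in planted_taxa]
    confounded = confound_pool[: design.med_confounded_features]

    truth = GroundTruth()
    truth.confounded_features = set(confounded)
    for effs in per_space.values():
        for e in effs:
            truth.differential_features.add(
                (e.feature_id, e.space, e.pattern, int(np.sign(e.target_cliffs_delta)))
            )

    # --- subjects: demographics, responder class, blood pressure ----------
    age = np.clip(rng.normal(60, 8, n_sub), 35, 80).round(0)
    sex = rng.choice(["F", "M"], size=n_sub, p=[0.62, 0.38])
    height = np.clip(rng.normal(171, 8, n_sub), 150, 195).round(1)
    bmi0 = np.clip(rng.normal(33.5, 4.8, n_sub), 25, 48)
    responder = rng.random(n_sub) < design.responder_fraction
    truth.responder_labels = {
        s: ("responder" if r else "non-responder") for s, r in zip(subjects, responder)
    }

    sbp1 = rng.normal(132, 9, n_sub)
    dbp1 = rng.normal(81, 8, n_sub)
    sbp = np.empty((n_sub, 3))
    dbp = np.empty((n_sub, 3))
    bmi = np.empty((n_sub, 3))
    is_fasting = np.array([a == "fasting+DASH" for a in arms])
    for i in range(n_sub):
        sbp[i, 0], dbp[i, 0], bmi[i, 0] = sbp1[i], dbp1[i], bmi0[i]
        acute = rng.normal(-6.0, 3.0) if is_fasting[i] else rng.normal(-1.0, 3.0)
        sbp[i, 1] = sbp1[i] + acute
        dbp[i, 1] = dbp1[i] + 0.5 * acute + rng.normal(0, 2)
        if responder[i]:
            drop = design.responder_sbp_drop_mmhg + rng.normal(0, 2.0)
        else:
            drop = 0.3 + rng.normal(0, 2.0)
        sbp[i, 2] = sbp1[i] - drop
        dbp[i, 2] = dbp1[i] - 0.5 * drop + rng.normal(0, 2)
        # fasting causes a sustained modest BMI/weight reduction
        dbmi = (-1.2, -1.5) if is_fasting[i] else (-0.1, -0.2)
        bmi[i, 1] = bmi0[i] + dbmi[0] + rng.normal(0, 0.2)
        bmi[i, 2] = bmi0[i] + dbmi[1] + rng.normal(0, 0.3)
    map_ = (sbp + 2.0 * dbp) / 3.0
    weight = bmi * (height[:, None] / 100.0) ** 2

    # --- medication ledger --------------------------------------------------
    med_rows = []
    medicated = rng.random(n_sub) < design.medicated_fraction
    drug_choices = ["beta-blockers", "RAS agents", "diuretics", "calcium-channel blockers"]
    reduce_v2 = rng.random(n_sub) < design.med_reduction_v2_fraction
    reduce_v3 = rng.random(n_sub) < 0.5  # responders only, below
    for i, s in enumerate(subjects):
        if not medicated[i]:
            continue
        n_drugs = 1 + int(rng.random() < 0.5)
        drugs = rng.choice(drug_choices, size=n_drugs, replace=False)
        for d_idx, drug_class in enumerate(drugs):
            dose1 = float(rng.choice([2.5, 5.0, 10.0]))
            doses = {visits[0]: dose1, visits[1]: dose1, visits[2]: dose1}
            if d_idx == 0 and reduce_v2[i]:
                doses[visits[1]] = dose1 / 2.0
                doses[visits[2]] = dose1 / 2.0
            if d_idx == 0 and responder[i] and reduce_v3[i]:
                doses[visits[2]] = doses[visits[2]] / 2.0
            for v in visits:
                med_rows.append(
                    {
                        "subject_id": s,
                        "drug_class": drug_class,
                        "drug": f"{drug_class}-{d_idx}",
                        "visit": v,
                        "dose": doses[v],
                    }
                )
    medication = MedicationLedger(
        pd.DataFrame(med_rows, columns=["subject_id", "drug_class", "drug", "visit", "dose"])
    )
    norm_med = normalize_medication(medication, visits=visits)
    # per-subject-visit change in the summed normalized dose from baseline
    agent_delta = np.zeros((n_sub, 3))
    for i, s in enumerate(subjects):
        base = norm_med.agent_sum_at(s, visits[0])
        for v_idx, v in enumerate(visits):
            agent_delta[i, v_idx] = norm_med.agent_sum_at(s, v) - base

    # --- latent feature fields ---------------------------------------------
    rho = design.within_subject_corr
    sigma = design.latent_sigma
    sd_b, sd_e = sigma * np.sqrt(rho), sigma * np.sqrt(1.0 - rho)

    def latent_field(ids: list[str], space: str, mu: np.ndarray) -> np.ndarray:
        """(subject, visit, feature) latent log-abundances with planted shifts."""
        nf = len(ids)
        b = rng.normal(0.0, sd_b, size=(n_sub, 1, nf))
        e = rng.normal(0.0, sd_e, size=(n_sub, 3, nf))
        lat = mu[None, None, :] + b + e
        for eff in per_space[space]:
            j = ids.index(eff.feature_id)
            shift = sigma * _delta_to_latent_shift(eff.target_cliffs_delta)
            onset = visits.index(eff.visit_of_onset)
            affected = [onset] if eff.pattern == "reversible" else list(range(onset, 3))
            for v_idx in affected:
                lat[is_fasting, v_idx, j] += shift
        if space == "taxa" and confounded:
            for t in confounded:
                j = ids.index(t)
                lat[:, :, j] += design.confounder_strength * sigma * agent_delta
        if space == "immune" and design.n_informative_predictors:
            sep = design.informative_separation
            for j in range(min(design.n_informative_predictors, nf)):
                lat[responder, :, j] += sep
                truth.informative_predictors.add(ids[j])
        return lat

    mu_taxa = rng.normal(0.0, 2.0, design.n_taxa)
    for e in per_space["taxa"]:
        mu_taxa[taxa_ids.index(e.feature_id)] = 1.0  # keep planted taxa well measured
    for t in confounded:
        mu_taxa[taxa_ids.index(t)] = 1.0
    lat_taxa = latent_field(taxa_ids, "taxa", mu_taxa)
    lat_mod = latent_field(module_ids, "module", rng.normal(0.0, 1.0, design.n_modules))
    lat_imm = latent_field(immune_ids, "immune", rng.normal(0.0, 1.0, design.n_immune))
    lat_clin = latent_field(
        list(LATENT_CLINICAL), "clinical", np.array([np.log(10.0), np.log(5.5), np.log(130.0), np.log(0.4)])
    )

    # --- assemble sample-level tables ---------------------------------------
    ids = [sample_id(s, v) for s in subjects for v in visits]
    depth = np.maximum(
        rng.lognormal(np.log(design.sequencing_depth_mean), design.depth_sigma, n_samples), 1.0
    ).astype(np.int64)
    probs = np.exp(lat_taxa.reshape(n_samples, design.n_taxa))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, design.n_taxa), dtype=np.int64)
    for r in range(n_samples):
        counts[r] = rng.multinomial(depth[r], probs[r])
    taxa_counts = FeatureTable(
        pd.DataFrame(counts, index=ids, columns=taxa_ids), space="taxa16S", unit="counts"
    )
    module_abundance = FeatureTable(
        pd.DataFrame(np.exp(lat_mod.reshape(n_samples, design.n_modules)), index=ids, columns=module_ids),
        space="functionalModule",
        unit="relative",
    )
    immune_table = FeatureTable(
        pd.DataFrame(np.exp(lat_imm.reshape(n_samples, design.n_immune)), index=ids, columns=immune_ids),
        space="immune",
        unit="relative",
    )

    meta_rows = []
    clin_rows = []
    labs = np.exp(lat_clin.reshape(n_samples, len(LATENT_CLINICAL)))
    r = 0
    for i, s in enumerate(subjects):
        for v_idx, v in enumerate(visits):
            insulin, glucose, ldl, crp = labs[r]
            homa = insulin * glucose / 22.5
            meta_rows.append(
                {
                    "subject_id": s,
                    "arm": arms[i],
                    "visit": v,
                    "age": age[i],
                    "sex": sex[i],
                    "weight": round(float(weight[i, v_idx]), 6),
                    "height": float(height[i]),
                    "bmi": round(float(weight[i, v_idx]), 6) / (float(height[i]) / 100.0) ** 2,
                    "sbp_24h": float(sbp[i, v_idx]),
                    "dbp_24h": float(dbp[i, v_idx]),
                    "map_24h": float(map_[i, v_idx]),
                    "insulin": float(insulin),
                    "glucose": float(glucose),
                    "homa": float(homa),
                }
            )
            clin_rows.append(
                {
                    "sbp_24h": float(sbp[i, v_idx]),
                    "dbp_24h": float(dbp[i, v_idx]),
                    "map_24h": float(map_[i, v_idx]),
                    "bmi": meta_rows[-1]["bmi"],
                    "weight": meta_rows[-1]["weight"],
                    "insulin": float(insulin),
                    "glucose": float(glucose),
                    "homa": float(homa),
                    "ldl": float(ldl),
                    "crp": float(crp),
                }
            )
            r += 1
    metadata = pd.DataFrame(
        meta_rows,
        columns=[
            "subject_id", "arm", "visit", "age", "sex", "weight", "height",
            "bmi", "sbp_24h", "dbp_24h", "map_24h", "insulin", "glucose", "homa",
        ],
    )
    clinical_table = FeatureTable(
        pd.DataFrame(clin_rows, index=ids, columns=list(CLINICAL_FEATURES)),
        space="clinical",
        unit="absolute",
    )

    return SyntheticCohort(
        design=design,
        metadata=metadata,
        taxa_counts=taxa_counts,
        module_abundance=module_abundance,
        immune_table=immune_table,
        clinical_table=clinical_table,
        medication=medication,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Triplet planting
# ---------------------------------------------------------------------------


def _equicorrelated_z(rng: np.random.Generator, n: int, r: float) -> np.ndarray:
    """Three jointly standard-normal columns with pairwise correlation r.

    Positive r uses a shared factor; negative r uses partial centering of
    three independent draws. An equicorrelation below -1/2 is not a valid
    correlation structure for three variables, so negative targets are
    clipped to -0.49.
    """
    if r >= 0:
        f = rng.normal(size=(n, 1))
        e = rng.normal(size=(n, 3))
        z = np.sqrt(r) * f + np.sqrt(1.0 - r) * e
    else:
        r = max(r, -0.49)
        c = 1.0 - np.sqrt(1.0 + 3.0 * r / (1.0 - r))
        e = rng.normal(size=(n, 3))
        z = e - c * e.mean(axis=1, keepdims=True)
        z /= np.sqrt(1.0 - 2.0 * c / 3.0 + c**2 / 3.0)
    return z


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``."""
    if values.sum() <= 0:
        out = np.zeros(len(values), dtype=np.int64)
        out[: int(total)] = 1  # degenerate: spread one unit each
        return out
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(np.int64)
    short = int(total - floors.sum())
    if short > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def plant_triplet(
    cohort: SyntheticCohort,
    rho_target: float,
    ids: tuple[str, str, str],
) -> SyntheticCohort:
    """Overwrite three features (clinical, immune, taxon) with correlated values.

    Each pair's pooled Spearman correlation approaches ``rho_target``
    (negative targets are bounded at -0.49, the equicorrelation limit for
    three variables). The new values preserve each feature's location and
    scale on the log axis; for the taxon, the remaining taxa in each sample
    are rescaled (largest-remainder rounding) so row sums still equal the
    sampled depths exactly. The planted triplet is recorded in the ground
    truth (a zero target only logs provenance).
    """
    clin_id, imm_id, mic_id = ids
    if clin_id not in cohort.clinical_table.data.columns:
        raise ValueError(f"{clin_id!r} is not a clinical feature")
    if imm_id not in cohort.immune_table.data.columns:
        raise ValueError(f"{imm_id!r} is not an immune feature")
    if mic_id not in cohort.taxa_counts.data.columns:
        raise ValueError(f"{mic_id!r} is not a taxon")
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    tag = zlib.crc32(("triplet:" + ":".join(ids)).encode())
    rng = np.random.default_rng(np.random.SeedSequence([cohort.design.seed, tag]))
    n = len(cohort.clinical_table.data)
    z = _equicorrelated_z(rng, n, rho_target)

    def remap_log(col: pd.Series, zcol: np.ndarray, floor: float = 1e-9) -> np.ndarray:
        logs = np.log(np.maximum(col.to_numpy(dtype=float), floor))
        mu, sd = logs.mean(), max(logs.std(), 0.25)
        return np.exp(mu + sd * zcol)

    cohort.clinical_table.data[clin_id] = remap_log(cohort.clinical_table.data[clin_id], z[:, 0])
    cohort.immune_table.data[imm_id] = remap_log(cohort.immune_table.data[imm_id], z[:, 1])

    counts = cohort.taxa_counts.data
    depths = counts.to_numpy().sum(axis=1)
    # rebuild the taxon at a moderate relative abundance (median 0.5% of the
    # library, log-sd 0.8) so re-closing the remaining taxa perturbs them only
    # marginally (no induced community-wide anticorrelation); the 5% cap keeps
    # extreme draws from dominating a sample
    new_target = np.round(0.005 * depths * np.exp(0.8 * z[:, 2] - 0.32)).astype(np.int64)
    new_target = np.minimum(new_target, (0.05 * depths).astype(np.int64))
    others = [c for c in counts.columns if c != mic_id]
    other_block = counts[others].to_numpy()
    for r in range(n):
        remaining = int(depths[r] - new_target[r])
        other_block[r] = _largest_remainder(other_block[r].astype(float), remaining)
    counts.loc[:, others] = other_block
    counts[mic_id] = new_target

    cohort.provenance.append({"op": "plant_triplet", "ids": list(ids), "rho": rho_target})
    if rho_target != 0:
        cohort.truth.planted_triplets.append(tuple(ids))
    return cohort


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_FILES = {
    "taxa_counts.tsv": ("taxa_counts", "taxa16S", "counts"),
    "modules.tsv": ("module_abundance", "functionalModule", "relative"),
    "immune.tsv": ("immune_table", "immune", "relative"),
    "clinical.tsv": ("clinical_table", "clinical", "absolute"),
}


def export_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write the cohort as the package's TSV file set (plus truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    write_metadata(cohort.metadata, directory / "metadata.tsv")
    written.append(directory / "metadata.tsv")
    for fname, (attr, _, _) in _FILES.items():
        write_feature_table(getattr(cohort, attr), directory / fname)
        written.append(directory / fname)
    write_medication(cohort.medication, directory / "medication.tsv")
    written.append(directory / "medication.tsv")
    truth = {
        "differential_features": sorted(map(list, cohort.truth.differential_features)),
        "confounded_features": sorted(cohort.truth.confounded_features),
        "planted_triplets": [list(t) for t in cohort.truth.planted_triplets],
        "responder_labels": cohort.truth.responder_labels,
        "informative_predictors": sorted(cohort.truth.informative_predictors),
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    written.append(directory / "truth.json")
    return written


def import_cohort(directory: str | Path, design: CohortDesign | None = None) -> SyntheticCohort:
    """Read back an exported cohort; inverse of :func:`export_cohort`."""
    directory = Path(directory)
    metadata = read_metadata(directory / "metadata.tsv")
    tables = {}
    for fname, (attr, space, unit) in _FILES.items():
        tables[attr] = read_feature_table(directory / fname, space=space, unit=unit)
    medication = read_medication(directory / "medication.tsv")
    truth_raw = json.loads((directory / "truth.json").read_text())
    truth = GroundTruth(
        differential_features={tuple(t) for t in truth_raw["differential_features"]},
        confounded_features=set(truth_raw["confounded_features"]),
        planted_triplets=[tuple(t) for t in truth_raw["planted_triplets"]],
        responder_labels=truth_raw["responder_labels"],
        informative_predictors=set(truth_raw["informative_predictors"]),
    )
    return SyntheticCohort(
        design=design or CohortDesign(),
        metadata=metadata,
        medication=medication,
        truth=truth,
        **tables,
    )


# ---------------------------------------------------------------------------
# Flat prediction testbeds
# ---------------------------------------------------------------------------


def simulate_prediction_dataset(
    n_subjects: int = 32,
    n_features: int = 494,
    n_informative: int = 0,
    separation: float = 1.5,
    responder_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-row-per-subject feature matrix with optional informative columns.

    The first ``n_informative`` features carry a standardized between-class
    mean separation of ``separation`` (difference of class means in
    within-class SD units); the rest are pure noise. Exactly
    ``round(responder_fraction * n_subjects)`` subjects are positive, in a
    shuffled order, so benchmark power is not confounded with random
    class-imbalance variation. Used to probe the leave-one-subject-out
    pipeline for leakage (null data must score at chance) and power (planted
    data must be learnable).
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(responder_fraction * n_subjects))
    y = np.zeros(n_subjects, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    X = rng.normal(size=(n_subjects, n_features))
    X[:, :n_informative] += (y[:, None] - 0.5) * separation
    names = [f"feat_{j:04d}" for j in range(n_features)]
    return X, y, names
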