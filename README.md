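# refeedomics

Statistical tooling for longitudinal multi-omics intervention studies of the
fasting/refeeding type: a cohort is sampled at baseline (V1), one week after
an intervention (V2) and at three-month follow-up (V3) across several
measurement spaces — microbial taxa (16S or shotgun counts), gene-functional
modules, immune-cell populations and clinical phenotypes — while
antihypertensive medication changes threaten to confound every
visit-associated signal. The package is aimed at analysts of such cohorts
who need the full chain from raw tables to subject-level response
prediction, with the medication deconfounding and repeated-measures guards
built in rather than bolted on.

## What it implements

* **Preprocessing** (`refeedomics.io`): TSV data model keyed by
  `subject:visit`; rarefaction without replacement (auto depth =
  `floor(0.95 × smallest library)`); KO→module mean-binning and taxonomic
  sum-rollup; antihypertensive dose normalization (baseline dose → 1,
  discontinued → 0, per-visit agent sums) and per-subject medication change
  classification; BMI and HOMA (= insulin × glucose / 22.5).
* **Diversity & ordination** (`refeedomics.diversity`): richness, Shannon,
  evenness, Simpson, inverse Simpson, bias-corrected Chao1; Bray–Curtis and
  Euclidean distances; PCoA; and PERMANOVA with permutations restricted to
  within-donor strata — the repeated-measures-correct multivariate test.
* **Longitudinal screening** (`refeedomics.contrasts`): per feature, a
  nested linear-model likelihood-ratio test of a visit effect with age, sex,
  patient identity and normalized drug doses as covariates (BH within
  measurement space, FDR < 0.1), gated by post-hoc Mann–Whitney U contrasts
  between visit pairs (BH across the three contrasts, FDR < 0.05), with
  signed Cliff's delta effect sizes throughout and a BMI sensitivity
  re-screen.
* **Cross-space networks** (`refeedomics.network`): pooled Spearman
  screening between spaces, a same-donor mixed-model post-hoc that rejects
  pseudo-replicated (between-subject-only) correlations, and assembly of
  clinical–immune–microbiome triplets (≥ 2 robust edges, ≥ 1
  intervention-affected member).
* **Response prediction** (`refeedomics.predict`): medication-adjusted
  responder stratification from ambulatory SBP change; leave-one-subject-out
  cross-validation in which z-scaling, forward-stepwise selection and the
  no-intercept ridge-logistic fit (C = 1) are all computed inside each
  training fold; cross-cohort transfer of a single trained model.
* **Synthetic cohorts** (`refeedomics.simulate`): a generator with
  compositional counts, within-subject correlation, planted
  reversible/sustained effects calibrated to target Cliff's deltas,
  medication-confounded features, planted correlation triplets and a
  responder mixture — with exact ground truth for scoring every stage.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import refeedomics as r
from refeedomics.io import FeatureTable, sample_id
from refeedomics.contrasts import significant_features
from refeedomics.diversity import beta_distance, permanova_stratified

design = r.CohortDesign(
    n_subjects_per_arm=35, n_taxa=200, n_modules=20, n_immune=20,
    med_confounded_features=10,
    planted_effects=[r.PlantedEffect(f"taxa_{i:03d}", "taxa", "reversible", 0.6)
                     for i in range(8)],
    seed=7,
)
cohort = r.simulate_cohort(design)

meta = cohort.metadata[cohort.metadata["arm"] == "fasting+DASH"].reset_index(drop=True)
keep = [sample_id(s, v) for s, v in zip(meta["subject_id"], meta["visit"])]
taxa = FeatureTable(cohort.taxa_counts.data.loc[keep], space="taxa16S", unit="counts")

rarefied = r.rarefy_table(taxa, depth="auto", seed=7)
results = r.run_contrast_screen([rarefied], meta, cohort.norm_medication)
sig = {f for _, f in significant_features(results)}

dist = beta_distance(rarefied, "bray-curtis")
perm = permanova_stratified(dist, meta["visit"], meta["subject_id"], 999, seed=7)
labels = r.stratify_responders(cohort.metadata, cohort.norm_medication)
```

Output for this seed:

```
rarefied depth: 10072
significant features: 8 | planted recovered: 8 / 8
taxa_000 fasting contrast: delta=0.530 q_lrt=0.0001 q_mwu=0.0002
responders: 49 of 70
PERMANOVA pseudo-F=0.97 p=0.005
```

All eight planted reversible effects (target Cliff's delta 0.6) pass both
screening gates with no false positives — the ten medication-confounded taxa
are screened out because the dose covariates absorb their apparent visit
effect. The recovered effect size (0.53) sits slightly below the latent
target, the expected attenuation from multinomial counting noise. The
donor-stratified PERMANOVA detects the community-level shift at p = 0.005
even though the pseudo-F is unremarkable: permuting visits only within
subjects makes the null distribution tight. The stratification rule labels
49 of 70 subjects responders (the generator's responder fraction is 22/32
with an 8 mmHg sustained SBP drop).

A thin CLI mirrors the library (`refeedomics simulate|validate|rarefy|
diversity|contrast|predict`); run `refeedomics --help`.

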