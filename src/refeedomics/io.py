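"""Tabular data model and preprocessing for longitudinal multi-omics cohorts.

The data model mirrors a three-visit (V1 baseline, V2 post-intervention,
V3 follow-up) two-arm intervention study: per-sample feature tables for
microbial taxa, gene-functional modules, immune-cell populations and clinical
phenotypes, a sample-metadata table, and a long-format medication ledger.
Samples are keyed by the composite id ``subject_id + ":" + visit``.

Preprocessing implemented here:

* rarefaction of count tables (without-replacement subsampling to a common
  depth, auto depth = ``floor(0.95 * smallest library)``),
* feature binning (mean for KO -> functional module, sum for taxonomic
  rollup),
* antihypertensive dose normalization (baseline-referenced, with per-visit
  agent sums) and per-subject medication change classification,
* HOMA insulin-resistance index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VISITS = ("V1", "V2", "V3")

#: measurement spaces a feature table can be tagged with
SPACES = ("taxa16S", "taxaShotgun", "functionalModule", "immune", "clinical")

UNITS = ("counts", "relative", "absolute")

DRUG_CLASSES = (
    "diuretics",
    "beta-blockers",
    "calcium-channel blockers",
    "RAS agents",
    "other antihypertensives",
)


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


def sample_id(subject_id: str, visit: str) -> str:
    """Composite sample key used to align all tables."""
    return f"{subject_id}:{visit}"


def split_sample_id(sid: str) -> tuple[str, str]:
    subject, _, visit = sid.rpartition(":")
    return subject, visit


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """A samples x features matrix tagged with measurement space and unit.

    ``data`` is a DataFrame indexed by sample id with one column per feature.
    Counts and relative abundances must be non-negative.
    """

    data: pd.DataFrame
    space: str
    unit: str

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {SPACES}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        self.validate()

    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.unit in ("counts", "relative") and len(self.data):
            values = self.data.to_numpy()
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative value at sample {self.data.index[r]!r}, "
                    f"feature {self.data.columns[c]!r} for unit {self.unit!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.space == other.space
            and self.unit == other.unit
            and self.data.equals(other.data)
        )


def read_feature_table(path: str | Path, space: str, unit: str) -> FeatureTable:
    """Read a TSV feature table (first column sample ids, header feature ids)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = [name for i, name in enumerate(header) if name in header[:i]]
    if dupes:
        raise FormatError(f"duplicate feature ids in {path}: {sorted(set(dupes))}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"malformed table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return FeatureTable(df, space=space, unit=unit)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "subject_id",
    "arm",
    "visit",
    "age",
    "sex",
    "weight",
    "height",
    "bmi",
    "sbp_24h",
    "dbp_24h",
    "map_24h",
]

ARMS = ("fasting+DASH", "DASH")


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index: weight in kg divided by squared height in meters."""
    return weight_kg / (height_cm / 100.0) ** 2


def compute_homa(insulin: float, glucose: float) -> float:
    """HOMA insulin-resistance index: insulin (uU/ml) * glucose (mmol/l) / 22.5."""
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(insulin < 0) or np.any(glucose < 0):
        raise ValueError("insulin and glucose must be non-negative")
    out = insulin * glucose / 22.5
    return float(out) if out.ndim == 0 else out


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check metadata invariants; returns the (indexed) table.

    One row per (subject, visit); arm constant within subject; BMI consistent
    with weight/height where all three are present.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    dup = meta.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        raise FormatError(
            f"duplicate (subject, visit) rows: "
            f"{meta.loc[dup, ['subject_id', 'visit']].to_records(index=False).tolist()}"
        )
    arms_per_subject = meta.groupby("subject_id")["arm"].nunique()
    bad = arms_per_subject[arms_per_subject > 1]
    if len(bad):
        raise FormatError(f"arm not constant within subject(s): {list(bad.index)}")
    complete = meta[["bmi", "weight", "height"]].notna().all(axis=1)
    if complete.any():
        expect = compute_bmi(
            meta.loc[complete, "weight"].astype(float),
            meta.loc[complete, "height"].astype(float),
        )
        if not np.allclose(meta.loc[complete, "bmi"].astype(float), expect, atol=1e-9):
            raise FormatError("bmi inconsistent with weight/height")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(Path(path), sep="\t", dtype={"subject_id": str, "visit": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Medication ledger and dose normalization
# ---------------------------------------------------------------------------

MEDICATION_COLUMNS = ["subject_id", "drug_class", "drug", "visit", "dose"]


@dataclass
class MedicationLedger:
    """Long-format per-subject per-drug doses across visits."""

    records: pd.DataFrame  # columns MEDICATION_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in MEDICATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"medication ledger missing columns: {missing}")
        if len(self.records):
            if (self.records["dose"] < 0).any():
                raise FormatError("negative dose in medication ledger")
            dup = self.records.duplicated(subset=["subject_id", "drug_class", "drug", "visit"])
            if dup.any():
                raise FormatError(
                    "duplicate (subject, drug_class, drug, visit) records: "
                    f"{self.records.loc[dup].to_records(index=False).tolist()}"
                )

    def __eq__(self, other: object) -> bool:  # pragma: no cover
        if not isinstance(other, MedicationLedger):
            return NotImplemented
        return self.records.equals(other.records)


@dataclass
class NormalizedMedication:
    """Baseline-referenced doses and per-visit agent sums.

    ``normalized`` has columns subject_id/drug_class/drug/visit/normalized_dose;
    ``agent_sum`` has columns subject_id/visit/agent_sum. An unchanged regimen
    normalizes to exactly 1 at every visit; a discontinued drug to 0.
    """

    normalized: pd.DataFrame
    agent_sum: pd.DataFrame

    def agent_sum_at(self, subject_id: str, visit: str) -> float:
        mask = (self.agent_sum["subject_id"] == subject_id) & (
            self.agent_sum["visit"] == visit
        )
        rows = self.agent_sum.loc[mask, "agent_sum"]
        return float(rows.iloc[0]) if len(rows) else 0.0


def read_medication(path: str | Path) -> MedicationLedger:
    rec = pd.read_csv(
        Path(path), sep="\t", dtype={"subject_id": str, "drug": str, "visit": str}
    )
    return MedicationLedger(rec)


def write_medication(ledger: MedicationLedger, path: str | Path) -> None:
    ledger.records.to_csv(Path(path), sep="\t", index=False)


def normalize_medication(
    ledger: MedicationLedger,
    visits: Iterable[str] = VISITS,
    baseline: str = "V1",
    mode: str = "dose-sum",
) -> NormalizedMedication:
    """Normalize each (subject, drug) dose trajectory to its reference dose.

    The reference is the baseline dose when nonzero, otherwise the lowest
    nonzero dose across visits (covers drugs initiated mid-study). Normalized
    dose is dose/reference, hence exactly 1 for an unchanged regimen and 0 for
    a discontinued drug. The per-visit agent sum is, in ``mode="dose-sum"``
    (default), the sum of normalized doses over drugs; in ``mode="agent-count"``
    it counts the drugs with a nonzero dose at that visit.

    Drugs with an all-zero trajectory are dropped with a warning.
    """
    if mode not in ("dose-sum", "agent-count"):
        raise ValueError(f"unknown mode {mode!r}")
    visits = list(visits)
    rec = ledger.records
    out_rows: list[dict] = []
    subjects = rec["subject_id"].unique() if len(rec) else []
    for (subject, drug_class, drug), grp in (
        rec.groupby(["subject_id", "drug_class", "drug"], sort=True) if len(rec) else []
    ):
        doses = {v: 0.0 for v in visits}
        doses.update(dict(zip(grp["visit"], grp["dose"].astype(float))))
        base = doses.get(baseline, 0.0)
        nonzero = [d for d in doses.values() if d > 0]
        if not nonzero:
            logger.warning(
                "dropping all-zero dose trajectory for subject %s drug %s", subject, drug
            )
            continue
        reference = base if base > 0 else min(nonzero)
        for v in visits:
            out_rows.append(
                {
                    "subject_id": subject,
                    "drug_class": drug_class,
                    "drug": drug,
                    "visit": v,
                    "normalized_dose": doses[v] / reference,
                }
            )
    normalized = pd.DataFrame(
        out_rows,
        columns=["subject_id", "drug_class", "drug", "visit", "normalized_dose"],
    )
    sums: list[dict] = []
    for subject in subjects:
        sub = normalized[normalized["subject_id"] == subject]
        for v in visits:
            at = sub[sub["visit"] == v]
            if mode == "dose-sum":
                total = float(at["normalized_dose"].sum())
            else:
                total = float((at["normalized_dose"] > 0).sum())
            sums.append({"subject_id": subject, "visit": v, "agent_sum": total})
    agent_sum = pd.DataFrame(sums, columns=["subject_id", "visit", "agent_sum"])
    return NormalizedMedication(normalized=normalized, agent_sum=agent_sum)


def medication_change_class(
    norm: NormalizedMedication,
    from_visit: str = "V1",
    to_visit: str = "V3",
    subjects: Iterable[str] | None = None,
    tol: float = 1e-9,
) -> pd.Series:
    """Classify each subject's medication change between two visits.

    Returns a Series (index subject_id) with values ``reduced`` / ``unchanged``
    / ``increased`` by the sign of the agent-sum difference. Subjects with no
    ledger entries are ``unchanged`` (agent sum 0 at both visits).
    """
    if subjects is None:
        subjects = sorted(norm.agent_sum["subject_id"].unique())
    out = {}
    for s in subjects:
        delta = norm.agent_sum_at(s, to_visit) - norm.agent_sum_at(s, from_visit)
        if delta < -tol:
            out[s] = "reduced"
        elif delta > tol:
            out[s] = "increased"
        else:
            out[s] = "unchanged"
    return pd.Series(out, name="medication_change", dtype=object)


def dose_covariates(
    norm: NormalizedMedication, meta: pd.DataFrame, by: str = "drug_class"
) -> pd.DataFrame:
    """Per-sample normalized-dose covariate matrix for the contrast models.

    One column per drug (or drug class, default), one row per sample in
    ``meta`` (keyed subject:visit); subjects without a record get dose 0.
    """
    index = [sample_id(s, v) for s, v in zip(meta["subject_id"], meta["visit"])]
    if not len(norm.normalized):
        return pd.DataFrame(index=index)
    wide = (
        norm.normalized.groupby(["subject_id", "visit", by])["normalized_dose"]
        .sum()
        .unstack(by, fill_value=0.0)
    )
    cols = list(wide.columns)
    rows = np.zeros((len(index), len(cols)))
    lookup = {k: i for i, k in enumerate(wide.index)}
    for i, (s, v) in enumerate(zip(meta["subject_id"], meta["visit"])):
        j = lookup.get((s, v))
        if j is not None:
            rows[i] = wide.to_numpy()[j]
    return pd.DataFrame(rows, index=index, columns=[f"dose_{c}" for c in cols])


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy_table(
    table: FeatureTable,
    depth: int | str = "auto",
    seed: int | np.random.Generator = 0,
    on_shallow: str = "drop",
) -> FeatureTable:
    """Subsample each sample's counts without replacement to a common depth.

    ``depth="auto"`` uses ``floor(0.95 * smallest row sum)``. Sampling is
    multivariate hypergeometric (without replacement), so every rarefied count
    is bounded by the original and row sums equal ``depth`` exactly. Samples
    shallower than ``depth`` are dropped with a warning (``on_shallow="drop"``)
    or raise (``on_shallow="error"``).
    """
    if table.unit != "counts":
        raise ValueError("rarefaction requires a count table")
    values = table.values
    if not np.allclose(values, np.round(values)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(values).astype(np.int64)
    row_sums = counts.sum(axis=1)
    if len(counts) == 0:
        return FeatureTable(table.data.copy(), space=table.space, unit="counts")
    if depth == "auto":
        depth = int(math.floor(0.95 * row_sums.min()))
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"non-positive rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep: list[int] = []
    out_rows: list[np.ndarray] = []
    for i, row in enumerate(counts):
        total = row_sums[i]
        if total < depth:
            msg = (
                f"sample {table.data.index[i]!r} has {total} < depth {depth} reads"
            )
            if on_shallow == "error":
                raise ValueError(msg)
            logger.warning("dropping %s", msg)
            continue
        keep.append(i)
        if total == depth:
            out_rows.append(row.copy())
        else:
            out_rows.append(rng.multivariate_hypergeometric(row, depth))
    data = pd.DataFrame(
        np.asarray(out_rows, dtype=np.int64).reshape(len(keep), counts.shape[1]),
        index=table.data.index[keep],
        columns=table.data.columns,
    )
    return FeatureTable(data, space=table.space, unit="counts")


# ---------------------------------------------------------------------------
# Feature binning
# ---------------------------------------------------------------------------


def bin_features(
    table: FeatureTable,
    mapping: Mapping[str, str],
    method: str = "mean",
    space: str | None = None,
) -> FeatureTable:
    """Bin features into groups (KO -> module, or taxonomic rollup).

    ``mapping`` maps member feature id -> group id; features outside the
    mapping are ignored. ``method="mean"`` averages over *all* mapped members
    of a group (members absent from the table contribute 0, matching
    gene-family averaging into modules); ``method="sum"`` sums the members
    present (taxonomic rollup). Groups with no member present are excluded
    with a warning under ``sum``; under ``mean`` they are excluded only if no
    member exists in the mapping.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown binning method {method!r}")
    groups: dict[str, list[str]] = {}
    for feat, grp in mapping.items():
        groups.setdefault(grp, []).append(feat)
    cols = {}
    for grp in sorted(groups):
        members = groups[grp]
        present = [m for m in members if m in table.data.columns]
        if not present:
            logger.warning("group %r has no member present in table; excluded", grp)
            continue
        block = table.data[present].to_numpy()
        if method == "mean":
            cols[grp] = block.sum(axis=1) / len(members)
        else:
            cols[grp] = block.sum(axis=1)
    data = pd.DataFrame(cols, index=table.data.index)
    unit = table.unit if method == "sum" else ("relative" if table.unit == "counts" else table.unit)
    return FeatureTable(data, space=space or table.space, unit=unit)
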