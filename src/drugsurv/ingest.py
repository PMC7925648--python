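"""Reading cohort tables and assembling cancer-drug patient groups.

The analysis consumes three patient-level tables: a genes x samples
expression matrix (FPKM-UQ-like non-negative values on disk), a clinical
table carrying vital status and follow-up, and a drug-exposure table with
free-text drug names.  This module reads them, log-transforms expression,
standardizes drug names against a curated synonym map, extracts
right-censored overall-survival records, and builds the cancer-drug patient
groups on which every downstream test runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, UsageError

logger = logging.getLogger(__name__)

#: Vital-status spellings treated as a death record (case-insensitive).
DEAD_STATUSES = frozenset({"dead", "deceased"})

DEFAULT_MIN_GROUP_SIZE = 20


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``scale`` is ``"linear"`` for raw FPKM-UQ-like values (all >= 0) and
    ``"log"`` after the log2(x+1) transform.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.scale not in ("linear", "log"):
            raise ConfigError(f"unknown scale tag: {self.scale!r}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise FormatError("linear-scale expression contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient right-censored time-to-event: days observed and whether
    the event (death) occurred at that time."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise UsageError(
                f"survival time must be finite and positive, got {self.time} "
                f"for patient {self.patient_id!r}"
            )


@dataclass
class PatientGroup:
    """All patients of one cancer type exposed to one canonical drug."""

    cancer: str
    drug: str
    patient_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def size(self) -> int:
        return len(self.patient_ids)


def read_expression_table(path, skip_header_lines: int = 0) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table (first column gene id,
    header row of sample ids) into a linear-scale :class:`ExpressionMatrix`.

    ``skip_header_lines`` drops that many preamble lines before the header
    row — the extent of BCR-Biotab-style dialect support.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         skiprows=skip_header_lines)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"expression file has no data cells: {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric or missing expression value at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere((numeric < 0).to_numpy())[0]
        raise FormatError(
            f"negative linear expression at gene {numeric.index[r]!r}, "
            f"sample {numeric.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(values=numeric, scale="linear")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform, the transcriptomics convention that maps 0 to 0
    and tames the heavy right tail of FPKM-UQ values."""
    if matrix.scale != "linear":
        raise UsageError("matrix is already log scale")
    return ExpressionMatrix(values=np.log2(matrix.values + 1.0), scale="log")


def _normalize_raw(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def standardize_drug_names(
    exposures: pd.DataFrame, synonym_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Map free-text drug names to canonical names.

    ``synonym_map`` maps raw names (matched case-insensitively after
    whitespace normalization) to canonical names.  Unmapped names fall back
    to the lower-cased, trimmed raw name, so a partial map degrades
    gracefully instead of erroring.  Returns a copy of ``exposures`` with a
    ``drug`` column of canonical names (raw name preserved in
    ``drug_name``).
    """
    synonym_map = synonym_map or {}
    lowered: dict[str, str] = {}
    for raw, canonical in synonym_map.items():
        key = _normalize_raw(raw)
        canon = _normalize_raw(canonical)
        if key in lowered and lowered[key] != canon:
            raise ConfigError(
                f"conflicting synonym map entries for {key!r}: "
                f"{lowered[key]!r} vs {canon!r}"
            )
        lowered[key] = canon
    out = exposures.copy()
    out["drug"] = [
        lowered.get(_normalize_raw(n), _normalize_raw(n)) for n in out["drug_name"]
    ]
    return out


def read_synonym_map(path) -> dict[str, str]:
    """Read a two-column (raw, canonical) tab-separated synonym table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"raw", "canonical"} <= set(df.columns):
        raise FormatError("synonym map needs 'raw' and 'canonical' columns")
    return dict(zip(df["raw"], df["canonical"]))


def extract_survival(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    """Build overall-survival records from a clinical table.

    Deceased patients (vital status in :data:`DEAD_STATUSES`) with a positive
    days-to-death become events; everyone else with a positive
    days-to-last-follow-up is censored at that time.  Deceased patients
    missing days-to-death are dropped (imputing an event time from follow-up
    would fabricate data), as are rows with no usable positive time; drop
    counts are logged.
    """
    records: list[SurvivalRecord] = []
    dropped = 0
    for row in clinical.itertuples(index=False):
        pid = str(row.patient_id)
        status = str(row.vital_status).strip().lower()
        death = pd.to_numeric(getattr(row, "days_to_death", None), errors="coerce")
        follow = pd.to_numeric(
            getattr(row, "days_to_last_followup", None), errors="coerce"
        )
        if status in DEAD_STATUSES:
            if pd.notna(death) and death > 0:
                records.append(SurvivalRecord(pid, float(death), True))
            else:
                dropped += 1
        elif pd.notna(follow) and follow > 0:
            records.append(SurvivalRecord(pid, float(follow), False))
        else:
            dropped += 1
    if dropped:
        logger.warning("extract_survival: dropped %d rows with no usable time", dropped)
    return records


def build_patient_groups(
    clinical: pd.DataFrame,
    exposures: pd.DataFrame,
    expression: ExpressionMatrix,
    survival: list[SurvivalRecord] | None = None,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> list[PatientGroup]:
    """One group per (cancer, canonical drug) pair with at least
    ``min_group_size`` patients having expression, survival, and that
    exposure.  A patient on k distinct drugs lands in k groups; duplicate
    exposure rows collapse.  Output is sorted for determinism.
    """
    if "drug" not in exposures.columns:
        raise UsageError("exposures must be standardized first (missing 'drug')")
    if survival is None:
        survival = extract_survival(clinical)
    with_surv = {r.patient_id for r in survival}
    with_expr = set(expression.sample_ids)
    cancer_of = dict(
        zip(clinical["patient_id"].astype(str), clinical["cancer"].astype(str))
    )
    eligible = with_surv & with_expr & set(cancer_of)
    dropped = (with_surv | with_expr | set(cancer_of)) - eligible
    if dropped:
        logger.info(
            "build_patient_groups: %d patients absent from at least one input "
            "excluded: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    members: dict[tuple[str, str], set[str]] = {}
    for pid, drug in zip(exposures["patient_id"].astype(str), exposures["drug"]):
        if pid not in eligible:
            continue
        members.setdefault((cancer_of[pid], drug), set()).add(pid)
    groups = [
        PatientGroup(cancer, drug, frozenset(pids))
        for (cancer, drug), pids in members.items()
        if len(pids) >= min_group_size
    ]
    groups.sort(key=lambda g: (g.cancer, g.drug))
    return groups
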