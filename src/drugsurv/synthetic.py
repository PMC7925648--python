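"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants exactly the features the pipeline is built to find:

* per-gene bimodal log2-scale expression, where each patient's mixture
  component is a latent binary high/low state;
* "signal" genes whose latent high state multiplies the patient's death
  hazard (exponential event times, independent exponential censoring);
* co-expression blocks sharing a latent patient factor (each member gene
  copies the factor with a small flip probability), optionally driving the
  hazard through that factor so block members are survival-associated;
* clinical and drug-exposure tables with messy raw drug-name variants,
  multi-drug patients, and duplicate exposure rows.

Every latent quantity is returned as ground truth so downstream recovery
(threshold placement, screen hits, community membership) can be scored
exactly.  Output expression is linear scale (2**y - 1, floored at 0) so the
ingest log2(x+1) transform is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import ExpressionMatrix, SurvivalRecord

#: Default drug list: (canonical name, raw variants seen in exposure rows).
DEFAULT_DRUG_NAMES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("cisplatin", ("Cisplatin", "CISPLATIN", "cis-platin")),
    ("paclitaxel", ("Taxol", "PACLITAXEL", "paclitaxel ")),
)
DEFAULT_CANCER_LABELS: tuple[str, ...] = ("LUAD", "BRCA")


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults describe a mid-size cohort: 200 patients, 500 genes of which
    5 independent signal genes and 2 blocks of 20 co-expressed genes carry
    a hazard ratio of 3 through their latent states; mixture components at
    log2 means 2 and 8 (sd 0.5); baseline hazard 1e-3 events/day with
    censoring hazard 5e-4/day (about two thirds of patients die on study).
    """

    n_patients: int = 200
    n_genes: int = 500
    n_signal_genes: int = 5
    signal_hazard_ratio: float = 3.0
    n_blocks: int = 2
    block_size: int = 20
    block_hazard_ratio: float = 3.0
    block_flip_prob: float = 0.05
    bimodal_fraction: float = 0.5
    low_mean: float = 2.0
    high_mean: float = 8.0
    component_sd: float = 0.5
    baseline_hazard: float = 1e-3
    censor_rate: float = 5e-4
    duplicate_row_prob: float = 0.1
    extra_drug_prob: float = 0.3
    drug_names: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_DRUG_NAMES
    cancer_labels: tuple[str, ...] = DEFAULT_CANCER_LABELS
    seed: int = 0

    def validate(self) -> None:
        def positive(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

        for name in ("n_patients", "n_genes", "signal_hazard_ratio",
                     "block_hazard_ratio", "component_sd", "baseline_hazard"):
            positive(name)
        for name in ("n_signal_genes", "n_blocks", "block_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("censor_rate", "duplicate_row_prob", "extra_drug_prob"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.bimodal_fraction <= 1.0:
            raise ConfigError("bimodal_fraction must be in [0, 1]")
        if not 0.0 <= self.block_flip_prob <= 1.0:
            raise ConfigError("block_flip_prob must be in [0, 1]")
        if self.n_signal_genes > self.n_genes:
            raise ConfigError("n_signal_genes exceeds n_genes")
        if self.n_signal_genes + self.n_blocks * self.block_size > self.n_genes:
            raise ConfigError("n_signal_genes + n_blocks * block_size exceeds n_genes")
        if self.low_mean >= self.high_mean:
            raise ConfigError("low_mean must be below high_mean")
        if len(self.cancer_labels) == 0:
            raise ConfigError("cancer_labels must be nonempty")
        if len(self.drug_names) == 0:
            raise ConfigError("drug_names must be nonempty")


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated cohort."""

    signal_hazard: dict[str, float]  # signal gene id -> true HR
    block_membership: dict[str, int]  # gene id -> block id (contiguous from 0)
    block_hazard: dict[int, float]  # block id -> true HR of its latent factor
    gene_latent: pd.DataFrame  # bimodal genes x patients, True = high state
    block_factors: pd.DataFrame  # blocks x patients, True = factor high
    cancer_of: dict[str, str]  # patient id -> cancer label

    @property
    def signal_gene_ids(self) -> frozenset[str]:
        return frozenset(self.signal_hazard)

    def to_frame(self) -> pd.DataFrame:
        """Per-gene role table (gene_id, role, block_id, true_hr)."""
        rows = []
        for g in self.gene_latent.index:
            if g in self.signal_hazard:
                role, block, hr = "signal", -1, self.signal_hazard[g]
            elif g in self.block_membership:
                b = self.block_membership[g]
                role, block, hr = "block", b, self.block_hazard.get(b, 1.0)
            else:
                role, block, hr = "bimodal", -1, 1.0
            rows.append({"gene_id": g, "role": role, "block_id": block, "true_hr": hr})
        return pd.DataFrame(rows, columns=["gene_id", "role", "block_id", "true_hr"])


@dataclass
class SyntheticCohort:
    """A fully simulated cohort plus its ground truth."""

    expression: ExpressionMatrix  # linear scale, as on disk
    truth: GroundTruth
    survival: list[SurvivalRecord] = field(default_factory=list)
    clinical: pd.DataFrame | None = None
    exposures: pd.DataFrame | None = None
    synonym_map: dict[str, str] = field(default_factory=dict)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the expression matrix and its latent structure.

    Gene layout: signal genes first, then block genes (block 0, block 1,
    ...), then enough extra independent bimodal genes to reach
    ``bimodal_fraction`` of all genes, then unimodal noise genes centred
    between the two component means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _ids("P", config.n_patients)
    genes = _ids("G", config.n_genes)
    n_sig = config.n_signal_genes
    n_block_genes = config.n_blocks * config.block_size
    target_bimodal = int(round(config.bimodal_fraction * config.n_genes))
    n_extra = max(0, min(target_bimodal - n_sig - n_block_genes,
                         config.n_genes - n_sig - n_block_genes))

    # latent states
    signal_latent = rng.random((n_sig, config.n_patients)) < 0.5
    block_factors = rng.random((config.n_blocks, config.n_patients)) < 0.5
    flips = (
        rng.random((n_block_genes, config.n_patients)) < config.block_flip_prob
    )
    block_latent = np.repeat(block_factors, config.block_size, axis=0) ^ flips
    extra_latent = rng.random((n_extra, config.n_patients)) < 0.5
    latent = np.vstack([signal_latent, block_latent, extra_latent])
    n_bimodal = latent.shape[0]

    span = config.high_mean - config.low_mean
    log_vals = np.empty((config.n_genes, config.n_patients))
    log_vals[:n_bimodal] = (
        config.low_mean
        + latent * span
        + rng.normal(0.0, config.component_sd, size=(n_bimodal, config.n_patients))
    )
    n_uni = config.n_genes - n_bimodal
    log_vals[n_bimodal:] = rng.normal(
        (config.low_mean + config.high_mean) / 2.0,
        config.component_sd,
        size=(n_uni, config.n_patients),
    )
    linear = np.maximum(np.exp2(log_vals) - 1.0, 0.0)

    cancers = rng.choice(np.asarray(config.cancer_labels, dtype=object),
                         size=config.n_patients)
    truth = GroundTruth(
        signal_hazard={genes[i]: config.signal_hazard_ratio for i in range(n_sig)},
        block_membership={
            genes[n_sig + b * config.block_size + j]: b
            for b in range(config.n_blocks)
            for j in range(config.block_size)
        },
        block_hazard={b: config.block_hazard_ratio for b in range(config.n_blocks)},
        gene_latent=pd.DataFrame(latent, index=genes[:n_bimodal], columns=patients),
        block_factors=pd.DataFrame(
            block_factors, index=list(range(config.n_blocks)), columns=patients
        ),
        cancer_of=dict(zip(patients, (str(c) for c in cancers))),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(linear, index=genes, columns=patients), scale="linear"
    )
    return matrix, truth


def patient_hazards(truth: GroundTruth, config: SimConfig) -> pd.Series:
    """Per-patient death hazard: baseline times the planted HR of every
    signal gene and hazard-carrying block whose latent state is high."""
    patients = list(truth.gene_latent.columns)
    h = np.full(len(patients), config.baseline_hazard)
    for g, hr in truth.signal_hazard.items():
        h *= np.where(truth.gene_latent.loc[g].to_numpy(), hr, 1.0)
    for b, hr in truth.block_hazard.items():
        h *= np.where(truth.block_factors.loc[b].to_numpy(), hr, 1.0)
    return pd.Series(h, index=patients, name="hazard")


def simulate_survival(truth: GroundTruth, config: SimConfig) -> list[SurvivalRecord]:
    """Exponential event times at each patient's hazard, independently
    right-censored at ``censor_rate`` (0 disables censoring)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    hazards = patient_hazards(truth, config)
    t_event = rng.exponential(1.0 / hazards.to_numpy())
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=hazards.size)
    else:
        t_cens = np.full(hazards.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return [
        SurvivalRecord(pid, float(t), bool(ev))
        for pid, t, ev in zip(hazards.index, time, event)
    ]


def simulate_clinical_tables(
    truth: GroundTruth, config: SimConfig, survival: list[SurvivalRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical and drug-exposure tables for a simulated cohort.

    Clinical rows carry the cancer label, vital status, and days-to-death
    (events) or days-to-last-follow-up (censored).  Every patient receives
    one drug uniformly at random plus, with probability ``extra_drug_prob``,
    a second distinct drug; each exposure row uses a raw name variant and is
    duplicated with probability ``duplicate_row_prob``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    clinical_rows = []
    for rec in survival:
        clinical_rows.append(
            {
                "patient_id": rec.patient_id,
                "cancer": truth.cancer_of[rec.patient_id],
                "vital_status": "Dead" if rec.event else "Alive",
                "days_to_death": f"{rec.time:.1f}" if rec.event else "",
                "days_to_last_followup": "" if rec.event else f"{rec.time:.1f}",
            }
        )
    clinical = pd.DataFrame(clinical_rows)

    drugs = list(config.drug_names)
    exposure_rows = []
    for rec in survival:
        idx = [int(rng.integers(len(drugs)))]
        if len(drugs) > 1 and rng.random() < config.extra_drug_prob:
            other = int(rng.integers(len(drugs) - 1))
            idx.append(other + (other >= idx[0]))
        for i in idx:
            canonical, variants = drugs[i]
            pool = [canonical, *variants]
            raw = pool[int(rng.integers(len(pool)))]
            exposure_rows.append({"patient_id": rec.patient_id, "drug_name": raw})
            if rng.random() < config.duplicate_row_prob:
                exposure_rows.append({"patient_id": rec.patient_id, "drug_name": raw})
    exposures = pd.DataFrame(exposure_rows)
    return clinical, exposures


def synonym_map_from_config(config: SimConfig) -> dict[str, str]:
    """The curated raw -> canonical map matching the generator's variants."""
    return {
        raw: canonical
        for canonical, variants in config.drug_names
        for raw in (canonical, *variants)
    }


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run the full generator: expression, survival, clinical tables."""
    expression, truth = simulate_expression(config)
    survival = simulate_survival(truth, config)
    clinical, exposures = simulate_clinical_tables(truth, config, survival)
    return SyntheticCohort(
        expression=expression,
        truth=truth,
        survival=survival,
        clinical=clinical,
        exposures=exposures,
        synonym_map=synonym_map_from_config(config),
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort as the tab-separated files the ingest module reads
    (plus the ground-truth gene table).  Returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "exposures": out / "exposures.tsv",
        "synonyms": out / "drug_synonyms.tsv",
        "truth": out / "ground_truth.tsv",
    }
    cohort.expression.to_tsv(paths["expression"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.exposures.to_csv(paths["exposures"], sep="\t", index=False)
    pd.DataFrame(
        [{"raw": k, "canonical": v} for k, v in cohort.synonym_map.items()]
    ).to_csv(paths["synonyms"], sep="\t", index=False)
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
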