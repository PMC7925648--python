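"""End-to-end orchestration: the DrugSurvivalScreen model and its results.

The full analysis — ingest, per-gene binarization, cancer-drug group
construction, per-group log-rank screening with BH-FDR, co-occurrence
clustering of significant genes into sets, set-level stratification, and TF
target enrichment — is wrapped in a statsmodels-style pair of objects:

* :class:`DrugSurvivalScreen` holds the data and the analysis parameters;
  :meth:`DrugSurvivalScreen.fit` runs the pipeline deterministically for a
  seed and returns
* :class:`ScreenResults`, which carries every table (gene results, group
  summaries, gene sets, enrichment, multi-cancer interactions), renders a
  ``summary()``, saves TSV outputs, and draws Kaplan-Meier plots.

Stage outputs are written incrementally when an output directory is given,
so a failure in a later stage preserves earlier results, and the JSON run
report is rebuilt by reading those files back.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binarize import BinaryMatrix, binarize_matrix
from .cooccur import (
    DEFAULT_GRAPH_ALPHA,
    DEFAULT_MIN_SET_SIZE,
    DEFAULT_MIN_SIG_GENES,
    GeneSet,
    _set_letter,
    cooccurrence_cluster,
    memberships_to_frame,
    set_stratify_and_test,
    sets_to_frame,
)
from .enrich import (
    DEFAULT_TF_FDR,
    TFTargetCollection,
    enrich_sets,
    enrichment_to_frame,
    read_gmt,
)
from .errors import UsageError
from .ingest import (
    DEFAULT_MIN_GROUP_SIZE,
    ExpressionMatrix,
    PatientGroup,
    SurvivalRecord,
    build_patient_groups,
    extract_survival,
    log_transform,
    read_expression_table,
    read_synonym_map,
    standardize_drug_names,
)
from .survival import (
    DEFAULT_GENE_FDR,
    DEFAULT_MIN_PER_ARM,
    GeneSurvivalResult,
    ScreenSummary,
    logrank_test,
    results_to_frame,
    screen_group,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths plus analysis parameters for one pipeline run."""

    expression: str
    clinical: str
    exposures: str
    synonyms: str | None = None
    gmt: str | None = None
    out_dir: str = "drugsurv_out"
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    min_per_arm: int = DEFAULT_MIN_PER_ARM
    gene_fdr: float = DEFAULT_GENE_FDR
    min_sig_genes: int = DEFAULT_MIN_SIG_GENES
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    graph_alpha: float = DEFAULT_GRAPH_ALPHA
    tf_fdr: float = DEFAULT_TF_FDR
    enrichment_universe: str = "group_tested"
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        for name in ("min_group_size", "min_per_arm", "min_sig_genes",
                     "min_set_size"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        for name in ("gene_fdr", "tf_fdr", "graph_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise UsageError(f"{name} must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON config mirroring the field names."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls(**data)


class DrugSurvivalScreen:
    """Drug-specific survival-marker screen over one expression cohort.

    Parameters mirror the analysis thresholds: groups need
    ``min_group_size`` patients, genes need ``min_per_arm`` low and high
    expressors to be tested, per-group BH control at ``gene_fdr``, groups
    with at least ``min_sig_genes`` significant genes are clustered into
    sets of at least ``min_set_size`` genes, and TF enrichment is called at
    ``tf_fdr``.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: pd.DataFrame,
        exposures: pd.DataFrame,
        synonym_map: dict[str, str] | None = None,
        tf_collection: TFTargetCollection | None = None,
        *,
        min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
        min_per_arm: int = DEFAULT_MIN_PER_ARM,
        gene_fdr: float = DEFAULT_GENE_FDR,
        min_sig_genes: int = DEFAULT_MIN_SIG_GENES,
        min_set_size: int = DEFAULT_MIN_SET_SIZE,
        graph_alpha: float = DEFAULT_GRAPH_ALPHA,
        tf_fdr: float = DEFAULT_TF_FDR,
        enrichment_universe: str = "group_tested",
    ) -> None:
        if expression.scale == "linear":
            expression = log_transform(expression)
        self.expression = expression
        self.clinical = clinical
        self.exposures = standardize_drug_names(exposures, synonym_map)
        self.tf_collection = tf_collection
        self.survival: list[SurvivalRecord] = extract_survival(clinical)
        self.min_group_size = min_group_size
        self.min_per_arm = min_per_arm
        self.gene_fdr = gene_fdr
        self.min_sig_genes = min_sig_genes
        self.min_set_size = min_set_size
        self.graph_alpha = graph_alpha
        self.tf_fdr = tf_fdr
        if enrichment_universe not in ("group_tested", "all_genes"):
            raise UsageError(
                "enrichment_universe must be 'group_tested' or 'all_genes'"
            )
        self.enrichment_universe = enrichment_universe

    @classmethod
    def from_files(
        cls,
        expression,
        clinical,
        exposures,
        synonyms=None,
        gmt=None,
        skip_header_lines: int = 0,
        **params,
    ) -> "DrugSurvivalScreen":
        """Build the model from the on-disk tab-separated tables.

        ``skip_header_lines`` skips that many preamble lines in each table
        (BCR-Biotab-style clinical supplements carry them).
        """
        matrix = read_expression_table(expression,
                                       skip_header_lines=skip_header_lines)
        clin = pd.read_csv(clinical, sep="\t", dtype=str,
                           skiprows=skip_header_lines)
        expo = pd.read_csv(exposures, sep="\t", dtype=str,
                           skiprows=skip_header_lines)
        syn = read_synonym_map(synonyms) if synonyms else None
        coll = read_gmt(gmt) if gmt else None
        return cls(matrix, clin, expo, synonym_map=syn, tf_collection=coll, **params)

    @classmethod
    def from_config(cls, config: RunConfig) -> "DrugSurvivalScreen":
        return cls.from_files(
            config.expression,
            config.clinical,
            config.exposures,
            synonyms=config.synonyms,
            gmt=config.gmt,
            min_group_size=config.min_group_size,
            min_per_arm=config.min_per_arm,
            gene_fdr=config.gene_fdr,
            min_sig_genes=config.min_sig_genes,
            min_set_size=config.min_set_size,
            graph_alpha=config.graph_alpha,
            tf_fdr=config.tf_fdr,
            enrichment_universe=config.enrichment_universe,
        )

    @classmethod
    def from_cohort(cls, cohort, tf_collection=None, **params) -> "DrugSurvivalScreen":
        """Build the model directly from a simulated cohort object."""
        return cls(
            cohort.expression,
            cohort.clinical,
            cohort.exposures,
            synonym_map=cohort.synonym_map,
            tf_collection=tf_collection,
            **params,
        )

    # -- fitting ---------------------------------------------------------

    def fit(
        self, seed: int = 0, out_dir=None, stop_after: str | None = None
    ) -> "ScreenResults":
        """Run the pipeline; deterministic given (inputs, seed).

        ``out_dir`` enables incremental stage checkpointing; ``stop_after``
        in {"screen", "cluster"} truncates the run after that stage.
        """
        out = Path(out_dir) if out_dir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
        results = ScreenResults(model=self, seed=seed)

        logger.info("binarize: %d genes x %d samples", *self.expression.shape)
        results.binary = binarize_matrix(self.expression)
        if out is not None:
            results.binary.thresholds_to_tsv(out / "thresholds.tsv")

        results.groups = build_patient_groups(
            self.clinical,
            self.exposures,
            self.expression,
            survival=self.survival,
            min_group_size=self.min_group_size,
        )
        logger.info("groups: %d of size >= %d", len(results.groups),
                    self.min_group_size)

        for group in results.groups:
            res, summary = screen_group(
                group,
                results.binary,
                self.survival,
                min_per_arm=self.min_per_arm,
                fdr=self.gene_fdr,
            )
            results.gene_results.extend(res)
            results.summaries.append(summary)
        if out is not None:
            results.gene_results_frame().to_csv(
                out / "gene_results.tsv", sep="\t", index=False
            )
            results.summary_frame().to_csv(
                out / "screen_summary.tsv", sep="\t", index=False
            )
        if stop_after == "screen":
            return results

        results.gene_sets = self._cluster_sets(results, seed)
        if out is not None:
            sets_to_frame(results.gene_sets).to_csv(
                out / "gene_sets.tsv", sep="\t", index=False
            )
            memberships_to_frame(results.gene_sets).to_csv(
                out / "set_members.tsv", sep="\t", index=False
            )
        if stop_after == "cluster":
            return results

        if self.tf_collection is not None and results.gene_sets:
            results.enrichment = self._enrich(results)
        if out is not None:
            enrichment_to_frame(results.enrichment).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )

        results.multi_cancer = count_multi_cancer_interactions(results.gene_results)
        if out is not None:
            results.multi_cancer.to_csv(
                out / "multi_cancer.tsv", sep="\t", index=False
            )
            results.write_report(out / "report.json", read_back=out)
        return results

    def _cluster_sets(self, results: "ScreenResults", seed: int) -> list[GeneSet]:
        gene_sets: list[GeneSet] = []
        for group in results.groups:
            sig = sorted(
                r.gene_id
                for r in results.gene_results
                if r.cancer == group.cancer
                and r.drug == group.drug
                and r.significant
            )
            if len(sig) < self.min_sig_genes:
                if sig:
                    logger.info(
                        "cluster: skipping %s/%s (%d significant genes < %d)",
                        group.cancer, group.drug, len(sig), self.min_sig_genes,
                    )
                continue
            surv_pids = {r.patient_id for r in self.survival}
            pids = sorted(
                p for p in group.patient_ids
                if p in surv_pids and p in results.binary.calls.columns
            )
            calls = results.binary.calls.loc[sig, pids]
            member_lists = cooccurrence_cluster(
                calls,
                seed=seed,
                min_set_size=self.min_set_size,
                min_patients=2 * self.min_per_arm,
                alpha=self.graph_alpha,
            )
            for i, members in enumerate(member_lists):
                gs = set_stratify_and_test(
                    group,
                    members,
                    results.binary.calls,
                    self.survival,
                    gene_results=results.gene_results,
                    set_id=_set_letter(i),
                )
                gene_sets.append(gs)
        return gene_sets

    def _enrich(self, results: "ScreenResults"):
        if self.enrichment_universe == "all_genes":
            universe = set(self.expression.gene_ids)
            return enrich_sets(
                results.gene_sets, self.tf_collection, universe, fdr=self.tf_fdr
            )
        tested: dict[tuple[str, str], set[str]] = {}
        for r in results.gene_results:
            tested.setdefault((r.cancer, r.drug), set()).add(r.gene_id)
        return enrich_sets(
            results.gene_sets,
            self.tf_collection,
            lambda gs: tested.get((gs.cancer, gs.drug), set()),
            fdr=self.tf_fdr,
        )


@dataclass
class ScreenResults:
    """Fitted pipeline outputs with tabulation, summary, save, and plots."""

    model: DrugSurvivalScreen
    seed: int = 0
    binary: BinaryMatrix | None = None
    groups: list[PatientGroup] = field(default_factory=list)
    gene_results: list[GeneSurvivalResult] = field(default_factory=list)
    summaries: list[ScreenSummary] = field(default_factory=list)
    gene_sets: list[GeneSet] = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    multi_cancer: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- tables ----------------------------------------------------------

    def gene_results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.gene_results)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cancer": s.cancer,
                    "drug": s.drug,
                    "patients": s.n_patients,
                    "genes_tested": s.genes_tested,
                    "genes_significant": s.genes_significant,
                }
                for s in self.summaries
            ],
            columns=["cancer", "drug", "patients", "genes_tested",
                     "genes_significant"],
        )

    def sets_frame(self) -> pd.DataFrame:
        return sets_to_frame(self.gene_sets)

    def enrichment_frame(self) -> pd.DataFrame:
        return enrichment_to_frame(self.enrichment)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.gene_results)

    def summary(self) -> str:
        """Human-readable run summary: per-group screen counts and the
        set-level table."""
        lines = [
            f"drugsurv {__version__} | seed {self.seed}",
            f"groups (>= {self.model.min_group_size} patients): "
            f"{len(self.groups)}",
            f"gene tests: {len(self.gene_results)} | significant at "
            f"{self.model.gene_fdr:.0%} FDR: {self.n_significant}",
            "",
            "Per-group screen:",
            self.summary_frame().to_string(index=False),
        ]
        if self.gene_sets:
            lines += ["", "Gene sets:", self.sets_frame().to_string(index=False)]
        if self.enrichment:
            sig = self.enrichment_frame()
            sig = sig[sig["significant"]]
            lines += ["", f"TF enrichments at {self.model.tf_fdr:.0%} FDR: "
                          f"{len(sig)}"]
        if len(self.multi_cancer):
            lines += ["", "Multi-cancer gene-drug interactions:",
                      self.multi_cancer.to_string(index=False)]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, out_dir, plots: bool | None = None) -> None:
        """Write every result table (and optionally KM plots) to a
        directory, then the JSON report derived by reading them back."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.binary.thresholds_to_tsv(out / "thresholds.tsv")
        self.gene_results_frame().to_csv(out / "gene_results.tsv", sep="\t",
                                         index=False)
        self.summary_frame().to_csv(out / "screen_summary.tsv", sep="\t",
                                    index=False)
        sets_to_frame(self.gene_sets).to_csv(out / "gene_sets.tsv", sep="\t",
                                             index=False)
        memberships_to_frame(self.gene_sets).to_csv(out / "set_members.tsv",
                                                    sep="\t", index=False)
        enrichment_to_frame(self.enrichment).to_csv(out / "enrichment.tsv",
                                                    sep="\t", index=False)
        self.multi_cancer.to_csv(out / "multi_cancer.tsv", sep="\t", index=False)
        if plots:
            self.save_plots(out / "plots")
        self.write_report(out / "report.json", read_back=out)

    def write_report(self, path, read_back=None) -> dict:
        """Build report.json.  With ``read_back`` set, every count is
        recomputed from the emitted TSVs rather than from memory."""
        if read_back is not None:
            rb = Path(read_back)
            genes = pd.read_csv(rb / "gene_results.tsv", sep="\t")
            summary = pd.read_csv(rb / "screen_summary.tsv", sep="\t")
            sets = pd.read_csv(rb / "gene_sets.tsv", sep="\t")
            enr_path = rb / "enrichment.tsv"
            enr = pd.read_csv(enr_path, sep="\t") if enr_path.exists() else pd.DataFrame()
            report = {
                "version": __version__,
                "seed": self.seed,
                "n_groups": int(len(summary)),
                "n_gene_tests": int(len(genes)),
                "n_significant_genes": int(genes["significant"].sum())
                if len(genes) else 0,
                "n_groups_with_hits": int(
                    (summary["genes_significant"] > 0).sum()
                ) if len(summary) else 0,
                "n_gene_sets": int(len(sets)),
                "n_enrichment_tests": int(len(enr)),
                "n_significant_enrichments": int(enr["significant"].sum())
                if len(enr) else 0,
                "config": {
                    "min_group_size": self.model.min_group_size,
                    "min_per_arm": self.model.min_per_arm,
                    "gene_fdr": self.model.gene_fdr,
                    "min_sig_genes": self.model.min_sig_genes,
                    "min_set_size": self.model.min_set_size,
                    "graph_alpha": self.model.graph_alpha,
                    "tf_fdr": self.model.tf_fdr,
                },
            }
        else:
            report = {
                "version": __version__,
                "seed": self.seed,
                "n_groups": len(self.groups),
                "n_gene_tests": len(self.gene_results),
                "n_significant_genes": self.n_significant,
                "n_gene_sets": len(self.gene_sets),
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report

    # -- plotting --------------------------------------------------------

    def _group_records(self, cancer: str, drug: str):
        group = next(
            (g for g in self.groups if g.cancer == cancer and g.drug == drug), None
        )
        if group is None:
            raise UsageError(f"no group ({cancer}, {drug})")
        surv = {r.patient_id: r for r in self.model.survival}
        return group, surv

    def plot_km_gene(self, cancer: str, drug: str, gene_id: str, path) -> bool:
        """KM curves of the group's low vs. high expressors of one gene."""
        group, surv = self._group_records(cancer, drug)
        calls = self.binary.calls.loc[gene_id]
        pids = [p for p in sorted(group.patient_ids) if p in surv]
        low = [surv[p] for p in pids if not calls[p]]
        high = [surv[p] for p in pids if calls[p]]
        return plot_km(low, high, f"{cancer} / {drug} / {gene_id}", path)

    def plot_km_set(self, gene_set: GeneSet, path) -> bool:
        """KM curves of the group's low vs. high set expressors."""
        group, surv = self._group_records(gene_set.cancer, gene_set.drug)
        frac = gene_set.fractions
        low, high = [], []
        for pid, f in frac.items():
            if pid not in surv:
                continue
            (high if f > gene_set.threshold else low).append(surv[pid])
        title = f"{gene_set.cancer} / {gene_set.drug} / set {gene_set.set_id}"
        return plot_km(low, high, title, path)

    def save_plots(self, plot_dir, max_genes: int = 5) -> list[str]:
        """Plot the top significant genes and every gene set."""
        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        written: list[str] = []
        top = [r for r in self.gene_results if r.significant]
        top.sort(key=lambda r: r.p_value)
        for r in top[:max_genes]:
            path = plot_dir / f"km_{r.cancer}_{r.drug}_{r.gene_id}.png"
            if self.plot_km_gene(r.cancer, r.drug, r.gene_id, path):
                written.append(str(path))
        for gs in self.gene_sets:
            path = plot_dir / f"km_set_{gs.cancer}_{gs.drug}_{gs.set_id}.png"
            if self.plot_km_set(gs, path):
                written.append(str(path))
        return written


def plot_km(low_records, high_records, title: str, path,
            labels=("low", "high")) -> bool:
    """Kaplan-Meier step curves for a low (blue) and high (orange) stratum,
    annotated with per-arm sizes and the log-rank p-value.  Returns False
    (plot skipped, warning logged) when either stratum is empty."""
    if len(low_records) == 0 or len(high_records) == 0:
        logger.warning("plot_km: empty stratum for %s, skipping", title)
        return False
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    lr = logrank_test(low_records, high_records)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for records, label, color in (
        (low_records, labels[0], "tab:blue"),
        (high_records, labels[1], "tab:orange"),
    ):
        kmf = KaplanMeierFitter()
        kmf.fit(
            [r.time for r in records],
            event_observed=[r.event for r in records],
            label=f"{label} (n={len(records)})",
        )
        kmf.plot_survival_function(ax=ax, color=color, ci_show=False)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title}\nlog-rank p = {lr.p_value:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def count_multi_cancer_interactions(
    gene_results: list[GeneSurvivalResult],
) -> pd.DataFrame:
    """Gene-drug pairs significant in two or more distinct cancers, with
    the cancers listed."""
    per_pair: dict[tuple[str, str], set[str]] = {}
    for r in gene_results:
        if r.significant:
            per_pair.setdefault((r.gene_id, r.drug), set()).add(r.cancer)
    rows = [
        {
            "gene_id": gene,
            "drug": drug,
            "n_cancers": len(cancers),
            "cancers": ",".join(sorted(cancers)),
        }
        for (gene, drug), cancers in sorted(per_pair.items())
        if len(cancers) >= 2
    ]
    return pd.DataFrame(rows, columns=["gene_id", "drug", "n_cancers", "cancers"])


@dataclass
class RunReport:
    """What ``run_pipeline`` returns: the fitted results plus the JSON
    report dictionary derived from the emitted files."""

    results: ScreenResults
    report: dict
    out_dir: str


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> RunReport:
    """Run the full analysis from a :class:`RunConfig` and write outputs."""
    model = DrugSurvivalScreen.from_config(config)
    results = model.fit(seed=config.seed, out_dir=config.out_dir,
                        stop_after=stop_after)
    out = Path(config.out_dir)
    if stop_after is None:
        report = json.loads((out / "report.json").read_text(encoding="utf-8"))
        if config.plots:
            results.save_plots(out / "plots")
    else:
        report = results.write_report(out / "report.json")
    return RunReport(results=results, report=report, out_dir=str(out))
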