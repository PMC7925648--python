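"""Transcription-factor target over-representation in discovered gene sets.

Each discovered co-expressed gene set is tested for overlap with every TF
target collection (supplied in GMT format, e.g. an MSigDB regulatory-target
sub-collection) with the hypergeometric upper tail — equivalently a
one-sided Fisher exact test — against a stated gene universe.  p-values are
BH-adjusted within each gene set across TFs, significant at 5% FDR by
default.

The universe defaults to the genes actually tested for survival in the
gene set's cancer-drug group; callers may widen it to all genes in the
expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .cooccur import GeneSet
from .errors import FormatError, UsageError
from .survival import bh_adjust

DEFAULT_TF_FDR = 0.05


@dataclass
class TFTargetCollection:
    """Named TF -> target-gene-set mapping (gene ids upper-cased)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"TF target set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    cancer: str
    drug: str
    tf_label: str
    overlap: int
    set_size: int
    tf_set_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def read_gmt(path) -> TFTargetCollection:
    """Read a GMT file: per line, set name, description, then member genes,
    tab-separated.  Gene ids are upper-cased for matching."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate GMT set name: {name!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return TFTargetCollection(sets=sets, source=str(path))


def write_gmt(collection: TFTargetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(genes)]) + "\n")


def hypergeom_overlap(query, tf_set, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test.

    Both sets are intersected with the universe first; p = P(X >= k) for X
    hypergeometric with population |universe|, successes |tf in universe|,
    draws |query in universe|.  An empty post-intersection query gives
    (0, 1.0).
    """
    universe = {str(g).upper() for g in universe}
    if len(universe) == 0:
        raise UsageError("universe must be nonempty")
    q = {str(g).upper() for g in query} & universe
    t = {str(g).upper() for g in tf_set} & universe
    k = len(q & t)
    if len(q) == 0 or k == 0:
        return k, 1.0
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(t), len(q)))
    return k, min(max(p, 5e-324), 1.0)


def enrich_sets(
    gene_sets: list[GeneSet],
    collection: TFTargetCollection,
    universe,
    fdr: float = DEFAULT_TF_FDR,
) -> list[EnrichmentResult]:
    """Test every (gene set, TF) pair; BH-adjust within each gene set
    across TFs.  ``universe`` is either a single iterable of gene ids used
    for all sets or a callable mapping a GeneSet to its universe."""
    results: list[EnrichmentResult] = []
    tf_names = sorted(collection.sets)
    for gs in gene_sets:
        uni = set(universe(gs)) if callable(universe) else set(universe)
        uni = {str(g).upper() for g in uni}
        per_set: list[EnrichmentResult] = []
        for tf in tf_names:
            k, p = hypergeom_overlap(gs.members, collection.sets[tf], uni)
            per_set.append(
                EnrichmentResult(
                    gene_set_id=gs.set_id,
                    cancer=gs.cancer,
                    drug=gs.drug,
                    tf_label=tf,
                    overlap=k,
                    set_size=gs.size,
                    tf_set_size=len(collection.sets[tf] & uni),
                    universe_size=len(uni),
                    p_value=p,
                )
            )
        q, sig = bh_adjust([r.p_value for r in per_set], fdr=fdr)
        for r, qi, si in zip(per_set, q, sig):
            results.append(
                EnrichmentResult(
                    gene_set_id=r.gene_set_id,
                    cancer=r.cancer,
                    drug=r.drug,
                    tf_label=r.tf_label,
                    overlap=r.overlap,
                    set_size=r.set_size,
                    tf_set_size=r.tf_set_size,
                    universe_size=r.universe_size,
                    p_value=r.p_value,
                    q_value=float(qi),
                    significant=bool(si),
                )
            )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cancer": r.cancer,
                "drug": r.drug,
                "set_id": r.gene_set_id,
                "tf": r.tf_label,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "tf_set_size": r.tf_set_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "cancer",
            "drug",
            "set_id",
            "tf",
            "overlap",
            "set_size",
            "tf_set_size",
            "universe_size",
            "p_value",
            "q_value",
            "significant",
        ],
    )
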