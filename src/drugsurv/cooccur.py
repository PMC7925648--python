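"""Co-occurrence clustering of significant genes into co-expressed sets.

Within one cancer-drug patient group, the binary calls of the group's
significant genes are clustered by (1) building a gene-gene graph whose
edges connect positively associated gene pairs (Pearson chi-square on the
2x2 table of calls, p < alpha), (2) partitioning the graph with seeded
Louvain community detection, (3) splitting the patients on each community's
per-patient expression fraction (thresholded with the same step-fit routine
used for single genes), and (4) recursing into each patient cluster.  Every
community of at least ``min_set_size`` genes discovered at any level is
emitted once, lettered in discovery order.

Each emitted set is then scored: patients are stratified into high/low
set expressors by their fraction of member genes called high, and the two
strata are compared with the log-rank test.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .binarize import binarize_scores
from .errors import UsageError
from .ingest import PatientGroup, SurvivalRecord
from .survival import TIED, GeneSurvivalResult, _logrank_arrays

DEFAULT_GRAPH_ALPHA = 1e-3
DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MIN_SIG_GENES = 10
MAX_RECURSION_DEPTH = 10


@dataclass
class GeneSet:
    """A co-expressed set of significant genes within one patient group."""

    set_id: str
    cancer: str
    drug: str
    members: tuple[str, ...]
    fractions: pd.Series | None = None  # per-patient fraction of members high
    threshold: float = float("nan")
    n_low: int = 0
    n_high: int = 0
    statistic: float = float("nan")
    p_value: float = float("nan")
    best_member_p: float = float("nan")
    percent_members_more_significant: float = float("nan")
    direction: str = TIED
    degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def chi2_pair(x, y) -> float:
    """Pearson chi-square of the 2x2 contingency table of two binary
    vectors, no continuity correction: n(ad-bc)^2 / (r1 r2 c1 c2).
    Zero whenever a margin is zero (the table is degenerate)."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise UsageError("chi2_pair requires equal-length vectors")
    n = x.size
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def _pairwise_chi2(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized chi-square and positive-association indicator for all
    gene pairs of a genes x patients boolean matrix."""
    x = calls.astype(np.float64)
    n = x.shape[1]
    a = x @ x.T  # co-high counts
    hi = x.sum(axis=1)
    b = hi[:, None] - a
    c = hi[None, :] - a
    d = n - a - b - c
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    positive = a * n > hi[:, None] * hi[None, :]  # observed co-high > expected
    return chi2, positive


def build_gene_graph(
    calls: pd.DataFrame, alpha: float = DEFAULT_GRAPH_ALPHA
) -> nx.Graph:
    """Gene-gene association graph from a genes x patients boolean frame.

    An edge joins two genes when their chi-square association is positive
    (co-high counts above expectation) and significant at ``alpha`` (1 df);
    the edge weight is the chi-square statistic.
    """
    if calls.shape[0] < 2:
        raise UsageError("need at least 2 genes to build a gene graph")
    genes = list(calls.index)
    chi2, positive = _pairwise_chi2(calls.to_numpy(dtype=bool))
    cutoff = stats.chi2.isf(alpha, df=1)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (chi2[iu, ju] > cutoff) & positive[iu, ju]
    for i, j in zip(iu[keep], ju[keep]):
        graph.add_edge(genes[i], genes[j], weight=float(chi2[i, j]))
    return graph


def louvain_partition(graph: nx.Graph, seed: int = 0) -> list[set[str]]:
    """Seeded Louvain modularity communities; isolated nodes become
    singleton communities.  Deterministic given (graph, seed)."""
    if graph.number_of_nodes() == 0:
        raise UsageError("louvain_partition needs at least one node")
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=1.0, seed=seed
    )
    return [set(c) for c in communities]


def set_fraction(calls: pd.DataFrame, members) -> pd.Series:
    """Per-patient fraction of the member genes called high."""
    members = list(members)
    if len(members) == 0:
        raise UsageError("set_fraction needs a nonempty member list")
    return calls.loc[members].mean(axis=0)


def _set_letter(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... in discovery order."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def cooccurrence_cluster(
    calls: pd.DataFrame,
    seed: int = 0,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    min_patients: int = 20,
    alpha: float = DEFAULT_GRAPH_ALPHA,
) -> list[list[str]]:
    """Iterative gene/patient co-clustering of a genes x patients boolean
    frame.  Returns the member lists of every gene community of size >=
    ``min_set_size`` found at any recursion level, deduplicated by member
    identity, in discovery order.

    A branch stops when its patient subset shrinks below ``min_patients``
    (two minimal log-rank arms), when its gene graph has no edges, or when
    a patient split fails to change the subset.
    """
    emitted: list[list[str]] = []
    seen_sets: set[frozenset[str]] = set()
    seen_patients: set[frozenset[str]] = set()

    def recurse(patient_ids: list[str], depth: int) -> None:
        if len(patient_ids) < min_patients or depth > MAX_RECURSION_DEPTH:
            return
        key = frozenset(patient_ids)
        if key in seen_patients:
            return
        seen_patients.add(key)
        sub = calls[patient_ids]
        if sub.shape[0] < 2:
            return
        graph = build_gene_graph(sub, alpha=alpha)
        if graph.number_of_edges() == 0:
            return
        communities = louvain_partition(graph, seed=seed)
        communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c))
        for comm in communities:
            if len(comm) >= min_set_size:
                fs = frozenset(comm)
                if fs not in seen_sets:
                    seen_sets.add(fs)
                    emitted.append(comm)
        # Patient splits: binarize each substantive community's expression
        # fraction.  Only communities of set size drive splits — letting
        # every chance two-gene community partition the patients makes the
        # recursion combinatorial without ever yielding a reportable set.
        for comm in communities:
            if len(comm) < min_set_size:
                continue
            frac = set_fraction(sub, comm)
            high, _t = binarize_scores(frac.to_numpy())
            if not high.any() or high.all():
                continue
            for side in (high, ~high):
                subset = [p for p, s in zip(patient_ids, side) if s]
                if len(subset) < len(patient_ids):
                    recurse(subset, depth + 1)

    recurse(list(calls.columns), 0)
    return emitted


def set_stratify_and_test(
    group: PatientGroup,
    members,
    calls: pd.DataFrame,
    survival: list[SurvivalRecord],
    gene_results: list[GeneSurvivalResult] | None = None,
    set_id: str = "A",
) -> GeneSet:
    """Score one gene set: stratify the group's patients into high/low set
    expressors by thresholding the member-high fraction, log-rank the two
    strata, and report how the set compares with its member genes.

    ``percent_members_more_significant`` is the percentage of member genes
    whose individual screen p-value is smaller than the set's p-value.
    """
    members = tuple(sorted(members))
    surv_by_pid = {r.patient_id: r for r in survival}
    pids = sorted(
        p for p in group.patient_ids if p in surv_by_pid and p in calls.columns
    )
    frac = set_fraction(calls[pids], members)
    high, threshold = binarize_scores(frac.to_numpy())
    gs = GeneSet(
        set_id=set_id,
        cancer=group.cancer,
        drug=group.drug,
        members=members,
        fractions=pd.Series(frac.to_numpy(), index=pids, name="set_fraction"),
        threshold=threshold,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
    )
    if np.isnan(threshold) or not high.any() or high.all():
        gs.degenerate = True
        gs.statistic = 0.0
        gs.p_value = 1.0
        return gs
    times = np.asarray([surv_by_pid[p].time for p in pids])
    events = np.asarray([surv_by_pid[p].event for p in pids])
    lr = _logrank_arrays(times[~high], events[~high], times[high], events[high])
    gs.statistic = lr.statistic
    gs.p_value = lr.p_value
    gs.direction = lr.direction
    if gene_results is not None:
        member_p = {
            r.gene_id: r.p_value
            for r in gene_results
            if r.cancer == group.cancer and r.drug == group.drug
        }
        ps = [member_p[g] for g in members if g in member_p]
        if ps:
            gs.best_member_p = float(min(ps))
            gs.percent_members_more_significant = float(
                100.0 * sum(p < gs.p_value for p in ps) / len(members)
            )
    return gs


def sets_to_frame(gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Set-level score table (one row per set)."""
    return pd.DataFrame(
        [
            {
                "cancer": s.cancer,
                "drug": s.drug,
                "set_id": s.set_id,
                "n_genes": s.size,
                "n_low": s.n_low,
                "n_high": s.n_high,
                "set_p_value": s.p_value,
                "best_member_p": s.best_member_p,
                "percent_members_more_significant": s.percent_members_more_significant,
                "direction": s.direction,
                "degenerate": s.degenerate,
            }
            for s in gene_sets
        ],
        columns=[
            "cancer",
            "drug",
            "set_id",
            "n_genes",
            "n_low",
            "n_high",
            "set_p_value",
            "best_member_p",
            "percent_members_more_significant",
            "direction",
            "degenerate",
        ],
    )


def memberships_to_frame(gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Long-format set membership table (one row per set member)."""
    rows = [
        {"cancer": s.cancer, "drug": s.drug, "set_id": s.set_id, "gene_id": g}
        for s in gene_sets
        for g in s.members
    ]
    return pd.DataFrame(rows, columns=["cancer", "drug", "set_id", "gene_id"])
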