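"""Kaplan-Meier estimation, the two-sample log-rank test, per-group gene
screening, and Benjamini-Hochberg FDR control.

The screen is the workhorse of the analysis: within one cancer-drug patient
group, every gene with at least ``min_per_arm`` low and ``min_per_arm``
high expressors is tested by comparing survival of its low vs. high arm
with the log-rank test, and p-values are BH-adjusted within the group.

The log-rank statistic is computed in-package (vectorized observed-minus-
expected tabulation with the hypergeometric tie variance) because the
screen also needs the direction of effect — the sign of the summed O-E for
the high arm — and a defined degenerate result when the variance is zero.
Kaplan-Meier curves come from lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from .binarize import BinaryMatrix
from .errors import UsageError
from .ingest import PatientGroup, SurvivalRecord

DEFAULT_MIN_PER_ARM = 10
DEFAULT_GENE_FDR = 0.10

HIGH_BETTER = "high_better"
LOW_BETTER = "low_better"
TIED = "tied"

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    direction: str


@dataclass(frozen=True)
class GeneSurvivalResult:
    """Log-rank screen outcome for one (cancer, drug, gene) combination."""

    cancer: str
    drug: str
    gene_id: str
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    q_value: float = float("nan")
    direction: str = TIED
    significant: bool = False


@dataclass(frozen=True)
class ScreenSummary:
    cancer: str
    drug: str
    n_patients: int
    genes_tested: int
    genes_significant: int


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    return times, events


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one stratum."""
    if len(records) == 0:
        raise UsageError("km_curve needs at least one record")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    observed = table["observed"].to_numpy()
    mask = observed > 0
    event_times = table.index.to_numpy()[mask]
    sf = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        event_times=event_times.astype(float),
        survival_probs=sf.loc[event_times].to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy()[mask].astype(int),
        events=observed[mask].astype(int),
    )


def logrank_test(
    low_records: list[SurvivalRecord], high_records: list[SurvivalRecord]
) -> LogrankResult:
    """Two-sample log-rank test of the low arm vs. the high arm.

    At each distinct event time, the observed high-arm deaths are compared
    with their expectation under the null; the variance is hypergeometric,
    which handles tied event times.  The statistic is
    (sum(O-E))^2 / sum(V) on 1 df.  Direction: fewer high-arm deaths than
    expected (sum(O-E) < 0) means the high expressors fare better.  When
    the total variance is zero (e.g. no events) the result is a tie with
    statistic 0 and p = 1.
    """
    if len(low_records) == 0 or len(high_records) == 0:
        raise UsageError("both arms must be nonempty")
    t_lo, e_lo = _to_arrays(low_records)
    t_hi, e_hi = _to_arrays(high_records)
    return _logrank_arrays(t_lo, e_lo, t_hi, e_hi)


def _logrank_arrays(t_lo, e_lo, t_hi, e_hi) -> LogrankResult:
    t = np.concatenate([t_lo, t_hi])
    e = np.concatenate([e_lo, e_hi])
    ut = np.unique(t[e])
    if ut.size == 0:
        return LogrankResult(0.0, 1.0, TIED)
    ts_all = np.sort(t)
    ts_hi = np.sort(t_hi)
    te_all = np.sort(t[e])
    te_hi = np.sort(t_hi[e_hi])
    n = t.size - np.searchsorted(ts_all, ut, side="left")
    n_hi = t_hi.size - np.searchsorted(ts_hi, ut, side="left")
    d = np.searchsorted(te_all, ut, side="right") - np.searchsorted(
        te_all, ut, side="left"
    )
    d_hi = np.searchsorted(te_hi, ut, side="right") - np.searchsorted(
        te_hi, ut, side="left"
    )
    frac = n_hi / n
    oe = d_hi - d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n > 1, d * frac * (1.0 - frac) * (n - d) / (n - 1.0), 0.0)
    u_sum = float(oe.sum())
    v_sum = float(v.sum())
    if v_sum <= 0.0:
        return LogrankResult(0.0, 1.0, TIED)
    statistic = u_sum * u_sum / v_sum
    p = float(stats.chi2.sf(statistic, df=1))
    p = max(p, _TINY_P)
    if u_sum < 0:
        direction = HIGH_BETTER
    elif u_sum > 0:
        direction = LOW_BETTER
    else:
        direction = TIED
    return LogrankResult(statistic, p, direction)


def bh_adjust(p_values, fdr: float = DEFAULT_GENE_FDR) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags at the
    given FDR.  Applied within one cancer-drug group."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, q = fdrcorrection(p, alpha=fdr, method="indep")
    return q, reject


def screen_group(
    group: PatientGroup,
    binary: BinaryMatrix,
    survival: list[SurvivalRecord],
    min_per_arm: int = DEFAULT_MIN_PER_ARM,
    fdr: float = DEFAULT_GENE_FDR,
) -> tuple[list[GeneSurvivalResult], ScreenSummary]:
    """Log-rank screen of every testable gene within one patient group.

    A gene is testable when it is non-degenerate and has at least
    ``min_per_arm`` low and ``min_per_arm`` high expressors among the group
    patients with survival records.  q-values are BH step-up within the
    group.  Patients lacking a survival record are dropped from the group.
    """
    surv_by_pid = {r.patient_id: r for r in survival}
    pids = sorted(
        p for p in group.patient_ids if p in surv_by_pid and p in binary.calls.columns
    )
    times = np.asarray([surv_by_pid[p].time for p in pids])
    events = np.asarray([surv_by_pid[p].event for p in pids])
    calls = binary.calls[pids].to_numpy()
    degenerate = binary.thresholds.isna().to_numpy()

    results: list[GeneSurvivalResult] = []
    for i, gene in enumerate(binary.gene_ids):
        if degenerate[i]:
            continue
        hi = calls[i]
        n_high = int(hi.sum())
        n_low = len(pids) - n_high
        if n_low < min_per_arm or n_high < min_per_arm:
            continue
        lr = _logrank_arrays(times[~hi], events[~hi], times[hi], events[hi])
        results.append(
            GeneSurvivalResult(
                cancer=group.cancer,
                drug=group.drug,
                gene_id=gene,
                n_low=n_low,
                n_high=n_high,
                statistic=lr.statistic,
                p_value=lr.p_value,
                direction=lr.direction,
            )
        )
    q, sig = bh_adjust([r.p_value for r in results], fdr=fdr)
    results = [
        GeneSurvivalResult(
            cancer=r.cancer,
            drug=r.drug,
            gene_id=r.gene_id,
            n_low=r.n_low,
            n_high=r.n_high,
            statistic=r.statistic,
            p_value=r.p_value,
            q_value=float(qi),
            direction=r.direction,
            significant=bool(si),
        )
        for r, qi, si in zip(results, q, sig)
    ]
    summary = ScreenSummary(
        cancer=group.cancer,
        drug=group.drug,
        n_patients=len(pids),
        genes_tested=len(results),
        genes_significant=int(sum(r.significant for r in results)),
    )
    return results, summary


def results_to_frame(results: list[GeneSurvivalResult]) -> pd.DataFrame:
    """Tabulate screen results, sorted by (cancer, drug, p, gene)."""
    df = pd.DataFrame(
        [
            {
                "cancer": r.cancer,
                "drug": r.drug,
                "gene_id": r.gene_id,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "cancer",
            "drug",
            "gene_id",
            "n_low",
            "n_high",
            "statistic",
            "p_value",
            "q_value",
            "direction",
            "significant",
        ],
    )
    if len(df):
        df = df.sort_values(["cancer", "drug", "p_value", "gene_id"]).reset_index(
            drop=True
        )
    return df
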