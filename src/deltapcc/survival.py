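"""Kaplan-Meier stratification by a pair's dPCC.

Patients are split at the median dPCC of the chosen RNA-miRNA pair into
high and low strata and their survival compared with the two-group
log-rank test. The comparison is run twice -- once in the cohort that
metastasized to the chosen site and once in the cohort that did not --
so a pair can be judged prognostic in a site-dependent way. Each cohort
is split at its own median.

Estimation and testing go through lifelines; this module adds the
median-split convention (ties to "low"), the dual-cohort orchestration,
and a permutation option for small cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import MetastasisAnnotation
from .engine import DeltaPccTensor
from .sites import partition_groups

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "stratify_by_median",
    "km_estimator",
    "logrank_test",
    "dual_site_km",
    "DualKmResult",
]


@dataclass
class SurvivalRecord:
    """One patient's time-to-event outcome.

    ``event`` is True for an observed death/event, False for censoring.
    """

    sample_id: str
    time: float
    event: bool
    stratum: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"invalid survival time {self.time} for {self.sample_id}")


@dataclass
class KmCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event, step function thereafter."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def stratify_by_median(delta_values: Mapping[str, float]) -> dict[str, str]:
    """Median split: strictly above the median -> "high", else -> "low".

    Values exactly at the median join the low stratum (fixed convention
    so the split is deterministic). All-identical values admit no split
    and raise; an empty stratum triggers a warning.
    """
    if len(delta_values) < 2:
        raise ValueError("need at least 2 samples to stratify")
    vals = np.array(list(delta_values.values()), dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all dPCC values identical: no median split possible")
    med = float(np.median(vals))
    strata = {s: ("high" if v > med else "low") for s, v in delta_values.items()}
    labels = set(strata.values())
    if len(labels) < 2:
        warnings.warn("degenerate median split: one stratum is empty", stacklevel=2)
    return strata


def km_estimator(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimate for one group of records."""
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = np.asarray(table.index[mask], dtype=float)
    at_risk = np.asarray(table.loc[mask, "at_risk"], dtype=int)
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    return KmCurve(event_times=event_times, survival=surv, at_risk=at_risk, n=len(records))


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    With ``permutations`` > 0 the p-value is instead estimated by
    permuting group labels (useful when risk sets are tiny and the
    chi-square approximation is doubtful).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta = np.array([r.time for r in group_a]); ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time for r in group_b]); eb = np.array([r.event for r in group_b], dtype=bool)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test needs at least one observed event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    if permutations <= 0:
        return chi2, float(res.p_value)

    rng = rng or np.random.default_rng()
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    na = len(ta)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(times))
        pa, pb = perm[:na], perm[na:]
        stat = float(_ll_logrank(times[pa], times[pb],
                                 event_observed_A=events[pa],
                                 event_observed_B=events[pb]).test_statistic)
        if stat >= chi2 - 1e-12:
            hits += 1
    return chi2, (hits + 1) / (permutations + 1)


@dataclass
class CohortKm:
    """KM comparison of the high/low dPCC strata within one cohort."""

    evaluable: bool
    reason: str = ""
    n_high: int = 0
    n_low: int = 0
    curves: dict[str, KmCurve] = field(default_factory=dict)
    chi2: float = float("nan")
    p_value: float = float("nan")


@dataclass
class DualKmResult:
    pair: tuple[str, str]
    site: str
    site_positive: CohortKm
    site_negative: CohortKm


def _cohort_km(sample_ids: list[str], delta: Mapping[str, float],
               clinical: Mapping[str, SurvivalRecord]) -> CohortKm:
    ids = [s for s in sample_ids if s in clinical and s in delta]
    if len(ids) < 2:
        return CohortKm(evaluable=False, reason=f"cohort has {len(ids)} usable samples (< 2)")
    values = {s: delta[s] for s in ids}
    try:
        strata = stratify_by_median(values)
    except ValueError as exc:
        return CohortKm(evaluable=False, reason=str(exc))
    high = [clinical[s] for s in ids if strata[s] == "high"]
    low = [clinical[s] for s in ids if strata[s] == "low"]
    if not high or not low:
        return CohortKm(evaluable=False, reason="degenerate median split: one stratum empty")
    try:
        chi2, p = logrank_test(high, low)
    except ValueError as exc:
        return CohortKm(evaluable=False, reason=str(exc), n_high=len(high), n_low=len(low))
    return CohortKm(
        evaluable=True, n_high=len(high), n_low=len(low),
        curves={"high": km_estimator(high), "low": km_estimator(low)},
        chi2=chi2, p_value=p,
    )


def dual_site_km(
    pair: tuple[str, str],
    site: str,
    tensor: DeltaPccTensor,
    annotation: MetastasisAnnotation,
    clinical: Mapping[str, SurvivalRecord] | Sequence[SurvivalRecord],
) -> DualKmResult:
    """Median-dPCC KM comparison in the site-positive and site-negative cohorts.

    Each cohort is stratified at its own median of the pair's dPCC.
    Cohorts too small (or unsplittable) come back flagged not evaluable
    rather than raising.
    """
    if not isinstance(clinical, Mapping):
        clinical = {r.sample_id: r for r in clinical}
    delta = tensor.sample_values(pair)
    pos_ids, neg_ids = partition_groups(annotation, site)
    return DualKmResult(
        pair=pair, site=site,
        site_positive=_cohort_km(pos_ids, delta, clinical),
        site_negative=_cohort_km(neg_ids, delta, clinical),
    )


def plot_dual_km(result: DualKmResult, path: str) -> None:
    """Save a two-panel KM figure (site-positive above, site-negative below)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(6, 8), sharex=True)
    for ax, (label, cohort) in zip(
        axes, [("with metastasis at site", result.site_positive),
               ("without metastasis at site", result.site_negative)]
    ):
        if not cohort.evaluable:
            ax.text(0.5, 0.5, f"not evaluable: {cohort.reason}", ha="center", va="center")
        else:
            for stratum, curve in cohort.curves.items():
                t = np.concatenate([[0.0], curve.event_times])
                s = np.concatenate([[1.0], curve.survival])
                ax.step(t, s, where="post", label=f"{stratum} dPCC")
            ax.legend()
            ax.set_title(f"{label}  (log-rank p={cohort.p_value:.3g})")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
    axes[-1].set_xlabel("time (days)")
    fig.suptitle(f"{result.pair[0]} - {result.pair[1]}, site: {result.site}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
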