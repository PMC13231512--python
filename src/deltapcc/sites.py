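"""Metastatic-site-specific pair screening.

For each site, metastatic tumour samples are split into those that
spread to the site and those that did not, and every pair's dPCC
distribution is compared between the two groups with a two-sided
Mann-Whitney U test (dPCC is not normally distributed, so a rank test
is appropriate). Pairs with raw p < 0.001 are called site-specific; no
multiple-testing correction is applied, a stringent raw threshold being
preferred so that rare sites with tiny cohorts are not excluded outright
-- the number of tests performed is reported so users can post-correct.

Also here: per-site unique-pair accounting within a cancer type,
exclusive cross-cancer intersections (UpSet semantics), and export of
the top-k network of lowest-p pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import MetastasisAnnotation
from .engine import DeltaPccTensor

logger = logging.getLogger(__name__)

__all__ = [
    "SitePairResult",
    "SiteTestReport",
    "SiteNetwork",
    "partition_groups",
    "mann_whitney_u",
    "test_site_pairs",
    "site_unique_pairs",
    "cross_cancer_intersection",
    "build_network",
]

EXACT_POOLED_MAX = 12  # exact enumeration below this pooled size (no ties)


@dataclass(frozen=True)
class SitePairResult:
    rna_id: str
    mirna_id: str
    site: str
    u_stat: float
    p_value: float
    n_site: int
    n_other: int
    effect: float  # difference of group medians of dPCC (site minus other)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.rna_id, self.mirna_id)


@dataclass
class SiteTestReport:
    """All screening output for one site, including the test count."""

    site: str
    n_site: int
    n_other: int
    n_tests: int
    alpha: float
    results: list[SitePairResult] = field(default_factory=list)
    skipped: bool = False
    skip_reason: str = ""

    def significant_pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.results}


def partition_groups(annotation: MetastasisAnnotation, site: str) -> tuple[list[str], list[str]]:
    """Split the metastatic universe into site-positive and site-negative ids.

    A sample with several site labels is site-positive for each of them.
    """
    from .containers import normalize_site_name

    if not site or not site.strip():
        raise ValueError("site name must be non-empty")
    target = normalize_site_name(site)
    pos = [s for s in annotation.universe if target in annotation.sites_of(s)]
    neg = [s for s in annotation.universe if target not in annotation.sites_of(s)]
    return pos, neg


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group ``a`` versus ``b``.

    U is the statistic of the first group (rank sums with midranks for
    ties). The p-value is from exact enumeration when the pooled sample
    is small (<= 12) and tie-free, otherwise from the normal
    approximation with tie and continuity corrections. A pooled sample
    that is entirely constant carries no rank information and returns
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0
    if pooled.size <= EXACT_POOLED_MAX and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _vectorized_mwu(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided MWU for (k, n1) vs (k, n2), asymptotic path."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=1)
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    pooled = np.concatenate([A, B], axis=1)
    flat = np.ptp(pooled, axis=1) == 0
    if np.any(flat):
        u[flat] = A.shape[1] * B.shape[1] / 2.0
        p[flat] = 1.0
    return u, np.minimum(p, 1.0)


def test_site_pairs(
    tensor: DeltaPccTensor,
    annotation: MetastasisAnnotation,
    site: str,
    alpha: float = 0.001,
    min_site_n: int = 5,
) -> SiteTestReport:
    """Screen every pair for a site-specific dPCC shift.

    Sites with fewer than ``min_site_n`` positive samples (or no
    negative samples) are skipped entirely, with the reason logged.
    Returned results are the pairs with raw p < ``alpha``, sorted by
    (p, -|effect|, rna_id, mirna_id).
    """
    pos_ids, neg_ids = partition_groups(annotation, site)
    missing = set(annotation.universe) - set(tensor.tumour_ids)
    if missing:
        raise KeyError(f"annotated samples missing from tensor: {sorted(missing)[:5]}")

    report = SiteTestReport(site=site, n_site=len(pos_ids), n_other=len(neg_ids),
                            n_tests=0, alpha=alpha)
    if len(pos_ids) < min_site_n:
        report.skipped = True
        report.skip_reason = f"site has {len(pos_ids)} samples, below minimum {min_site_n}"
        logger.info("site %r skipped: %s", site, report.skip_reason)
        return report
    if len(neg_ids) < 1:
        report.skipped = True
        report.skip_reason = "no site-negative samples"
        logger.info("site %r skipped: %s", site, report.skip_reason)
        return report
    if len(neg_ids) < min_site_n:
        logger.warning("site %r: only %d site-negative samples", site, len(neg_ids))

    col = {s: i for i, s in enumerate(tensor.tumour_ids)}
    A = tensor.values[:, [col[s] for s in pos_ids]]
    B = tensor.values[:, [col[s] for s in neg_ids]]
    n1, n2 = A.shape[1], B.shape[1]

    if n1 + n2 <= EXACT_POOLED_MAX:
        u = np.empty(A.shape[0])
        p = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            u[i], p[i] = mann_whitney_u(A[i], B[i])
    else:
        u, p = _vectorized_mwu(A, B)

    effect = np.median(A, axis=1) - np.median(B, axis=1)
    report.n_tests = A.shape[0]
    hits = np.flatnonzero(p < alpha)
    results = [
        SitePairResult(
            rna_id=tensor.pair_index[i][0], mirna_id=tensor.pair_index[i][1],
            site=site, u_stat=float(u[i]), p_value=float(p[i]),
            n_site=n1, n_other=n2, effect=float(effect[i]),
        )
        for i in hits
    ]
    results.sort(key=lambda r: (r.p_value, -abs(r.effect), r.rna_id, r.mirna_id))
    report.results = results
    logger.info("site %r: %d of %d pairs significant at alpha=%g", site, len(results), report.n_tests, alpha)
    return report


def site_unique_pairs(
    per_site: dict[str, set[tuple[str, str]]],
) -> dict[str, tuple[int, int, set[tuple[str, str]]]]:
    """Per-site (total, unique, unique set) within one cancer type.

    A pair is unique to a site when it is significant there and at no
    other site of the same cancer type.
    """
    out: dict[str, tuple[int, int, set[tuple[str, str]]]] = {}
    for site, pairs in per_site.items():
        others: set[tuple[str, str]] = set()
        for s2, p2 in per_site.items():
            if s2 != site:
                others |= p2
        unique = pairs - others
        out[site] = (len(pairs), len(unique), unique)
    return out


def cross_cancer_intersection(
    per_cancer: dict[str, set[tuple[str, str]]],
) -> dict[frozenset[str], int]:
    """Exclusive intersection counts across cancer types (UpSet semantics).

    For each non-empty combination of cancer types, counts the pairs
    present in exactly those sets; counts sum to the size of the union.
    """
    if not per_cancer:
        raise ValueError("need at least one cancer type")
    membership: dict[tuple[str, str], frozenset[str]] = {}
    for cancer, pairs in per_cancer.items():
        for p in pairs:
            membership[p] = membership.get(p, frozenset()) | {cancer}
    counts: dict[frozenset[str], int] = {}
    for combo in membership.values():
        counts[combo] = counts.get(combo, 0) + 1
    return counts


@dataclass
class SiteNetwork:
    """Top-k lowest-p pairs for one (cancer type, site) as a bipartite network."""

    site: str
    cancer_type: str
    edges: list[SitePairResult]

    @property
    def rna_nodes(self) -> list[str]:
        return sorted({e.rna_id for e in self.edges})

    @property
    def mirna_nodes(self) -> list[str]:
        return sorted({e.mirna_id for e in self.edges})

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(site=self.site, cancer_type=self.cancer_type)
        for e in self.edges:
            g.add_node(e.rna_id, type="RNA")
            g.add_node(e.mirna_id, type="miRNA")
            g.add_edge(e.rna_id, e.mirna_id, p_value=e.p_value, effect=e.effect)
        return g


def build_network(results: list[SitePairResult], top_k: int = 100,
                  site: str = "", cancer_type: str = "") -> SiteNetwork:
    """Keep the ``top_k`` edges after the deterministic p/effect/id sort."""
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    ordered = sorted(results, key=lambda r: (r.p_value, -abs(r.effect), r.rna_id, r.mirna_id))
    return SiteNetwork(site=site, cancer_type=cancer_type, edges=ordered[:top_k])
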