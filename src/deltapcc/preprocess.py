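"""Expression preprocessing: normalization, filtering, sample matching.

RNA expression arrives as TPM and miRNA expression as raw counts that are
CPM-normalized here (miRNAs are short and fairly uniform in length, so
depth-only normalization keeps them on a scale comparable to TPM).
Features that do not vary across the normal cohort carry no correlation
signal and are removed before any Pearson statistics are formed.
RNA-seq and miRNA-seq aliquots are paired at the vial level of TCGA-style
barcodes so both measurements come from the same biological specimen;
plain sample ids fall back to exact-string matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .containers import CohortSummary, ExpressionMatrix, MetastasisAnnotation, normalize_site_name

logger = logging.getLogger(__name__)

__all__ = [
    "SampleBarcode",
    "cpm_normalize",
    "filter_zero_variance",
    "match_samples",
    "select_portion",
    "check_cancer_eligibility",
    "build_annotation",
]


@dataclass(frozen=True)
class SampleBarcode:
    """A TCGA-style hyphen-delimited sample barcode.

    ``vial_prefix`` is the first four fields (project-TSS-participant-
    sampleVial), the granularity at which RNA-seq and miRNA-seq aliquots
    are matched. ``portion_id`` is the fifth field when present.
    ``is_ffpe`` is True/False when known, None when unknown.
    """

    raw: str
    vial_prefix: str
    portion_id: str
    is_ffpe: bool | None = None

    @classmethod
    def parse(cls, raw: str, is_ffpe: bool | None = None) -> "SampleBarcode":
        fields = raw.split("-")
        if len(fields) >= 4:
            vial = "-".join(fields[:4])
            portion = fields[4] if len(fields) >= 5 else ""
        else:
            # plain (non-barcode) id: the whole string is the matching key
            vial = raw
            portion = ""
        return cls(raw=raw, vial_prefix=vial, portion_id=portion, is_ffpe=is_ffpe)

    @property
    def is_plain(self) -> bool:
        return self.vial_prefix == self.raw and "-" not in self.raw


class MatchReport(NamedTuple):
    pairs: list[tuple[str, str]]
    unmatched_rna: list[str]
    unmatched_mirna: list[str]


class FilterReport(NamedTuple):
    matrix: ExpressionMatrix
    removed: list[str]


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts Per Million: scale each sample so its column sum is 10^6.

    Raises
    ------
    ValueError
        If the input unit is not ``raw_count`` (``CPM`` is also
        accepted: re-normalizing is a no-op) or a sample has zero total
        counts (the sample is named in the message).
    """
    if counts.unit not in ("raw_count", "CPM"):
        raise ValueError(f"cpm_normalize expects raw_count (or CPM) input, got {counts.unit}")
    totals = counts.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"cannot CPM-normalize samples with zero total counts: {bad}")
    values = counts.values / totals[np.newaxis, :] * 1e6
    return ExpressionMatrix(values, counts.feature_ids, counts.sample_ids, "CPM", counts.sample_class)


def filter_zero_variance(m: ExpressionMatrix, normal_ids: Sequence[str]) -> FilterReport:
    """Drop features constant across the normal samples.

    Uses the exact min == max criterion (variance exactly zero); the
    sample set is unchanged. Returns the filtered matrix and the list of
    removed feature ids.
    """
    normal_ids = list(normal_ids)
    if len(normal_ids) < 2:
        raise ValueError("zero-variance filtering needs at least 2 normal samples")
    idx = m._sample_indices(normal_ids)
    sub = m.values[:, idx]
    keep_mask = sub.min(axis=1) < sub.max(axis=1)
    removed = [f for f, k in zip(m.feature_ids, keep_mask) if not k]
    kept = [f for f, k in zip(m.feature_ids, keep_mask) if k]
    logger.info("filter_zero_variance: removed %d of %d features", len(removed), m.n_features)
    out = ExpressionMatrix(m.values[keep_mask, :], kept, m.sample_ids, m.unit, m.sample_class)
    return FilterReport(out, removed)


def select_portion(candidates: Sequence[SampleBarcode]) -> SampleBarcode:
    """Pick one aliquot per vial: prefer non-FFPE, then earliest portion id.

    Portions known to be FFPE-free are preferred; if every candidate is
    FFPE or of unknown status, all compete. Ties resolve to the
    lexicographically smallest ``portion_id`` (then smallest raw id, so
    the choice is independent of input order).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("select_portion: empty candidate list")
    prefixes = {c.vial_prefix for c in candidates}
    if len(prefixes) != 1:
        raise ValueError(f"select_portion: mixed vial prefixes {sorted(prefixes)}")
    non_ffpe = [c for c in candidates if c.is_ffpe is False]
    eligible = non_ffpe if non_ffpe else candidates
    return min(eligible, key=lambda c: (c.portion_id, c.raw))


def match_samples(
    rna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    ffpe_flags: dict[str, bool] | None = None,
) -> MatchReport:
    """Pair RNA and miRNA samples originating from the same specimen.

    Samples are matched on equal vial prefix (or exact id equality for
    plain ids); when several portions share a vial, one is chosen per
    side by :func:`select_portion`. Unmatched samples are reported and
    logged, never silently dropped.
    """
    ffpe_flags = ffpe_flags or {}

    def by_vial(ids: Iterable[str]) -> dict[str, list[SampleBarcode]]:
        groups: dict[str, list[SampleBarcode]] = {}
        for sid in ids:
            bc = SampleBarcode.parse(sid, is_ffpe=ffpe_flags.get(sid))
            groups.setdefault(bc.vial_prefix, []).append(bc)
        return groups

    rna_groups = by_vial(rna.sample_ids)
    mirna_groups = by_vial(mirna.sample_ids)
    shared = sorted(set(rna_groups) & set(mirna_groups))
    pairs = [
        (select_portion(rna_groups[v]).raw, select_portion(mirna_groups[v]).raw)
        for v in shared
    ]
    matched_rna = {r for r, _ in pairs}
    matched_mirna = {m for _, m in pairs}
    unmatched_rna = [s for s in rna.sample_ids if s not in matched_rna]
    unmatched_mirna = [s for s in mirna.sample_ids if s not in matched_mirna]
    if unmatched_rna or unmatched_mirna:
        logger.info(
            "match_samples: %d pairs; unmatched %d RNA, %d miRNA samples",
            len(pairs), len(unmatched_rna), len(unmatched_mirna),
        )
    return MatchReport(pairs, unmatched_rna, unmatched_mirna)


def check_cancer_eligibility(summary: CohortSummary, has_followup_sites: bool) -> tuple[bool, list[str]]:
    """Apply the three cohort-eligibility criteria for a cancer type.

    Eligible iff metastatic-site information exists in follow-up data,
    at least 10 normal samples are present, and at least one metastatic
    site has five or more samples.
    """
    reasons: list[str] = []
    if not has_followup_sites:
        reasons.append("no metastatic-site information in follow-up data")
    if summary.n_normal < 10:
        reasons.append(f"normals < 10 (found {summary.n_normal})")
    max_site = max(summary.site_counts.values(), default=0)
    if max_site < 5:
        reasons.append(f"no metastatic site with >= 5 samples (max {max_site})")
    return (not reasons, reasons)


def build_annotation(
    diagnosis_rows: Iterable[tuple[str, str]],
    followup_rows: Iterable[tuple[str, str]],
    metastatic_samples: Iterable[str] = (),
) -> MetastasisAnnotation:
    """Merge diagnosis and follow-up site records into one annotation.

    Site sets are unioned per sample across both sources after name
    normalization. ``metastatic_samples`` adds samples known to have
    metastasis information but no site rows; they enter the universe
    with an empty site set (and so count as site-negative everywhere).
    """
    sites: dict[str, set[str]] = {}
    for sid, site in list(diagnosis_rows) + list(followup_rows):
        name = normalize_site_name(site)
        if not name:
            continue
        sites.setdefault(sid, set()).add(name)
    universe = sorted(set(sites) | set(metastatic_samples))
    return MetastasisAnnotation(
        sites={sid: frozenset(ss) for sid, ss in sites.items()},
        universe=universe,
    )
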