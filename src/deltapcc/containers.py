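"""Core in-memory containers shared across the pipeline.

The pipeline moves expression data through three representations: an
:class:`ExpressionMatrix` (features x samples, TPM/CPM/raw counts), a
:class:`MetastasisAnnotation` (which tumour samples spread to which
anatomical sites), and the per-pair differential-correlation tensor
produced by the engine (see :mod:`deltapcc.engine`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "MetastasisAnnotation",
    "CohortSummary",
    "normalize_site_name",
]

VALID_UNITS = ("TPM", "CPM", "raw_count")
VALID_CLASSES = ("normal", "tumour")


def normalize_site_name(name: str) -> str:
    """Canonicalize a metastatic-site label: case-fold, trim, collapse spaces."""
    return " ".join(name.strip().casefold().split())


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of non-negative expression values.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Finite, non-negative expression values.
    feature_ids, sample_ids : list of str
        Unique, ordered identifiers for rows and columns.
    unit : {"TPM", "CPM", "raw_count"}
    sample_class : dict, optional
        Per-sample label, ``"normal"`` or ``"tumour"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    unit: str
    sample_class: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (features x samples)")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature_ids")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.sample_class is not None:
            bad = {v for v in self.sample_class.values()} - set(VALID_CLASSES)
            if bad:
                raise ValueError(f"invalid sample classes: {sorted(bad)}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def _sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = self._sample_indices(sample_ids)
        cls = None
        if self.sample_class is not None:
            cls = {s: self.sample_class[s] for s in sample_ids if s in self.sample_class}
        return ExpressionMatrix(self.values[:, idx], self.feature_ids, list(sample_ids), self.unit, cls)

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        idx = np.array([pos[f] for f in feature_ids], dtype=int)
        return ExpressionMatrix(self.values[idx, :], list(feature_ids), self.sample_ids, self.unit, self.sample_class)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self._sample_indices([sample_id])[0]]

    def samples_of_class(self, cls: str) -> list[str]:
        if self.sample_class is None:
            return []
        return [s for s in self.sample_ids if self.sample_class.get(s) == cls]


@dataclass
class MetastasisAnnotation:
    """Map from tumour sample id to its set of metastatic-site names.

    ``universe`` lists every tumour sample with metastasis information,
    including samples whose site set is empty; group comparisons for a
    site partition this universe into site-positive and site-negative.
    """

    sites: dict[str, frozenset[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        self.universe = list(self.universe)
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate sample ids in universe")
        extra = set(self.sites) - uni
        if extra:
            raise ValueError(f"annotated samples not in universe: {sorted(extra)[:5]}")
        norm: dict[str, frozenset[str]] = {}
        for sid, ss in self.sites.items():
            cleaned = frozenset(normalize_site_name(s) for s in ss if normalize_site_name(s))
            norm[sid] = cleaned
        self.sites = norm

    def sites_of(self, sample_id: str) -> frozenset[str]:
        return self.sites.get(sample_id, frozenset())

    def all_sites(self) -> list[str]:
        out: set[str] = set()
        for ss in self.sites.values():
            out |= ss
        return sorted(out)

    def site_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sid in self.universe:
            for s in self.sites_of(sid):
                counts[s] = counts.get(s, 0) + 1
        return counts


@dataclass
class CohortSummary:
    """Per-cancer-type sample accounting used by the eligibility check."""

    n_normal: int
    n_tumour: int
    n_metastatic: int
    site_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_tumour, self.n_metastatic, *([0] + list(self.site_counts.values()))) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_metastatic > self.n_tumour:
            raise ValueError("n_metastatic cannot exceed n_tumour")

    @classmethod
    def from_annotation(cls, annotation: MetastasisAnnotation, n_normal: int, n_tumour: int) -> "CohortSummary":
        return cls(
            n_normal=n_normal,
            n_tumour=n_tumour,
            n_metastatic=len(annotation.universe),
            site_counts=annotation.site_counts(),
        )
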