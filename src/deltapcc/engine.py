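r"""Single-sample differential Pearson correlation (dPCC) engine.

For each (RNA, miRNA) pair the baseline Pearson correlation PCC_n is
computed over the n normal samples. Appending one tumour sample gives
PCC_{n+1}, and the pair's differential correlation for that sample is

    dPCC = PCC_{n+1} - PCC_n.

Recomputing PCC_{n+1} from raw expression for every tumour sample costs
O(t * n * k) time for t tumour samples and k pairs and requires keeping
the full normal matrix in memory. Instead, the normal cohort is reduced
once to sufficient statistics -- per-feature means and sums of squared
deviations (SS), plus the per-pair covariance numerator (CN):

    SS_X = sum_i (X_i - Xbar)^2,   CN = sum_i (X_i - Xbar)(Y_i - Ybar).

Appending a single point (x, y) updates these in closed form with the
single-point covariance factor n/(n+1):

    PCC_{n+1} = [CN + (n/(n+1)) (x - Xbar)(y - Ybar)]
                / sqrt(SS_X + (n/(n+1)) (x - Xbar)^2)
                / sqrt(SS_Y + (n/(n+1)) (y - Ybar)^2)

which makes every tumour sample O(k) and the retained state O(k),
independent of n. This is exact: it agrees with brute-force
recomputation over the n+1 samples to floating-point precision, and the
brute-force path (:func:`pcc_matrix`) is kept as the engine's oracle.

A variant that drops the n/(n+1) factor from the numerator only (while
keeping it in the denominators) circulates in the literature; it is
available via ``as_printed=True`` for comparison but is not exact and is
never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "NormalStats",
    "DeltaPccTensor",
    "pcc_matrix",
    "precompute_normal_stats",
    "delta_pcc_sample",
    "delta_pcc_all",
]


def _centered(m: ExpressionMatrix, sample_ids: Sequence[str], kind: str):
    """Return (sorted feature ids, centered values, means, SS) over sample_ids."""
    order = sorted(range(m.n_features), key=lambda i: m.feature_ids[i])
    ids = [m.feature_ids[i] for i in order]
    idx = m._sample_indices(list(sample_ids))
    vals = m.values[np.ix_(order, idx)]
    mean = vals.mean(axis=1)
    centered = vals - mean[:, None]
    ss = np.einsum("ij,ij->i", centered, centered)
    bad = np.flatnonzero(vals.min(axis=1) >= vals.max(axis=1))
    if bad.size:
        names = [ids[i] for i in bad[:5]]
        raise ValueError(f"zero-variance {kind} feature(s) on the given samples: {names}")
    return ids, centered, mean, ss


@dataclass
class NormalStats:
    """Sufficient statistics of the normal cohort: the O(k) engine state.

    Feature ids are frozen in lexicographic order so the flattened pair
    index (RNA-major) is reproducible across runs.
    """

    n: int
    rna_ids: list[str]
    mirna_ids: list[str]
    rna_mean: np.ndarray
    mirna_mean: np.ndarray
    rna_ss: np.ndarray
    mirna_ss: np.ndarray
    cn: np.ndarray      # (R, M) covariance numerators
    pcc_n: np.ndarray   # (R, M) baseline correlations

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 normal samples")
        if np.any(self.rna_ss <= 0) or np.any(self.mirna_ss <= 0):
            raise ValueError("zero-variance features must be filtered before precompute")
        if np.any(np.abs(self.pcc_n) > 1 + 1e-12):
            raise ValueError("baseline PCC outside [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.rna_ids) * len(self.mirna_ids)

    def pair_index(self) -> list[tuple[str, str]]:
        return [(r, m) for r in self.rna_ids for m in self.mirna_ids]

    def nbytes(self) -> int:
        """Size of the retained numeric state (independent of n)."""
        arrays = (self.rna_mean, self.mirna_mean, self.rna_ss, self.mirna_ss, self.cn, self.pcc_n)
        return int(sum(a.nbytes for a in arrays))


@dataclass
class DeltaPccTensor:
    """dPCC values for k pairs x t tumour samples."""

    values: np.ndarray
    pair_index: list[tuple[str, str]]
    tumour_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pair_index), len(self.tumour_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pair_index)} pairs x {len(self.tumour_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("dPCC values must be finite")
        if self.values.size and np.any(np.abs(self.values) > 2 + 1e-9):
            raise ValueError("dPCC values outside [-2, 2]")

    def row(self, rna_id: str, mirna_id: str) -> np.ndarray:
        try:
            i = self.pair_index.index((rna_id, mirna_id))
        except ValueError:
            raise KeyError(f"pair ({rna_id}, {mirna_id}) not in tensor") from None
        return self.values[i]

    def sample_values(self, pair: tuple[str, str]) -> dict[str, float]:
        r = self.row(*pair)
        return {sid: float(v) for sid, v in zip(self.tumour_ids, r)}


def pcc_matrix(rna: ExpressionMatrix, mirna: ExpressionMatrix, sample_ids: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Brute-force all-pairs Pearson correlation over exactly sample_ids.

    This is the definitional path used as the oracle for the incremental
    engine. Returns (R x M correlation matrix, sorted RNA ids, sorted
    miRNA ids).
    """
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples for a correlation")
    rids, xc, _, ssx = _centered(rna, sample_ids, "RNA")
    mids, yc, _, ssy = _centered(mirna, sample_ids, "miRNA")
    cn = xc @ yc.T
    pcc = cn / np.sqrt(ssx)[:, None] / np.sqrt(ssy)[None, :]
    return pcc, rids, mids


def precompute_normal_stats(rna: ExpressionMatrix, mirna: ExpressionMatrix, normal_ids: Sequence[str]) -> NormalStats:
    """Reduce the normal cohort to the engine's sufficient statistics.

    After this call the normal expression matrices are no longer needed:
    every subsequent per-sample update consumes only the returned state.
    """
    normal_ids = list(normal_ids)
    if len(normal_ids) < 2:
        raise ValueError("need at least 2 normal samples")
    rids, xc, xmean, ssx = _centered(rna, normal_ids, "RNA")
    mids, yc, ymean, ssy = _centered(mirna, normal_ids, "miRNA")
    cn = xc @ yc.T
    pcc_n = cn / np.sqrt(ssx)[:, None] / np.sqrt(ssy)[None, :]
    return NormalStats(
        n=len(normal_ids),
        rna_ids=rids, mirna_ids=mids,
        rna_mean=xmean, mirna_mean=ymean,
        rna_ss=ssx, mirna_ss=ssy,
        cn=cn, pcc_n=np.clip(pcc_n, -1.0, 1.0),
    )


def delta_pcc_sample(
    stats: NormalStats,
    x_t: np.ndarray,
    y_t: np.ndarray,
    *,
    rna_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
    as_printed: bool = False,
) -> np.ndarray:
    """dPCC for one tumour sample against the normal baseline.

    ``x_t`` and ``y_t`` must be aligned to ``stats.rna_ids`` and
    ``stats.mirna_ids``; pass the id sequences to have the alignment
    verified. Returns an (R, M) matrix of PCC_{n+1} - PCC_n.
    """
    x_t = np.asarray(x_t, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if rna_ids is not None and list(rna_ids) != stats.rna_ids:
        raise ValueError("RNA feature order does not match engine state")
    if mirna_ids is not None and list(mirna_ids) != stats.mirna_ids:
        raise ValueError("miRNA feature order does not match engine state")
    if x_t.shape != (len(stats.rna_ids),) or y_t.shape != (len(stats.mirna_ids),):
        raise ValueError("tumour vectors are not aligned to the engine's feature order")
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(y_t))):
        raise ValueError("tumour expression values must be finite")

    n = stats.n
    f = n / (n + 1.0)
    dx = x_t - stats.rna_mean
    dy = y_t - stats.mirna_mean
    num_factor = 1.0 if as_printed else f
    num = stats.cn + num_factor * np.outer(dx, dy)
    den = np.sqrt(stats.rna_ss + f * dx**2)[:, None] * np.sqrt(stats.mirna_ss + f * dy**2)[None, :]
    pcc_new = num / den
    if not as_printed:
        pcc_new = np.clip(pcc_new, -1.0, 1.0)
    return pcc_new - stats.pcc_n


def delta_pcc_all(
    stats: NormalStats,
    tumour_rna: ExpressionMatrix,
    tumour_mirna: ExpressionMatrix,
    paired_ids: Sequence[tuple[str, str]] | Sequence[str],
    *,
    as_printed: bool = False,
) -> DeltaPccTensor:
    """dPCC for every pair and every paired tumour sample.

    ``paired_ids`` is a sequence of (rna_sample_id, mirna_sample_id)
    tuples (or bare ids used for both matrices). Consumes only the
    engine state, never normal expression. The tensor's tumour id is the
    RNA-side sample id of each pair.
    """
    pairs: list[tuple[str, str]] = [
        (p, p) if isinstance(p, str) else (p[0], p[1]) for p in paired_ids
    ]
    rpos = {s: i for i, s in enumerate(tumour_rna.sample_ids)}
    mpos = {s: i for i, s in enumerate(tumour_mirna.sample_ids)}
    missing = [p for p in pairs if p[0] not in rpos or p[1] not in mpos]
    if missing:
        raise KeyError(f"paired samples missing from tumour matrices: {missing[:5]}")

    rorder = sorted(range(tumour_rna.n_features), key=lambda i: tumour_rna.feature_ids[i])
    morder = sorted(range(tumour_mirna.n_features), key=lambda i: tumour_mirna.feature_ids[i])
    rids = [tumour_rna.feature_ids[i] for i in rorder]
    mids = [tumour_mirna.feature_ids[i] for i in morder]
    if rids != stats.rna_ids or mids != stats.mirna_ids:
        raise ValueError("tumour matrices do not carry the engine's feature set")

    k = stats.n_pairs
    out = np.empty((k, len(pairs)), dtype=float)
    for j, (rs, ms) in enumerate(pairs):
        x_t = tumour_rna.values[rorder, rpos[rs]]
        y_t = tumour_mirna.values[morder, mpos[ms]]
        out[:, j] = delta_pcc_sample(stats, x_t, y_t, as_printed=as_printed).ravel()
    return DeltaPccTensor(out, stats.pair_index(), [rs for rs, _ in pairs])
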