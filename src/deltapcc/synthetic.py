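"""Synthetic cohorts with planted correlation and survival effects.

Every downstream module is testable without any external download: the
generator emits normal and tumour expression, metastatic-site
annotations and a survival table, together with a truth ledger naming
the planted effects.

Expression model. Each feature has a latent standard-Gaussian value per
sample; designated (RNA_j, MIR_j) pairs share a latent correlation
``baseline_corr``. Latents map to a non-negative, right-skewed TPM/CPM-
like scale through exp(sigma * z + mu) with a modest sigma (0.5) so the
observed-scale Pearson correlation stays close to the latent target.
Tumour samples are drawn from the normal model; a planted site effect
then displaces the pair's two values in opposite directions (RNA up,
miRNA down, by ``shift`` latent SDs) in site-positive samples only,
which drives that pair's dPCC consistently negative there.

Survival model. Times are exponential. Within the prognostic pair's
designated site cohort the low-dPCC stratum (its own median split, the
same convention the analysis uses) has its hazard multiplied by the
planted hazard ratio; all other patients carry the base hazard, so the
site-negative cohort is a survival null. Censoring is independent
exponential with per-sample rate chosen so that the expected censored
fraction equals ``censor_rate`` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import ExpressionMatrix, MetastasisAnnotation
from .engine import precompute_normal_stats
from .survival import SurvivalRecord, stratify_by_median

__all__ = ["SyntheticSpec", "PlantedSitePair", "Cohort", "generate_cohort", "null_cohort", "truth_evaluation"]

LATENT_SIGMA = 0.5
LATENT_MU = 2.0
BASE_HAZARD = np.log(2) / 1000.0  # median survival ~1000 days at baseline


@dataclass(frozen=True)
class PlantedSitePair:
    rna_index: int
    mirna_index: int
    site: str
    shift: float


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults describe a small but realistic screening scenario: a
    cohort with tens of normals, a metastatic universe split across a
    few sites (each clearing the 5-sample screening minimum), moderate
    baseline co-expression for a handful of designated pairs, one
    strongly planted site-specific pair and one prognostic pair.
    """

    n_rna: int = 30
    n_mirna: int = 20
    n_normal: int = 30
    n_tumour: int = 40
    sites: dict[str, int] = field(default_factory=lambda: {"lung": 10, "bone": 10})
    baseline_corr: float = 0.5
    n_correlated: int = 5
    planted_site_pairs: list[PlantedSitePair] = field(
        default_factory=lambda: [PlantedSitePair(0, 0, "lung", 6.0)]
    )
    prognostic_pair: tuple[int, int] = (0, 0)
    prognostic_site: str = "lung"
    hazard_ratio: float = 6.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_rna, self.n_mirna) < 2 or self.n_normal < 2 or self.n_tumour < 1:
            raise ValueError("dimensions too small")
        if not -1 < self.baseline_corr < 1:
            raise ValueError("baseline_corr must be in (-1, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_correlated > min(self.n_rna, self.n_mirna):
            raise ValueError("n_correlated exceeds feature counts")
        for name, count in self.sites.items():
            if count > self.n_tumour:
                raise ValueError(f"site {name!r} count {count} exceeds n_tumour {self.n_tumour}")
        for p in self.planted_site_pairs:
            if p.rna_index >= self.n_rna or p.mirna_index >= self.n_mirna:
                raise ValueError(f"planted pair index out of range: {p}")
            if p.site not in self.sites:
                raise ValueError(f"planted pair site {p.site!r} not among sites")
        if self.hazard_ratio != 1.0 and self.prognostic_site not in self.sites:
            raise ValueError(f"prognostic site {self.prognostic_site!r} not among sites")
        if self.prognostic_pair[0] >= self.n_rna or self.prognostic_pair[1] >= self.n_mirna:
            raise ValueError("prognostic pair index out of range")


@dataclass
class Cohort:
    rna: ExpressionMatrix
    mirna: ExpressionMatrix
    annotation: MetastasisAnnotation
    clinical: list[SurvivalRecord]
    truth: dict

    @property
    def normal_ids(self) -> list[str]:
        return self.rna.samples_of_class("normal")

    @property
    def tumour_ids(self) -> list[str]:
        return self.rna.samples_of_class("tumour")


def _rna_id(i: int) -> str:
    return f"RNA{i:04d}"


def _mirna_id(i: int) -> str:
    return f"MIR{i:04d}"


def _latents(rng: np.random.Generator, spec: SyntheticSpec, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    zr = rng.standard_normal((spec.n_rna, n_samples))
    zm = rng.standard_normal((spec.n_mirna, n_samples))
    rho = spec.baseline_corr
    for j in range(spec.n_correlated):
        zm[j] = rho * zr[j] + np.sqrt(1 - rho**2) * zm[j]
    return zr, zm


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw one fully reproducible cohort from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    normal_ids = [f"N{i:03d}" for i in range(spec.n_normal)]
    tumour_ids = [f"T{i:03d}" for i in range(spec.n_tumour)]

    zr_n, zm_n = _latents(rng, spec, spec.n_normal)
    zr_t, zm_t = _latents(rng, spec, spec.n_tumour)

    # site memberships drawn before shifts so effects land on known samples
    site_members: dict[str, np.ndarray] = {}
    for site in sorted(spec.sites):
        site_members[site] = np.sort(rng.choice(spec.n_tumour, size=spec.sites[site], replace=False))

    for p in spec.planted_site_pairs:
        cols = site_members[p.site]
        zr_t[p.rna_index, cols] += p.shift
        zm_t[p.mirna_index, cols] -= p.shift

    def observe(z: np.ndarray) -> np.ndarray:
        return np.exp(LATENT_SIGMA * z + LATENT_MU)

    rna_ids = [_rna_id(i) for i in range(spec.n_rna)]
    mirna_ids = [_mirna_id(i) for i in range(spec.n_mirna)]
    sample_ids = normal_ids + tumour_ids
    classes = {s: "normal" for s in normal_ids} | {s: "tumour" for s in tumour_ids}
    rna = ExpressionMatrix(
        np.concatenate([observe(zr_n), observe(zr_t)], axis=1),
        rna_ids, sample_ids, "TPM", classes,
    )
    mirna = ExpressionMatrix(
        np.concatenate([observe(zm_n), observe(zm_t)], axis=1),
        mirna_ids, sample_ids, "CPM", classes,
    )

    sites_map = {
        tumour_ids[i]: frozenset(
            s for s, cols in site_members.items() if i in set(cols.tolist())
        )
        for i in range(spec.n_tumour)
    }
    annotation = MetastasisAnnotation(
        sites={k: v for k, v in sites_map.items() if v}, universe=tumour_ids,
    )

    clinical = _simulate_survival(spec, rng, rna, mirna, normal_ids, tumour_ids, annotation)

    truth = {
        "seed": spec.seed,
        "planted_site_pairs": [
            {"rna_id": _rna_id(p.rna_index), "mirna_id": _mirna_id(p.mirna_index),
             "site": p.site, "shift": p.shift}
            for p in spec.planted_site_pairs if p.shift != 0
        ],
        "prognostic": {
            "rna_id": _rna_id(spec.prognostic_pair[0]),
            "mirna_id": _mirna_id(spec.prognostic_pair[1]),
            "site": spec.prognostic_site,
            "hazard_ratio": spec.hazard_ratio,
        } if spec.hazard_ratio != 1.0 else None,
        "spec": {
            "n_rna": spec.n_rna, "n_mirna": spec.n_mirna,
            "n_normal": spec.n_normal, "n_tumour": spec.n_tumour,
            "sites": dict(spec.sites), "baseline_corr": spec.baseline_corr,
            "censor_rate": spec.censor_rate,
        },
    }
    return Cohort(rna=rna, mirna=mirna, annotation=annotation, clinical=clinical, truth=truth)


def _simulate_survival(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    rna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    normal_ids: list[str],
    tumour_ids: list[str],
    annotation: MetastasisAnnotation,
) -> list[SurvivalRecord]:
    hazards = {s: BASE_HAZARD for s in tumour_ids}
    if spec.hazard_ratio != 1.0:
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        ri, mi = _rna_id(spec.prognostic_pair[0]), _mirna_id(spec.prognostic_pair[1])
        r_idx = stats.rna_ids.index(ri)
        m_idx = stats.mirna_ids.index(mi)
        cohort = [s for s in tumour_ids if spec.prognostic_site in annotation.sites_of(s)]
        if len(cohort) >= 2:
            from .engine import delta_pcc_sample

            delta = {}
            for s in cohort:
                d = delta_pcc_sample(stats, rna.column(s), mirna.column(s))
                delta[s] = float(d[r_idx, m_idx])
            try:
                strata = stratify_by_median(delta)
            except ValueError:
                strata = {}
            for s, lab in strata.items():
                if lab == "low":
                    hazards[s] = BASE_HAZARD * spec.hazard_ratio

    records = []
    c = spec.censor_rate
    for s in tumour_ids:
        lam = hazards[s]
        t_event = rng.exponential(1.0 / lam)
        if c > 0:
            t_cens = rng.exponential((1.0 - c) / (lam * c))
            records.append(SurvivalRecord(s, min(t_event, t_cens), t_event <= t_cens))
        else:
            records.append(SurvivalRecord(s, t_event, True))
    return records


def null_cohort(spec: SyntheticSpec) -> Cohort:
    """The spec's cohort with every planted effect switched off."""
    null = dataclasses.replace(
        spec,
        planted_site_pairs=[dataclasses.replace(p, shift=0.0) for p in spec.planted_site_pairs],
        hazard_ratio=1.0,
    )
    return generate_cohort(null)


def truth_evaluation(
    per_site_significant: Mapping[str, set[tuple[str, str]]],
    truth: dict,
) -> dict[str, dict[str, float | None]]:
    """Precision/recall of significant calls against the planted ledger.

    Precision is None (reported as NA downstream) when a site has no
    significant calls; recall is None when nothing was planted there.
    """
    planted: dict[str, set[tuple[str, str]]] = {}
    for p in truth.get("planted_site_pairs", []):
        planted.setdefault(p["site"], set()).add((p["rna_id"], p["mirna_id"]))
    out: dict[str, dict[str, float | None]] = {}
    for site in set(per_site_significant) | set(planted):
        sig = set(per_site_significant.get(site, set()))
        tru = planted.get(site, set())
        hit = len(sig & tru)
        out[site] = {
            "precision": (hit / len(sig)) if sig else None,
            "recall": (hit / len(tru)) if tru else None,
            "n_significant": len(sig),
            "n_planted": len(tru),
        }
    return out
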