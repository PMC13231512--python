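"""Readers and writers for the pipeline's text formats.

Everything is tab-separated UTF-8 with "NA" for missing values:

* expression TSV -- first column ``feature_id``, then one column per
  sample; a sidecar metadata TSV carries ``sample_id``, ``class`` and
  optional barcode fields.
* clinical TSV -- ``sample_id``, ``time``, ``event`` (0/1).
* annotation TSV -- one (``sample_id``, ``metastatic_site``) row per
  sample-site membership; rows with empty site mark samples that have
  metastasis information but no recorded site.
* results TSV -- one row per significant pair.

Every output directory receives a ``manifest.json`` with package
version, configuration echo and SHA-256 digests of the inputs, so a
run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, MetastasisAnnotation
from .sites import SitePairResult, SiteTestReport
from .survival import SurvivalRecord
from .synthetic import Cohort

__all__ = [
    "read_expression", "write_expression",
    "read_metadata", "write_metadata",
    "read_clinical", "write_clinical",
    "read_annotation", "write_annotation",
    "write_site_results", "read_site_results",
    "write_cohort", "read_cohort",
    "write_manifest",
]

NA = "NA"


def _fmt(v: float) -> str:
    return repr(float(v))


def read_expression(path: str | Path, unit: str, sample_class: dict[str, str] | None = None) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):  # pandas would silently rename these
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample column(s) {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a feature_id column plus sample columns")
    feature_col = df.columns[0]
    features = df[feature_col].tolist()
    if len(set(features)) != len(features):
        dupes = df[feature_col][df[feature_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature id(s) {dupes[:5]}")
    samples = list(df.columns[1:])
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample column(s)")
    try:
        values = df[samples].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    return ExpressionMatrix(values, features, samples, unit, sample_class)


def write_expression(path: str | Path, m: ExpressionMatrix) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            fh.write(fid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Sample-class mapping from a metadata TSV (sample_id, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return dict(zip(df["sample_id"], df["class"]))


def write_metadata(path: str | Path, sample_class: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tclass\n")
        for sid, cls in sample_class.items():
            fh.write(f"{sid}\t{cls}\n")


def read_clinical(path: str | Path, time_col: str = "time", event_col: str = "event") -> dict[str, SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    for col in ("sample_id", time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    out = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = SurvivalRecord(
            sample_id=row["sample_id"],
            time=float(row[time_col]),
            event=bool(int(row[event_col])),
        )
    return out


def write_clinical(path: str | Path, records: list[SurvivalRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{_fmt(r.time)}\t{int(r.event)}\n")


def read_annotation(path: str | Path) -> MetastasisAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "metastatic_site"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sites: dict[str, set[str]] = {}
    universe: list[str] = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid not in sites:
            sites[sid] = set()
            universe.append(sid)
        site = row["metastatic_site"]
        if site and site != NA:
            sites[sid].add(site)
    return MetastasisAnnotation(
        sites={k: frozenset(v) for k, v in sites.items() if v}, universe=universe,
    )


def write_annotation(path: str | Path, annotation: MetastasisAnnotation) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tmetastatic_site\n")
        for sid in annotation.universe:
            ss = sorted(annotation.sites_of(sid))
            if not ss:
                fh.write(f"{sid}\t{NA}\n")
            for s in ss:
                fh.write(f"{sid}\t{s}\n")


def write_site_results(path: str | Path, report: SiteTestReport) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rna_id\tmirna_id\tsite\tn_site\tn_other\tu_stat\tp_value\teffect\n")
        for r in report.results:
            fh.write(
                f"{r.rna_id}\t{r.mirna_id}\t{r.site}\t{r.n_site}\t{r.n_other}\t"
                f"{_fmt(r.u_stat)}\t{_fmt(r.p_value)}\t{_fmt(r.effect)}\n"
            )


def read_site_results(path: str | Path) -> list[SitePairResult]:
    df = pd.read_csv(path, sep="\t", dtype={"rna_id": str, "mirna_id": str, "site": str})
    return [
        SitePairResult(
            rna_id=row.rna_id, mirna_id=row.mirna_id, site=row.site,
            u_stat=float(row.u_stat), p_value=float(row.p_value),
            n_site=int(row.n_site), n_other=int(row.n_other), effect=float(row.effect),
        )
        for row in df.itertuples()
    ]


def write_cohort(directory: str | Path, cohort: Cohort) -> dict[str, Path]:
    """Write a synthetic cohort in exactly the formats the readers accept."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna": directory / "rna_expression.tsv",
        "mirna": directory / "mirna_expression.tsv",
        "metadata": directory / "sample_metadata.tsv",
        "annotation": directory / "metastasis_annotation.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.json",
    }
    write_expression(paths["rna"], cohort.rna)
    write_expression(paths["mirna"], cohort.mirna)
    write_metadata(paths["metadata"], cohort.rna.sample_class or {})
    write_annotation(paths["annotation"], cohort.annotation)
    write_clinical(paths["clinical"], cohort.clinical)
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    classes = read_metadata(directory / "sample_metadata.tsv")
    rna = read_expression(directory / "rna_expression.tsv", "TPM", classes)
    mirna = read_expression(directory / "mirna_expression.tsv", "CPM", classes)
    annotation = read_annotation(directory / "metastasis_annotation.tsv")
    clinical = list(read_clinical(directory / "clinical.tsv").values())
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return Cohort(rna=rna, mirna=mirna, annotation=annotation, clinical=clinical, truth=truth)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(directory: str | Path, config: dict, inputs: list[str | Path],
                   filename: str = "run_manifest.json") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "deltapcc",
        "version": __version__,
        "config": _jsonable(config),
        "input_digests": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
    }
    out = directory / filename
    out.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
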