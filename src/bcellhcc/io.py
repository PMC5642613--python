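"""Readers and writers for the pipeline's tabular formats.

Expression matrices travel as plain TSV (genes in rows, header row of
sample ids, first column gene ids; a GCT-style two-line preamble is
tolerated and skipped). Annotations, survival tables and IHC count
tables are CSV. Run configuration is YAML. No science lives here:
loaders validate and reject, they never transform or repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import LoadError
from .matrix import ExpressionMatrix, ANNOTATION_COLUMNS
from .records import IHCCountRecord, SurvivalRecord, REGIONS

log = logging.getLogger("bcellhcc")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-level thresholds shared by the three stages."""

    cc_threshold: float = 0.8
    linkage: str = "complete"
    k_range: tuple[int, int] = (2, 10)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cc_threshold < 1:
            raise LoadError(f"cc_threshold must be in (0,1), "
                            f"got {self.cc_threshold}")
        if self.linkage != "complete":
            raise LoadError(f"unsupported linkage {self.linkage!r}")
        lo, hi = self.k_range
        if not (2 <= lo <= hi):
            raise LoadError(f"invalid k_range {self.k_range}")
        if not 0 < self.alpha < 1:
            raise LoadError(f"alpha must be in (0,1), got {self.alpha}")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise LoadError(f"{path}: configuration must be a mapping")
    return cfg


def packaged_config(name: str) -> dict:
    """Load one of the shipped default fixture configurations
    (``discovery``, ``validation``, ``ihc`` or ``study``)."""
    ref = resources.files("bcellhcc") / "configs" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def run_config_from(cfg: dict, **overrides) -> RunConfig:
    block = dict(cfg.get("pipeline", {}))
    block.update(overrides)
    kw = {}
    for key in ("cc_threshold", "linkage", "alpha", "seed"):
        if key in block:
            kw[key] = block[key]
    if "k_range" in block:
        kw["k_range"] = tuple(block["k_range"])
    return RunConfig(**kw)


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def read_expression_matrix(path: str | Path,
                           annotation_path: str | Path | None = None
                           ) -> ExpressionMatrix:
    """Read a TSV expression matrix, optionally joining sample annotations.

    The first column holds gene ids and the header row sample ids. A
    GCT-style preamble (``#1.2`` plus a dimensions line) is skipped.
    Duplicate ids, missing cells and non-numeric cells are rejected with
    the offending row/column named.
    """
    path = Path(path)
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            skip = 2  # GCT preamble: version line + dimensions line
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, dtype=str)
    if df.index.isnull().any() or df.columns.isnull().any():
        raise LoadError(f"{path}: empty gene or sample id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate gene id(s) {dup[:5]}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate sample id(s) {dup[:5]}")
    try:
        # numpy string->float conversion is correctly rounded, so a
        # write/read cycle is exact
        values = df.astype(float)
    except (ValueError, TypeError):
        values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"{path}: missing or non-numeric value at gene "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    ann = None
    if annotation_path is not None:
        ann = read_annotations(annotation_path)
        missing = [s for s in values.columns if s not in ann.index]
        if missing:
            raise LoadError(
                f"{annotation_path}: no annotation for sample(s) "
                f"{missing[:5]}"
            )
        ann = ann.loc[values.columns]
    m = ExpressionMatrix(values, ann)
    log.info("read expression matrix %s: %d genes x %d samples",
             path.name, m.n_genes, m.n_samples)
    return m


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            annotation_path: str | Path | None = None
                            ) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if annotation_path is not None and matrix.annotations is not None:
        write_annotations(matrix.annotations, annotation_path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col=0, dtype=str)
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate sample id(s) {dup[:5]}")
    ann.index.name = "sample_id"
    return ann


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# --------------------------------------------------------------------------
# probe -> gene maps
# --------------------------------------------------------------------------

def read_probe_map(path: str | Path) -> dict:
    """CSV with columns ``probe_id,gene_id``; many probes per gene allowed,
    duplicate probe ids rejected."""
    df = pd.read_csv(path, dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise LoadError(f"{path}: duplicate probe id(s) {dup[:5]}")
    return dict(zip(df["probe_id"], df["gene_id"]))


# --------------------------------------------------------------------------
# survival tables
# --------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """CSV with columns ``patient_id,time_months,event[,group]``."""
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    for col in ("patient_id", "time_months", "event"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        time = float(row["time_months"])
        if time < 0:
            raise LoadError(
                f"{path}: patient {row['patient_id']}: negative time {time}"
            )
        ev = row["event"]
        if ev not in (0, 1, 0.0, 1.0, "0", "1"):
            raise LoadError(
                f"{path}: patient {row['patient_id']}: unknown event "
                f"code {ev!r}"
            )
        group = None
        if "group" in df.columns and pd.notna(row["group"]) \
                and str(row["group"]) != "":
            group = str(row["group"])
        records.append(SurvivalRecord(str(row["patient_id"]), time,
                                      int(float(ev)), group))
    log.info("read survival table %s: %d records", Path(path).name,
             len(records))
    return records


def write_survival_table(records: list[SurvivalRecord],
                         path: str | Path) -> None:
    df = pd.DataFrame(
        {"patient_id": [r.patient_id for r in records],
         "time_months": [r.time_months for r in records],
         "event": [r.event for r in records],
         "group": [r.group if r.group is not None else "" for r in records]}
    )
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# IHC count tables
# --------------------------------------------------------------------------

_IHC_REQUIRED = ("patient_id", "marker", "region",
                 "count1", "count2", "count3")
_IHC_BOOL = ("kappa_positive", "igm_positive")


def read_ihc_table(path: str | Path) -> list[IHCCountRecord]:
    """CSV with one row per patient x marker x region.

    Required columns: ``patient_id, marker, region, count1..count3``.
    Optional: ``kappa_positive, igm_positive`` (0/1) and any further
    columns, which are carried as clinical covariates.
    """
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    for col in _IHC_REQUIRED:
        if col not in df.columns:
            raise LoadError(f"{path}: missing column {col!r}")
    covar_cols = [c for c in df.columns
                  if c not in _IHC_REQUIRED and c not in _IHC_BOOL]
    records = []
    for _, row in df.iterrows():
        region = str(row["region"])
        if region not in REGIONS:
            raise LoadError(
                f"{path}: patient {row['patient_id']}: region {region!r} "
                f"not in {REGIONS}"
            )
        counts = tuple(float(row[f"count{i}"]) for i in (1, 2, 3))
        if any(c < 0 for c in counts):
            raise LoadError(
                f"{path}: patient {row['patient_id']} "
                f"({row['marker']}/{region}): negative count"
            )
        flags = {}
        for col in _IHC_BOOL:
            val = row[col] if col in df.columns else None
            flags[col] = None if val is None or pd.isna(val) \
                else bool(int(val))
        covars = {c: row[c] for c in covar_cols if pd.notna(row[c])}
        records.append(IHCCountRecord(
            str(row["patient_id"]), str(row["marker"]), region, counts,
            kappa_positive=flags["kappa_positive"],
            igm_positive=flags["igm_positive"],
            covariates=covars,
        ))
    log.info("read IHC table %s: %d records", Path(path).name, len(records))
    return records


def write_ihc_table(records: list[IHCCountRecord], path: str | Path) -> None:
    covar_cols = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "marker": r.marker,
               "region": r.region,
               "count1": r.counts[0], "count2": r.counts[1],
               "count3": r.counts[2], "mean_count": r.mean_count}
        for col in _IHC_BOOL:
            val = getattr(r, col)
            row[col] = "" if val is None else int(val)
        for c in covar_cols:
            row[c] = r.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
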