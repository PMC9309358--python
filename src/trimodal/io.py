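"""Readers, writers and pipeline configuration.

TSV is the default table dialect; ``.csv`` files are detected by extension.
Writers emit a fixed ``%.10g`` float format so that identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DK_REGIONS,
    MCCB_COLUMNS,
    SUBSET_PCT_COLUMNS,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    PhenotypeTable,
    ThicknessTable,
    ValidationError,
)

log = logging.getLogger("trimodal")

FLOAT_FORMAT = "%.10g"

_PHENO_NUMERIC = ("age", "education") + MCCB_COLUMNS + SUBSET_PCT_COLUMNS


def _sep_for(path: str | Path, dialect: str | None = None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_phenotypes(path: str | Path, dialect: str | None = None) -> PhenotypeTable:
    """Read a per-subject phenotype table (see :class:`PhenotypeTable`).

    Missing numeric cells become nulls and the row is retained; duplicate
    subject ids or unknown group labels raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), comment="#")
    for col in _PHENO_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "smoker" in df.columns:
        df["smoker"] = df["smoker"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path, dialect: str | None = None) -> None:
    table.frame.to_csv(path, sep=_sep_for(path, dialect), index=False,
                       float_format=FLOAT_FORMAT)


def read_counts(path: str | Path, dialect: str | None = None) -> CountMatrix:
    """Read a gene x subject raw count table (first column = gene symbols)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return CountMatrix(df)


def write_counts(m: CountMatrix, path: str | Path, dialect: str | None = None) -> None:
    m.frame.to_csv(path, sep=_sep_for(path, dialect))


def read_annotation(path: str | Path, dialect: str | None = None) -> GeneAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), comment="#")
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path, dialect: str | None = None) -> None:
    ann.frame.to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_expression(path: str | Path, provenance: str = "raw-normalized",
                    dialect: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(df, provenance=provenance)


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    m.frame.to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FORMAT)


def read_thickness(path: str | Path, mode: str = "left+right",
                   dialect: str | None = None) -> ThicknessTable:
    """Read a subject x region cortical thickness table.

    In ``left+right`` mode, columns are ``<region>_lh``/``<region>_rh`` pairs;
    a missing hemisphere partner is an error.  Columns that do not match any
    canonical Desikan-Killiany label are dropped with a warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    known = set(DK_REGIONS)
    if mode == "left+right":
        keep, unknown = [], []
        for col in df.columns:
            base, _, hemi = col.rpartition("_")
            if hemi in ("lh", "rh") and base in known:
                keep.append(col)
            else:
                unknown.append(col)
        if unknown:
            warnings.warn(f"dropping unknown thickness columns: {unknown}")
            log.warning("dropping unknown thickness columns: %s", unknown)
        present = set(keep)
        for col in keep:
            base, _, hemi = col.rpartition("_")
            partner = f"{base}_{'rh' if hemi == 'lh' else 'lh'}"
            if partner not in present:
                raise ValidationError(f"column {col!r} has no hemisphere partner {partner!r}")
        missing = [r for r in DK_REGIONS if f"{r}_lh" not in present]
        if missing:
            raise ValidationError(f"missing DK regions: {missing}")
        return ThicknessTable(df[keep], mode="left+right")
    elif mode == "averaged":
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            warnings.warn(f"dropping unknown thickness columns: {unknown}")
            log.warning("dropping unknown thickness columns: %s", unknown)
            df = df.drop(columns=unknown)
        missing = [r for r in DK_REGIONS if r not in df.columns]
        if missing:
            raise ValidationError(f"missing DK regions: {missing}")
        return ThicknessTable(df, mode="averaged")
    raise ValueError(f"unknown mode {mode!r}")


def write_thickness(t: ThicknessTable, path: str | Path, dialect: str | None = None) -> None:
    t.frame.to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs: inputs, parameters, seed.

    When ``synthetic`` is true the four input tables are generated by the
    ``paper-like`` preset of the synthetic cohort generator instead of being
    read from ``phenotypes``/``counts``/``annotation``/``thickness`` paths.
    """

    phenotypes: str | None = None
    counts: str | None = None
    annotation: str | None = None
    thickness: str | None = None
    thickness_mode: str = "left+right"
    synthetic: bool = False
    preset: str = "paper-like"

    covariates: tuple[str, ...] = ("age", "sex")
    cognition_covariates: tuple[str, ...] = ("age", "sex", "education")

    min_mean_count: float = 4.0
    var_percentile: float = 15.0
    pseudocount: float = 1.0

    alpha: float = 0.05
    alpha_nominal: float = 0.01
    n_boot: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.var_percentile < 100):
            raise ValueError("var_percentile must lie in [0, 100)")
        if self.n_boot < 1:
            raise ValueError("bootstrap reps must be >= 1")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        self.covariates = tuple(self.covariates)
        self.cognition_covariates = tuple(self.cognition_covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("inputs", "preprocess", "coupling", "mediation", "output"):
            flat.update(raw.pop(section, {}) or {})
        flat.update(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["cognition_covariates"] = list(self.cognition_covariates)
        return yaml.safe_dump(d, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration (used in output manifests)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
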