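"""Core table types shared across the pipeline.

Each type is a light wrapper around a :class:`pandas.DataFrame` that owns the
column conventions and validates its invariants at construction time.  The
wrappers stay deliberately thin: analysis code works on the underlying frames
and NumPy views, the wrappers only guarantee that what flows between stages is
well formed (unique subjects, known group labels, canonical atlas regions,
non-negative integer counts, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DK_REGIONS",
    "MCCB_DOMAINS",
    "MONOCYTE_SUBSETS",
    "GROUPS",
    "PhenotypeTable",
    "CountMatrix",
    "GeneAnnotation",
    "ExpressionMatrix",
    "ThicknessTable",
    "ValidationError",
]

#: The 34 bilateral gyral regions of the Desikan-Killiany cortical atlas,
#: in alphabetical FreeSurfer label order (the canonical matrix layout).
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: The seven MATRICS Consensus Cognitive Battery domains (T-scores).
MCCB_DOMAINS: tuple[str, ...] = (
    "processing_speed",
    "attention_vigilance",
    "working_memory",
    "verbal_learning",
    "visual_learning",
    "reasoning",
    "social_cognition",
)

#: CD14/CD16 monocyte subset classes used to label signature genes.
MONOCYTE_SUBSETS: tuple[str, ...] = ("pan", "classical", "intermediate", "nonclassical")

GROUPS: tuple[str, ...] = ("HC", "FES")

MCCB_COLUMNS: tuple[str, ...] = tuple(f"mccb_{d}" for d in MCCB_DOMAINS) + ("mccb_composite",)
SUBSET_PCT_COLUMNS: tuple[str, ...] = (
    "pct_classical",
    "pct_intermediate",
    "pct_nonclassical",
)


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class PhenotypeTable:
    """Per-subject group label, covariates, cognition scores and subset fractions.

    Columns: ``subject_id``, ``group`` (HC/FES), ``age`` (years), ``sex``
    (male/female), ``education`` (years), ``smoker`` (bool), the seven
    ``mccb_*`` domain T-scores plus ``mccb_composite``, and three ``pct_*``
    monocyte subset percentages.  Cognition and subset columns are nullable;
    subjects with missing values drop out of an analysis pairwise, not from
    the whole pipeline.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        _require("subject_id" in df.columns, "phenotype table needs a subject_id column")
        _require("group" in df.columns, "phenotype table needs a group column")
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate subject_id values: {sorted(set(dup))}")
        bad = set(df["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)} (expected {GROUPS})")
        _require(not df["group"].isna().any(), "group label may not be null")
        if "sex" in df.columns:
            bad_sex = set(df["sex"].dropna()) - {"male", "female"}
            if bad_sex:
                raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        for col in SUBSET_PCT_COLUMNS:
            if col in df.columns:
                vals = df[col].dropna()
                if len(vals) and not ((vals >= 0) & (vals <= 100)).all():
                    raise ValidationError(f"{col} outside [0, 100]")
        self.frame = df.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame["subject_id"])

    def group_mask(self, group: str) -> np.ndarray:
        _require(group in GROUPS, f"unknown group {group!r}")
        return (self.frame["group"] == group).to_numpy()

    def sex_numeric(self) -> np.ndarray:
        """Sex as 0=female, 1=male — the single model-matrix convention."""
        return self.frame["sex"].map({"female": 0.0, "male": 1.0}).to_numpy()

    def covariate_matrix(self, covariates: tuple[str, ...]) -> np.ndarray:
        """Subjects x covariates design block (no intercept), sex encoded 0/1."""
        cols = []
        for name in covariates:
            if name == "sex":
                cols.append(self.sex_numeric())
            else:
                _require(name in self.frame.columns, f"unknown covariate {name!r}")
                cols.append(self.frame[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(self.frame), 0))


@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x subjects, non-negative integers."""

    frame: pd.DataFrame  # index = gene symbols, columns = subject ids

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbols: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                i, j = np.argwhere((arr != np.round(arr)) | ~np.isfinite(arr))[0]
                raise ValidationError(
                    f"non-integer count at gene {df.index[i]!r}, subject {df.columns[j]!r}"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            i, j = np.argwhere(df.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[i]!r}, subject {df.columns[j]!r}"
            )
        self.frame = df

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass
class GeneAnnotation:
    """Maps gene symbols to the monocyte subset whose signature they belong to."""

    frame: pd.DataFrame  # columns: gene, subset

    def __post_init__(self) -> None:
        df = self.frame
        _require({"gene", "subset"} <= set(df.columns), "annotation needs gene and subset columns")
        if df["gene"].duplicated().any():
            dups = sorted(set(df["gene"][df["gene"].duplicated()]))
            raise ValidationError(f"gene annotated more than once: {dups}")
        _require(not df["subset"].isna().any(), "subset label may not be null")
        bad = set(df["subset"]) - set(MONOCYTE_SUBSETS)
        if bad:
            raise ValidationError(f"unknown subset labels: {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    def subset_of(self) -> dict[str, str]:
        return dict(zip(self.frame["gene"], self.frame["subset"]))

    def genes_in(self, subset: str) -> list[str]:
        _require(subset in MONOCYTE_SUBSETS, f"unknown subset {subset!r}")
        return list(self.frame.loc[self.frame["subset"] == subset, "gene"])


@dataclass
class ExpressionMatrix:
    """Normalized log2 counts-per-million, genes x subjects."""

    frame: pd.DataFrame
    provenance: str = "raw-normalized"  # or "synthetic"

    def __post_init__(self) -> None:
        _require(self.provenance in ("raw-normalized", "synthetic"),
                 f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.frame.to_numpy(dtype=float))):
            raise ValidationError("expression matrix contains non-finite values")
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass
class ThicknessTable:
    """Subject x region cortical thickness in mm.

    ``mode="left+right"`` carries 68 columns named ``<region>_lh``/``<region>_rh``;
    ``mode="averaged"`` carries the 34 bilateral means named ``<region>``.
    """

    frame: pd.DataFrame  # index = subject ids
    mode: str = "averaged"

    def __post_init__(self) -> None:
        _require(self.mode in ("left+right", "averaged"), f"unknown mode {self.mode!r}")
        cols = list(self.frame.columns)
        if self.mode == "averaged":
            _require(set(cols) == set(DK_REGIONS),
                     "averaged thickness table must carry exactly the 34 DK regions")
            self.frame = self.frame[list(DK_REGIONS)]
        else:
            expected = {f"{r}_{h}" for r in DK_REGIONS for h in ("lh", "rh")}
            _require(set(cols) == expected,
                     "left+right thickness table must carry all 68 hemisphere columns")
            order = [f"{r}_{h}" for r in DK_REGIONS for h in ("lh", "rh")]
            self.frame = self.frame[order]
        arr = self.frame.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if len(finite) and not ((finite > 0) & (finite < 6)).all():
            raise ValidationError("cortical thickness values must lie in (0, 6) mm")

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.index)

    @property
    def regions(self) -> list[str]:
        if self.mode == "averaged":
            return list(self.frame.columns)
        return list(DK_REGIONS)
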