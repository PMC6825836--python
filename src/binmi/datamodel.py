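"""Core data containers, per-site standardization, and plain-text I/O.

The package works with two paired objects: a :class:`MethylationMatrix`
(CpG sites x individuals, no missing entries — only covariate
missingness is modelled) and a :class:`CovariateTable` (individuals x
typed covariates, with missing cells).  Methylation files are TSV with a
``site_id`` first column; covariate files are CSV with a ``sample_id``
first column plus a YAML/JSON sidecar schema declaring each variable's
type, levels, and reference level.  The missing-value token in covariate
files is the literal ``NA``; methylation files admit no missing token.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Variable",
    "MethylationMatrix",
    "CovariateTable",
    "AnalysisConfig",
    "SMOKING_LEVELS",
    "standardize_methylation",
    "read_methylation",
    "write_methylation",
    "read_schema",
    "write_schema",
    "read_covariates",
    "write_covariates",
    "write_results",
    "read_results",
]

SMOKING_LEVELS = ("never", "former", "current")

RESULT_COLUMNS = [
    "site_id",
    "beta_former",
    "se_former",
    "p_former",
    "beta_current",
    "se_current",
    "p_current",
    "df",
    "significant",
]

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


@dataclass(frozen=True)
class Variable:
    """Schema entry for one covariate.

    kind is one of ``continuous``, ``binary``, ``categorical``.  For
    categorical variables ``levels`` lists the admissible values and
    ``reference`` names the baseline level used when dummy-coding.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical variable {self.name!r} needs explicit levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(f"reference {ref!r} not among levels of {self.name!r}")
            object.__setattr__(self, "reference", ref)
            object.__setattr__(self, "levels", tuple(self.levels))


@dataclass
class MethylationMatrix:
    """Sites x individuals methylation matrix with no missing entries."""

    site_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.site_ids.size, self.sample_ids.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.site_ids.size} sites x {self.sample_ids.size} samples"
            )
        if len(set(self.site_ids)) != self.site_ids.size:
            raise ValueError("duplicate site IDs")
        if len(set(self.sample_ids)) != self.sample_ids.size:
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("methylation matrix contains missing or non-finite entries")
        if self.standardized:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1, ddof=1)
            if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd - 1) > 1e-8):
                raise ValueError("standardized flag set but rows are not mean 0 / SD 1")

    @property
    def n_sites(self) -> int:
        return self.site_ids.size

    @property
    def n_individuals(self) -> int:
        return self.sample_ids.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)


@dataclass
class CovariateTable:
    """Per-individual covariates with a typed schema and missing cells.

    ``data`` is indexed by sample ID; categorical columns hold level
    strings (or NaN), binary columns 0/1, continuous columns floats.
    """

    data: pd.DataFrame
    schema: dict[str, Variable]

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        for name in self.data.columns:
            if name not in self.schema:
                raise ValueError(f"column {name!r} missing from schema")
        for name, var in self.schema.items():
            if name not in self.data.columns:
                raise ValueError(f"schema variable {name!r} missing from data")
            col = self.data[name]
            if var.kind == "categorical":
                bad = col.dropna()[~col.dropna().isin(var.levels)]
                if len(bad):
                    row = bad.index[0]
                    raise ValueError(
                        f"unknown level {bad.iloc[0]!r} for {name!r} at sample {row!r} "
                        f"(levels: {list(var.levels)})"
                    )
            elif var.kind == "binary":
                vals = pd.to_numeric(col.dropna())
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"binary variable {name!r} has values outside {{0,1}}")
        if "smoking" in self.schema:
            var = self.schema["smoking"]
            if var.kind != "categorical" or tuple(var.levels) != SMOKING_LEVELS or var.reference != "never":
                raise ValueError(
                    "smoking must be categorical with levels (never, former, current) "
                    "and reference 'never'"
                )

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=object)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def complete_mask(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of rows with no missing value in ``columns`` (all by default)."""
        cols = list(columns) if columns is not None else list(self.data.columns)
        return (~self.data[cols].isna()).all(axis=1).to_numpy()

    def copy(self) -> "CovariateTable":
        return CovariateTable(self.data.copy(), dict(self.schema))


@dataclass
class AnalysisConfig:
    """Settings for one imputation + EWAS run.

    m is the number of imputed data sets (default 100, a deliberately
    conservative choice; desk-scale studies use fewer — see the methods
    note).  ``bin_size`` counts sites per imputation bin, including any
    always-included selected sites.  ``n_cycles`` applies only to the
    chained-equations path with several incomplete covariates.
    """

    bin_size: int = 45
    m: int = 100
    alpha: float = 0.05
    n_cycles: int = 10
    seed: int = 0
    ewas_covariates: tuple[str, ...] = ("age", "sex", "smoking")
    imputation_only_covariates: tuple[str, ...] = ()
    ridge: float = 1e-5
    param_uncertainty: str = "none"

    def __post_init__(self):
        if self.param_uncertainty not in ("none", "bootstrap"):
            raise ValueError("param_uncertainty must be 'none' or 'bootstrap'")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        overlap = set(self.ewas_covariates) & set(self.imputation_only_covariates)
        if overlap:
            raise ValueError(f"auxiliaries overlap EWAS covariates: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# standardization


def standardize_methylation(matrix: MethylationMatrix) -> MethylationMatrix:
    """Standardize each site row to mean 0, sample SD 1 (denominator n-1).

    Raises ``ValueError`` naming the first offending site if any row has
    zero variance.  Idempotent on already-standardized input.
    """
    mu = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero variance at site {matrix.site_ids[zero[0]]!r}: cannot standardize")
    return MethylationMatrix(
        site_ids=matrix.site_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=(matrix.values - mu) / sd,
        standardized=True,
    )


# ---------------------------------------------------------------------------
# methylation I/O


def read_methylation(path, standardized: bool = False) -> MethylationMatrix:
    """Read a sites-x-samples TSV (first column ``site_id``)."""
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, keep_default_na=False, na_values=[],
        float_precision="round_trip",
    )
    if df.columns[0] != "site_id":
        raise ValueError(f"first column of {path} must be 'site_id', got {df.columns[0]!r}")
    df = df.set_index("site_id")
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric methylation cell in {path}: {exc}") from exc
    return MethylationMatrix(
        site_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        values=values,
        standardized=standardized,
    )


def write_methylation(matrix: MethylationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="site_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# covariate schema + table I/O


def read_schema(path) -> dict[str, Variable]:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    variables = raw["variables"] if "variables" in raw else raw
    schema = {}
    for name, entry in variables.items():
        schema[name] = Variable(
            name=name,
            kind=entry["kind"],
            levels=tuple(entry["levels"]) if entry.get("levels") else None,
            reference=entry.get("reference"),
        )
    return schema


def write_schema(schema: Mapping[str, Variable], path) -> None:
    path = Path(path)
    out = {"variables": {}}
    for name, var in schema.items():
        entry: dict = {"kind": var.kind}
        if var.levels:
            entry["levels"] = list(var.levels)
            entry["reference"] = var.reference
        out["variables"][name] = entry
    if path.suffix == ".json":
        path.write_text(json.dumps(out, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(out, sort_keys=False))


def read_covariates(path, schema) -> CovariateTable:
    """Read a covariate CSV under a schema (path or mapping); ``NA`` = missing."""
    if not isinstance(schema, Mapping):
        schema = read_schema(schema)
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=["NA"], float_precision="round_trip"
    )
    if df.columns[0] != "sample_id":
        raise ValueError(f"first column of {path} must be 'sample_id', got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    for name, var in schema.items():
        if name not in df.columns:
            raise ValueError(f"covariate file lacks column {name!r}")
        if var.kind in ("continuous", "binary"):
            df[name] = pd.to_numeric(df[name], errors="raise")
    return CovariateTable(df[list(schema)], dict(schema))


def write_covariates(table: CovariateTable, path) -> None:
    df = table.data.copy()
    for name, var in table.schema.items():
        if var.kind in ("continuous", "binary"):
            df[name] = df[name].map(lambda v: _FLOAT_FMT % v if pd.notna(v) else np.nan)
    df.to_csv(path, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# results I/O


def write_results(table: pd.DataFrame, path) -> None:
    """Write a per-site results table as TSV (core columns first)."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table lacks columns {missing}")
    cols = RESULT_COLUMNS + [c for c in table.columns if c not in RESULT_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str}, float_precision="round_trip")
    df["significant"] = df["significant"].astype(bool)
    return df
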