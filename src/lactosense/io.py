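"""Readers/writers for genotype and phenotype tables, plus run configuration.

Genotype matrices arrive either as Roary/Piggy-style Rtab files (tab
separated, one row per feature, one column per strain, 0/1 cells) or as plain
CSV with samples as rows.  Alignment between genotype and phenotype tables is
always by sample id, never by row order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimDesign, design_from_dict, design_to_dict

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
]


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("rtab", "csv"):
            raise ValueError(f"format must be 'rtab' or 'csv', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "rtab" if suffix in (".rtab", ".tab", ".tsv") else "csv"


def _validate_binary(df: pd.DataFrame, path) -> pd.DataFrame:
    vals = df.to_numpy()
    try:
        vals = vals.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cell in genotype matrix ({err})") from None
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValueError(
            f"{path}: missing/ragged cell at sample {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    if (vals < 0).any():
        raise ValueError(f"{path}: negative cell values in genotype matrix")
    nonbinary = int(((vals != 0) & (vals != 1)).sum())
    if nonbinary:
        warnings.warn(
            f"{path}: coerced {nonbinary} non-binary cell(s) > 0 to 1", stacklevel=3
        )
        vals = (vals > 0).astype(np.int8)
    return pd.DataFrame(vals.astype(np.int8), index=df.index, columns=df.columns)


def read_genotype_matrix(path, fmt: str | None = None) -> pd.DataFrame:
    """Load a samples × binary-features matrix.

    Rtab stores features as rows and is transposed on load; CSV stores
    samples as rows with the sample id in the first column.  Cells must be
    numeric and non-negative; values > 1 are coerced to 1 with a warning.
    Duplicate sample or feature ids are rejected.
    """
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "rtab":
            df = pd.read_csv(path, sep="\t", index_col=0).T
        else:
            df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed file — {err}") from None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return _validate_binary(df, path)


def write_genotype_matrix(G: pd.DataFrame, path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "rtab":
        out = G.T
        out.index.name = "Feature"
        out.to_csv(path, sep="\t")
    else:
        out = G.copy()
        out.index.name = "Sample"
        out.to_csv(path)


def read_phenotypes(path, genotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load the samples × sensory-channels table (CSV, sample id first column).

    Cells must be numeric and present; with ``genotypes`` given, rows are
    aligned to the genotype matrix by sample id and any mismatch in the two
    sample sets is an error listing the offenders.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at sample {row!r}, column {col!r}")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ValueError(f"{path}: missing value at sample {row!r}, column {col!r}")
        df[col] = numeric.astype(float)
    if genotypes is not None:
        g_ids, p_ids = set(genotypes.index), set(df.index)
        if g_ids != p_ids:
            missing = sorted(g_ids - p_ids)
            extra = sorted(p_ids - g_ids)
            raise ValueError(
                f"{path}: sample sets differ from genotype matrix "
                f"(missing: {missing[:5]}, unmatched: {extra[:5]})"
            )
        df = df.loc[genotypes.index]
    return df


def write_phenotypes(P: pd.DataFrame, path) -> None:
    out = P.copy()
    out.index.name = "Sample"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one CLI run needs: data source, search budget, output dir.

    Exactly one of (``genotype_paths`` + ``phenotype_path``) or ``design``
    must be present.  ``bounds`` overrides individual pipeline search ranges
    (keys: variance_threshold, percentile, rfecv_step, min_features,
    n_components).
    """

    outdir: str = "lactosense_run"
    seed: int = 0
    genotype_paths: list[str] | None = None
    phenotype_path: str | None = None
    design: SimDesign | None = None
    pop_size: int = 50
    max_iter: int = 100
    bounds: dict | None = None
    models: list[str] | None = None
    phenotypes: list[str] | None = None

    def validate(self) -> None:
        has_files = bool(self.genotype_paths) and self.phenotype_path is not None
        has_design = self.design is not None
        if has_files == has_design:
            raise ValueError(
                "config must provide exactly one of (genotype_paths + phenotype_path) or design"
            )
        if has_files:
            for p in list(self.genotype_paths) + [self.phenotype_path]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        design = design_from_dict(d["design"]) if d.get("design") else None
        return cls(
            outdir=d.get("outdir", "lactosense_run"),
            seed=int(d.get("seed", 0)),
            genotype_paths=d.get("genotype_paths"),
            phenotype_path=d.get("phenotype_path"),
            design=design,
            pop_size=int(d.get("pop_size", 50)),
            max_iter=int(d.get("max_iter", 100)),
            bounds=d.get("bounds"),
            models=d.get("models"),
            phenotypes=d.get("phenotypes"),
        )

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "genotype_paths": self.genotype_paths,
            "phenotype_path": self.phenotype_path,
            "design": design_to_dict(self.design) if self.design else None,
            "pop_size": self.pop_size,
            "max_iter": self.max_iter,
            "bounds": self.bounds,
            "models": self.models,
            "phenotypes": self.phenotypes,
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
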