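"""On-disk formats: expression TSV, metadata CSV, GMT gene sets,
factorization archives and the flat pipeline configuration.

All writers are bit-deterministic given identical inputs: fixed column
order, fixed float formatting (6 significant digits in result tables, full
precision in the factorization archive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, ExpressionMatrixError, GeneSet, validate_metadata


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- expression

def read_expression_tsv(path, transform_tag: str = "raw_tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``, header row of
    sample ids). Duplicate identifiers, ragged rows and (for raw TPM)
    negative values are rejected with the offending name or line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: expected a gene_id column plus samples")
        n_fields = len(header)
        genes, data = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
            genes.append(parts[0])
            try:
                data.append([float(v) for v in parts[1:]])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    df = pd.DataFrame(data, index=genes, columns=header[1:], dtype=float)
    try:
        return ExpressionMatrix(df, transform_tag=transform_tag)
    except ExpressionMatrixError as e:
        raise FormatError(f"{path}: {e}") from e


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ------------------------------------------------------------------ metadata

def read_metadata_csv(path) -> pd.DataFrame:
    """Read and validate a per-sample cohort metadata CSV.

    Hours are (re)derived from the canonical timepoint label; sepsis rows
    with a blank outcome become ``unknown``; healthy rows must carry
    ``not_applicable`` (or blank, which is normalised to it)."""
    meta = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                    "timepoint": str, "group": str},
                       keep_default_na=False, na_values=[""])
    if "outcome" not in meta.columns:
        meta["outcome"] = ""
    meta["outcome"] = meta["outcome"].astype(object)
    healthy = meta["group"] == "healthy"
    blank = meta["outcome"].isna() | (meta["outcome"] == "")
    meta.loc[healthy & blank, "outcome"] = "not_applicable"
    return validate_metadata(meta)


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    cols = ["sample_id", "subject_id", "timepoint", "hours",
            "group", "outcome", "age", "sex"]
    meta[cols].to_csv(path, index=False)


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (set name, description, tab-separated genes).

    Duplicate genes within a set are collapsed with a warning; an empty set
    after deduplication is an error."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(parts)}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            seen, unique = set(), []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                unique.append(g)
            if len(unique) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set "
                              f"{name!r} collapsed")
            if not unique:
                raise FormatError(f"{path}:{lineno}: set {name!r} empty "
                                  "after deduplication")
            sets.append(GeneSet(name=name, genes=tuple(unique), description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ------------------------------------------------------- result-table output

def write_table_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Human-readable result table: 6 significant digits."""
    df.to_csv(path, sep="\t", float_format="%.6g", index=index)


def write_manifest(entries: dict, path) -> None:
    with open(path, "w") as fh:
        for k in entries:
            fh.write(f"{k}: {entries[k]}\n")


def read_manifest(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if ":" in line:
                k, v = line.split(":", 1)
                out[k.strip()] = v.strip()
    return out


# --------------------------------------------------- factorization archives

def write_factorization(result, outdir) -> None:
    """Archive A.tsv / P.tsv / loss.tsv plus a manifest, full precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    A = result.A.copy()
    A.index.name = "gene_id"
    A.to_csv(outdir / "A.tsv", sep="\t", float_format="%.17g")
    P = result.P.copy()
    P.index.name = "pattern"
    P.to_csv(outdir / "P.tsv", sep="\t", float_format="%.17g")
    loss = pd.DataFrame({"iteration": np.arange(len(result.loss_trace)),
                         "objective": result.loss_trace})
    loss.to_csv(outdir / "loss.tsv", sep="\t", index=False,
                float_format="%.17g")
    write_manifest({
        "K": result.K,
        "seed": result.seed,
        "lambda_A": result.sparsity_weights[0],
        "lambda_P": result.sparsity_weights[1],
        "tol": result.model.tol,
        "max_iter": result.model.max_iter,
        "n_restarts": result.model.n_restarts,
        "iterations": result.n_iterations,
        "converged": result.converged,
        "final_objective": result.loss_trace[-1],
    }, outdir / "manifest.txt")


def read_factorization(indir) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Load (A, P, manifest) from a factorization archive directory."""
    indir = Path(indir)
    A = pd.read_csv(indir / "A.tsv", sep="\t", index_col=0)
    P = pd.read_csv(indir / "P.tsv", sep="\t", index_col=0)
    manifest = read_manifest(indir / "manifest.txt")
    return A, P, manifest


# -------------------------------------------------------------- ground truth

def write_ground_truth(truth, config, outdir) -> None:
    from .simulate import config_manifest
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    A = truth.A_true.copy()
    A.index.name = "gene_id"
    A.to_csv(outdir / "A_true.tsv", sep="\t", float_format="%.17g")
    P = truth.P_true.copy()
    P.index.name = "pattern"
    P.to_csv(outdir / "P_true.tsv", sep="\t", float_format="%.17g")
    effects = pd.DataFrame([
        {"pattern": truth.P_true.index[k], "class": v["class"],
         "effect_size": v["effect_size"]}
        for k, v in sorted(truth.outcome_effects.items())])
    effects.to_csv(outdir / "outcome_effects.tsv", sep="\t", index=False)
    write_manifest(config_manifest(config), outdir / "manifest.txt")


# -------------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Flat configuration of the end-to-end pipeline.

    ``simulate=True`` generates the default synthetic cohort; otherwise
    ``expression`` / ``metadata`` paths must point at existing inputs.
    """

    # inputs (ignored when simulate=True)
    expression: str = ""
    metadata: str = ""
    gene_sets: str = ""
    simulate: bool = True
    # generator
    n_genes: int = 2000
    # factorization
    k: int = 30
    sparsity: float = -1.0        # lambda as absolute value; <0 = 0.01*mean(D)
    tol: float = 1e-5
    max_iter: int = 300
    n_restarts: int = 2
    pseudocount: float = 1.0
    # projection
    projection_method: str = "ols"
    min_shared_fraction: float = 0.5
    # modeling (desk-scale CV defaults; rf_importance_pipeline itself
    # defaults to the full 10-repeat, 500-tree configuration)
    threshold: float = 0.70
    n_resplits: int = 10
    n_folds: int = 10
    n_repeats: int = 3
    n_trees: int = 200
    model_timepoint: str = "0h"
    # enrichment
    n_perm: int = 9999
    iterations: int = 10_000
    set_size: int = 20
    # global
    seed: int = 0

    _RANGES = {
        "k": (1, 10_000), "n_genes": (1, 10**7), "tol": (0.0, 1.0),
        "max_iter": (1, 10**6), "n_restarts": (1, 1000),
        "pseudocount": (1e-12, 100.0), "min_shared_fraction": (0.0, 1.0),
        "threshold": (0.0, 1.0), "n_resplits": (1, 1000),
        "n_folds": (2, 100), "n_repeats": (1, 1000), "n_trees": (1, 100_000),
        "n_perm": (1, 10**8), "iterations": (1, 10**8),
        "set_size": (1, 10**6),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise FormatError(
                    f"config {name}={v} outside documented range [{lo}, {hi}]")
        if self.projection_method not in ("ols", "nnls"):
            raise FormatError(
                f"projection_method must be ols|nnls, got {self.projection_method!r}")
        if not self.simulate and not (self.expression and self.metadata):
            raise FormatError(
                "simulate=false requires expression and metadata paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a flat key-value map")
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise FormatError(f"{path}: unknown config keys {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if not f.name.startswith("_")}
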