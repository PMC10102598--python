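"""Tab-separated file formats for the pipeline.

All tables are UTF-8 TSV with a header row; a ``.gz`` suffix triggers
transparent gzip (de)compression via pandas.  Matrices encode missing
values as the literal string ``NA``.  Readers validate and reject rather
than coerce: malformed coordinates, negative or non-integer counts, and
duplicate identifiers raise :class:`~barseqfit.config.ValidationError`
naming the offending column and row.

Formats
-------
genes.tsv        gene_id, replicon, begin, end, strand, gc, nonrepetitive_nt, desc
replicons.tsv    replicon, length, is_main        (optional sidecar)
pool.tsv         barcode, replicon, strand, pos, n_reads
counts.tsv       barcode, then one integer column per sample
experiments.tsv  sample, role, time0_group, condition, replicate
fitness matrices gene_id, then one float column per experiment ("NA" allowed)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import ValidationError
from .design import DESIGN_COLUMNS, ExperimentDesign
from .genome import GENE_COLUMNS, POOL_COLUMNS, GenomeModel, InsertionPool, Replicon


def _read_tsv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse {what} table {path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{what} table {path} is missing required column {col!r}")
    return df


def _to_int(df: pd.DataFrame, col: str, what: str, minimum: int | None = None) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() | (s != s.round())
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise ValidationError(f"{what}: column {col!r}, line {row}: not an integer ({df[col].iloc[row - 2]!r})")
    if minimum is not None and (s < minimum).any():
        row = int(np.flatnonzero(s < minimum)[0]) + 2
        raise ValidationError(f"{what}: column {col!r}, line {row}: value below {minimum}")
    return s.astype(np.int64)


def _to_float(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & (df[col] != "NA") & (df[col] != "")
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValidationError(f"{what}: column {col!r}, line {row}: not a number")
    return s.astype(float)


# -- genes / replicons -------------------------------------------------------

def read_genes(path: str | Path, replicons_path: str | Path | None = None) -> GenomeModel:
    """Read a gene table (and optional replicon sidecar) into a GenomeModel.

    Without a sidecar, replicons are inferred: each replicon's length is the
    maximum gene end (plus a small margin) and the replicon carrying the
    most genes is flagged as the main chromosome.
    """
    df = _read_tsv(path, GENE_COLUMNS, "genes")
    df = df.copy()
    df["begin"] = _to_int(df, "begin", "genes", minimum=1)
    df["end"] = _to_int(df, "end", "genes", minimum=1)
    df["nonrepetitive_nt"] = _to_int(df, "nonrepetitive_nt", "genes", minimum=0)
    df["gc"] = _to_float(df, "gc", "genes")
    if replicons_path is not None and Path(replicons_path).exists():
        rdf = _read_tsv(replicons_path, ["replicon", "length", "is_main"], "replicons")
        rdf = rdf.copy()
        rdf["length"] = _to_int(rdf, "length", "replicons", minimum=1)
        replicons = [
            Replicon(r["replicon"], int(r["length"]), str(r["is_main"]) in ("1", "True", "true"))
            for _, r in rdf.iterrows()
        ]
    else:
        counts = df["replicon"].value_counts()
        main = counts.idxmax() if len(counts) else None
        replicons = [
            Replicon(rep, int(df.loc[df["replicon"] == rep, "end"].max()) + 100, rep == main)
            for rep in df["replicon"].unique()
        ]
    return GenomeModel(replicons, df)


def write_genes(genome: GenomeModel, path: str | Path,
                replicons_path: str | Path | None = None) -> None:
    genome.genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)
    if replicons_path is not None:
        pd.DataFrame(
            [(r.id, r.length, int(r.is_main)) for r in genome.replicons],
            columns=["replicon", "length", "is_main"],
        ).to_csv(replicons_path, sep="\t", index=False)


# -- pool --------------------------------------------------------------------

def read_pool(path: str | Path, genome: GenomeModel | None = None) -> InsertionPool:
    df = _read_tsv(path, POOL_COLUMNS, "pool").copy()
    df["pos"] = _to_int(df, "pos", "pool", minimum=1)
    df["n_reads"] = _to_int(df, "n_reads", "pool", minimum=0)
    pool = InsertionPool(df[POOL_COLUMNS], genome=genome)
    return pool.annotate(genome) if genome is not None else pool


def write_pool(pool: InsertionPool, path: str | Path) -> None:
    pool.strains[POOL_COLUMNS].to_csv(path, sep="\t", index=False)


# -- counts ------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["barcode"], "counts")
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValidationError(f"counts: duplicate barcode {dup!r}")
    samples = [c for c in df.columns if c != "barcode"]
    if len(set(samples)) != len(samples):
        raise ValidationError("counts: duplicate sample column")
    out = pd.DataFrame(index=pd.Index(df["barcode"], name="barcode"))
    for col in samples:
        out[col] = _to_int(df, col, "counts", minimum=0).to_numpy()
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("barcode").to_csv(path, sep="\t")


# -- design ------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    df = _read_tsv(path, DESIGN_COLUMNS, "experiments").copy()
    df["replicate"] = _to_int(df, "replicate", "experiments", minimum=0)
    return ExperimentDesign(df)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


# -- fitness matrices --------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


# -- json artifacts ----------------------------------------------------------

def write_json(obj: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON-serializable: {type(value)}")
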