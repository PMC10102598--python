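"""Genome and insertion-pool containers.

A :class:`GenomeModel` holds replicons (typically a main chromosome plus a
plasmid) and a gene table with 1-based inclusive coordinates, per-gene GC
fraction and the number of non-repetitive nucleotides (insertions in
repetitive sequence cannot be mapped unambiguously, so genes with little
non-repetitive sequence are excluded from essentiality calling).

An :class:`InsertionPool` maps each barcoded transposon mutant to its
insertion position and Tn-seq read count.  Gene assignment and the position
of the insertion within the gene (``gene_fraction``) are derived from the
genome with :meth:`InsertionPool.annotate`; an insertion in the central
10–90% of a gene is assumed to disrupt it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ValidationError

GENE_COLUMNS = ["gene_id", "replicon", "begin", "end", "strand", "gc", "nonrepetitive_nt", "desc"]
POOL_COLUMNS = ["barcode", "replicon", "strand", "pos", "n_reads"]


@dataclass(frozen=True)
class Replicon:
    id: str
    length: int
    is_main: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"replicon {self.id!r} has non-positive length")


class GenomeModel:
    """Replicons plus a validated gene table.

    Parameters
    ----------
    replicons : sequence of Replicon
        Exactly one may be flagged as the main chromosome.
    genes : DataFrame
        Columns ``gene_id, replicon, begin, end, strand, gc,
        nonrepetitive_nt, desc``; coordinates are 1-based inclusive.
    """

    def __init__(self, replicons: Sequence[Replicon], genes: pd.DataFrame):
        self.replicons = list(replicons)
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate replicon ids")
        n_main = sum(r.is_main for r in self.replicons)
        if n_main > 1:
            raise ValidationError("at most one replicon may be flagged main chromosome")
        missing = [c for c in GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValidationError(f"gene table missing required column(s): {missing}")
        genes = genes[GENE_COLUMNS].reset_index(drop=True)
        if genes["gene_id"].duplicated().any():
            dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        lengths = {r.id: r.length for r in self.replicons}
        unknown = set(genes["replicon"]) - set(lengths)
        if unknown:
            raise ValidationError(f"gene(s) reference unknown replicon(s): {sorted(unknown)}")
        if not genes["strand"].isin(["+", "-"]).all():
            bad = genes.loc[~genes["strand"].isin(["+", "-"])].index[0]
            raise ValidationError(f"invalid strand in gene row {bad + 1} (must be '+' or '-')")
        begin = genes["begin"].to_numpy()
        end = genes["end"].to_numpy()
        if (begin < 1).any() or (begin > end).any():
            bad = int(np.flatnonzero((begin < 1) | (begin > end))[0])
            raise ValidationError(
                f"gene {genes['gene_id'].iloc[bad]!r}: invalid interval "
                f"[{begin[bad]}, {end[bad]}] (need 1 <= begin <= end)"
            )
        rep_len = genes["replicon"].map(lengths).to_numpy()
        if (end > rep_len).any():
            bad = int(np.flatnonzero(end > rep_len)[0])
            raise ValidationError(
                f"gene {genes['gene_id'].iloc[bad]!r} extends past its replicon end"
            )
        if ((genes["gc"] < 0) | (genes["gc"] > 1)).any():
            raise ValidationError("gc fraction outside [0, 1]")
        span = end - begin + 1
        if (genes["nonrepetitive_nt"] < 0).any() or (genes["nonrepetitive_nt"] > span).any():
            raise ValidationError("nonrepetitive_nt must be within [0, gene length]")
        self.genes = genes

    @property
    def main_chromosome(self) -> Replicon | None:
        for r in self.replicons:
            if r.is_main:
                return r
        return None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise ValidationError(f"unknown replicon {replicon_id!r}")

    def genes_sorted(self) -> pd.DataFrame:
        """Genes ordered by replicon (main chromosome first) then position."""
        order = {r.id: (0 if r.is_main else 1, r.id) for r in self.replicons}
        g = self.genes.copy()
        g["_key"] = g["replicon"].map(order)
        g = g.sort_values(["_key", "begin", "end"], kind="mergesort").drop(columns="_key")
        return g.reset_index(drop=True)

    def locate(self, replicon_ids: Iterable[str], positions: Iterable[int]) -> pd.DataFrame:
        """Assign positions to genes.

        Returns a DataFrame with ``gene_id`` (NA for intergenic positions)
        and ``gene_fraction`` = (pos - begin + 1) / (end - begin + 1),
        computed in the + coordinate direction regardless of gene strand.
        If genes overlap, the containing gene with the largest ``begin``
        wins.
        """
        replicon_ids = np.asarray(list(replicon_ids), dtype=object)
        positions = np.asarray(list(positions), dtype=np.int64)
        gene_id = np.full(len(positions), None, dtype=object)
        fraction = np.full(len(positions), np.nan)
        for rep in self.replicons:
            sel = np.flatnonzero(replicon_ids == rep.id)
            if len(sel) == 0:
                continue
            sub = self.genes[self.genes["replicon"] == rep.id].sort_values("begin")
            if len(sub) == 0:
                continue
            begins = sub["begin"].to_numpy()
            ends = sub["end"].to_numpy()
            names = sub["gene_id"].to_numpy()
            idx = np.searchsorted(begins, positions[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(len(sel), dtype=bool)
            hit[ok] = positions[sel[ok]] <= ends[idx[ok]]
            gidx = idx[hit]
            gene_id[sel[hit]] = names[gidx]
            span = (ends[gidx] - begins[gidx] + 1).astype(float)
            fraction[sel[hit]] = (positions[sel[hit]] - begins[gidx] + 1) / span
        return pd.DataFrame({"gene_id": gene_id, "gene_fraction": fraction})


class InsertionPool:
    """Barcoded transposon insertion strains.

    ``strains`` has columns ``barcode, replicon, strand, pos, n_reads`` and,
    after :meth:`annotate`, ``gene_id`` and ``gene_fraction``.
    """

    def __init__(self, strains: pd.DataFrame, genome: GenomeModel | None = None):
        missing = [c for c in POOL_COLUMNS if c not in strains.columns]
        if missing:
            raise ValidationError(f"pool table missing required column(s): {missing}")
        keep = POOL_COLUMNS + [c for c in ("gene_id", "gene_fraction") if c in strains.columns]
        strains = strains[keep].reset_index(drop=True)
        if strains["barcode"].duplicated().any():
            dup = strains.loc[strains["barcode"].duplicated(), "barcode"].iloc[0]
            raise ValidationError(f"duplicate barcode {dup!r}")
        if (strains["pos"] < 1).any():
            raise ValidationError("insertion position must be >= 1")
        if (strains["n_reads"] < 0).any():
            raise ValidationError("Tn-seq read counts must be non-negative")
        if not strains["strand"].isin(["+", "-"]).all():
            raise ValidationError("pool strand must be '+' or '-'")
        if genome is not None:
            lengths = {r.id: r.length for r in genome.replicons}
            unknown = set(strains["replicon"]) - set(lengths)
            if unknown:
                raise ValidationError(f"pool references unknown replicon(s): {sorted(unknown)}")
            too_far = strains["pos"] > strains["replicon"].map(lengths)
            if too_far.any():
                bc = strains.loc[too_far, "barcode"].iloc[0]
                raise ValidationError(f"strain {bc!r} lies past its replicon end")
        self.strains = strains

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def is_annotated(self) -> bool:
        return "gene_id" in self.strains.columns

    def annotate(self, genome: GenomeModel) -> "InsertionPool":
        """Return a copy with gene assignments and gene fractions filled in."""
        located = genome.locate(self.strains["replicon"], self.strains["pos"])
        strains = self.strains[POOL_COLUMNS].copy()
        strains["gene_id"] = located["gene_id"].to_numpy()
        strains["gene_fraction"] = located["gene_fraction"].to_numpy()
        return InsertionPool(strains, genome=genome)

    def central_mask(self, lo: float = 0.1, hi: float = 0.9) -> pd.Series:
        if not self.is_annotated:
            raise ValidationError("pool must be annotated against a genome first")
        frac = self.strains["gene_fraction"]
        return self.strains["gene_id"].notna() & (frac >= lo) & (frac <= hi)
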