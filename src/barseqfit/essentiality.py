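"""Essential-gene calling from transposon insertion statistics.

Two median-scaled statistics are computed per gene from central insertions
(those landing in 10–90% of the gene length): ``dens``, the density of
distinct insertion positions per non-repetitive nucleotide, and
``normreads``, GC-corrected Tn-seq reads per kilobase.  Both are scaled so
that their median over analyzable genes (>= 100 non-repetitive nt) is 1.
A gene is called essential when both statistics fall below 0.2 and its
mutants were too scarce at Time0 to yield fitness scores; genes below the
cutoff on only one statistic (or on both but with measurable fitness) are
called nearly essential.

GC correction: analyzable genes are binned by GC fraction (width 0.05) and
each gene's raw reads/kb is divided by its bin's median; bins with fewer
than 10 genes fall back to the global median.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig, ValidationError
from .genome import GenomeModel, InsertionPool

CALL_ESSENTIAL = "essential"
CALL_NEARLY = "nearly_essential"
CALL_DISPENSABLE = "dispensable"
CALL_NOT_ANALYZABLE = "not_analyzable"


def compute_insertion_stats(
    pool: InsertionPool,
    genome: GenomeModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-gene central-insertion statistics.

    Returns a DataFrame indexed by gene_id with columns ``analyzable,
    n_central_positions, central_reads, raw_density, reads_per_kb, dens,
    normreads``.  ``dens`` and ``normreads`` are median-scaled to 1 over
    analyzable genes; they are NaN for non-analyzable genes, and NaN
    everywhere (with a warning) when the library is degenerate (median raw
    density 0).
    """
    if not pool.is_annotated:
        pool = pool.annotate(genome)
    genes = genome.genes.set_index("gene_id")
    central = pool.strains[pool.central_mask(config.central_lo, config.central_hi)]

    # distinct insertion positions (strand ignored) and total reads per gene
    pos_counts = (
        central.drop_duplicates(["gene_id", "replicon", "pos"]).groupby("gene_id").size()
    )
    read_sums = central.groupby("gene_id")["n_reads"].sum()

    out = pd.DataFrame(index=genes.index)
    out["analyzable"] = genes["nonrepetitive_nt"] >= config.min_nonrepetitive_nt
    out["n_central_positions"] = pos_counts.reindex(genes.index).fillna(0).astype(int)
    out["central_reads"] = read_sums.reindex(genes.index).fillna(0).astype(int)
    nonrep = genes["nonrepetitive_nt"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["raw_density"] = np.where(nonrep > 0, out["n_central_positions"] / nonrep, np.nan)
        out["reads_per_kb"] = np.where(nonrep > 0, out["central_reads"] / (nonrep / 1000.0), np.nan)

    analyzable = out["analyzable"].to_numpy()
    med_density = float(np.nanmedian(out.loc[analyzable, "raw_density"])) if analyzable.any() else 0.0
    out["dens"] = np.nan
    out["normreads"] = np.nan
    if not analyzable.any() or med_density == 0 or not np.isfinite(med_density):
        warnings.warn(
            "degenerate library: median raw insertion density over analyzable genes is 0; "
            "dens/normreads are undefined",
            stacklevel=2,
        )
        return out

    out.loc[analyzable, "dens"] = out.loc[analyzable, "raw_density"] / med_density

    # GC correction of reads/kb, then median scaling
    gc_bin = np.floor(genes["gc"].to_numpy() / config.gc_bin_width).astype(int)
    rpk = out["reads_per_kb"].copy()
    global_med = float(np.nanmedian(rpk[analyzable]))
    corrected = pd.Series(np.nan, index=out.index)
    for b in np.unique(gc_bin[analyzable]):
        sel = analyzable & (gc_bin == b)
        bin_med = float(np.nanmedian(rpk[sel])) if sel.sum() >= config.gc_min_bin_genes else global_med
        if bin_med == 0 or not np.isfinite(bin_med):
            bin_med = global_med
        if bin_med == 0 or not np.isfinite(bin_med):
            bin_med = 1.0
        corrected[sel] = rpk[sel] / bin_med
    med_corrected = float(np.nanmedian(corrected[analyzable]))
    if med_corrected > 0 and np.isfinite(med_corrected):
        out.loc[analyzable, "normreads"] = corrected[analyzable] / med_corrected
    else:
        out.loc[analyzable, "normreads"] = corrected[analyzable]
    return out


def call_essentiality(
    stats: pd.DataFrame,
    fitness_availability: Mapping[str, bool] | pd.Series | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Classify genes as essential / nearly essential / dispensable.

    ``fitness_availability`` maps gene_id -> whether the companion fitness
    analysis produced fitness values for the gene (absent genes count as
    False).  A gene is essential when dens and normreads are both below the
    0.2 cutoff *and* no fitness could be measured; if only one statistic is
    below the cutoff — or both are but fitness was measurable — it is nearly
    essential.
    """
    if fitness_availability is None:
        fitness_availability = {}
    thr = config.essentiality_threshold
    out = stats[["analyzable", "dens", "normreads"]].copy()
    avail = pd.Series(
        [bool(fitness_availability.get(g, False)) for g in out.index], index=out.index
    )
    out["has_fitness"] = avail

    analyzable = out["analyzable"].to_numpy(dtype=bool)
    if analyzable.any() and out.loc[analyzable, ["dens", "normreads"]].isna().any().any():
        raise ValidationError(
            "degenerate library: dens/normreads undefined for analyzable genes; "
            "compute_insertion_stats on a non-empty pool first"
        )
    low_d = out["dens"] < thr
    low_r = out["normreads"] < thr
    both = low_d & low_r
    one = low_d ^ low_r

    call = np.full(len(out), CALL_DISPENSABLE, dtype=object)
    call[(both & ~avail).to_numpy()] = CALL_ESSENTIAL
    call[(one | (both & avail)).to_numpy()] = CALL_NEARLY
    call[~analyzable] = CALL_NOT_ANALYZABLE
    out["call"] = call
    return out


def call_dispensable_from_positions(
    position_reads: Iterable[tuple[int, int]],
    gene: Mapping[str, int] | tuple[int, int],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> bool:
    """Dispensability from raw (position, reads) pairs within one gene.

    Counts only central positions (10–90% of gene length) with more than one
    read; the gene is dispensable for viability when at least 10 such
    positions carry at least 100 reads in total.
    """
    if isinstance(gene, tuple):
        begin, end = gene
    else:
        begin, end = int(gene["begin"]), int(gene["end"])
    span = end - begin + 1
    if span < 1:
        raise ValidationError("gene interval is empty")
    n_pos = 0
    total = 0
    for pos, reads in position_reads:
        if not begin <= pos <= end:
            raise ValidationError(f"position {pos} outside gene [{begin}, {end}]")
        frac = (pos - begin + 1) / span
        if frac < config.central_lo or frac > config.central_hi:
            continue
        if reads <= config.dispensable_ignore_reads:
            continue
        n_pos += 1
        total += reads
    return n_pos >= config.dispensable_min_positions and total >= config.dispensable_min_reads
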