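"""Phenotype analytics on a fitted gene x experiment fitness matrix.

* significant phenotypes: |f| > 0.5 and |t| > 4;
* empirical FDR: genes called significant across Time0-vs-Time0 null
  comparisons, scaled to the number of condition experiments;
* specific phenotypes: a strong effect (|f| > 1, |t| > 5) in a condition
  for a gene that is near-neutral (|f| < 1) in at least 95% of its
  experiments and whose effect exceeds its own 95th percentile of |f| by
  0.5;
* cofitness: pairwise-complete Pearson correlation of two genes' fitness
  profiles; r >= 0.8 flags likely shared function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig, ValidationError

logger = logging.getLogger(__name__)


def significant_phenotypes(
    f: pd.DataFrame,
    t: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Long table of per-(gene, experiment) significance calls.

    Only measured (non-NA) entries are returned; ``significant`` is True
    when |f| and |t| clear the configured thresholds.
    """
    if not f.index.equals(t.index) or not f.columns.equals(t.columns):
        raise ValidationError("fitness and t matrices must share index and columns")
    long = pd.concat(
        {"f": f.stack(), "t": t.stack()}, axis=1
    ).reset_index()
    long.columns = ["gene_id", "experiment", "f", "t"]
    long = long.dropna(subset=["f", "t"])
    long["significant"] = (long["f"].abs() > config.sig_min_abs_f) & (
        long["t"].abs() > config.sig_min_abs_t
    )
    return long.reset_index(drop=True)


def significant_summary(
    f: pd.DataFrame,
    t: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-gene summary: number of significant experiments and any-flag."""
    sig = (f.abs() > config.sig_min_abs_f) & (t.abs() > config.sig_min_abs_t)
    sig &= f.notna() & t.notna()
    return pd.DataFrame(
        {
            "n_experiments": f.notna().sum(axis=1),
            "n_significant": sig.sum(axis=1),
            "any_significant": sig.any(axis=1),
        },
        index=f.index,
    )


@dataclass(frozen=True)
class FdrEstimate:
    """Empirical false-discovery estimate from Time0 null comparisons."""

    n_fp_time0: int
    n_time0_comparisons: int
    n_condition_experiments: int
    n_significant_genes: int
    expected_fp: int
    fdr: float

    def as_dict(self) -> dict:
        return {
            "n_fp_time0": self.n_fp_time0,
            "n_time0_comparisons": self.n_time0_comparisons,
            "n_condition_experiments": self.n_condition_experiments,
            "n_significant_genes": self.n_significant_genes,
            "expected_fp": self.expected_fp,
            "fdr": self.fdr,
        }


def estimate_fdr(
    n_fp_time0: int,
    n_time0_comparisons: int,
    n_condition_experiments: int,
    n_significant_genes: int,
) -> FdrEstimate:
    """Scale Time0 false positives to the condition experiments.

    expected_fp = round(n_fp_time0 * n_condition_experiments /
    n_time0_comparisons) (nearest integer); fdr = expected_fp /
    n_significant_genes.
    """
    for name, v in (
        ("n_fp_time0", n_fp_time0),
        ("n_time0_comparisons", n_time0_comparisons),
        ("n_condition_experiments", n_condition_experiments),
        ("n_significant_genes", n_significant_genes),
    ):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    if n_time0_comparisons < 1:
        raise ValidationError("need at least one Time0 comparison")
    if n_significant_genes < 1:
        raise ValidationError("need at least one significant gene")
    # nearest integer (half rounds up), in exact integer arithmetic
    expected_fp = (2 * n_fp_time0 * n_condition_experiments + n_time0_comparisons) // (
        2 * n_time0_comparisons
    )
    return FdrEstimate(
        n_fp_time0=int(n_fp_time0),
        n_time0_comparisons=int(n_time0_comparisons),
        n_condition_experiments=int(n_condition_experiments),
        n_significant_genes=int(n_significant_genes),
        expected_fp=expected_fp,
        fdr=expected_fp / n_significant_genes,
    )


def specific_phenotypes(
    f: pd.DataFrame,
    t: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Condition-specific phenotypes.

    A (gene, experiment) pair qualifies when |f| > 1 and |t| > 5, the gene
    has |f| < 1 in at least 95% of its measured experiments, and |f|
    exceeds the gene's 95th percentile of |f| (linear interpolation over
    its non-NA values) by at least 0.5.  Genes with fewer than
    ``config.specific_min_experiments`` measured experiments are skipped.
    """
    if not f.index.equals(t.index) or not f.columns.equals(t.columns):
        raise ValidationError("fitness and t matrices must share index and columns")
    rows = []
    absf = f.abs()
    n_meas = absf.notna().sum(axis=1)
    skipped = 0
    for gene in f.index:
        n = int(n_meas[gene])
        if n == 0:
            continue
        if n < config.specific_min_experiments:
            skipped += 1
            continue
        a = absf.loc[gene]
        quiet_frac = float((a < config.specific_min_abs_f).sum()) / n
        if quiet_frac < config.specific_quiet_fraction:
            continue
        pct95 = float(np.nanpercentile(a.to_numpy(dtype=float), 95))
        hits = a[
            (a > config.specific_min_abs_f)
            & (t.loc[gene].abs() > config.specific_min_abs_t)
            & (a > pct95 + config.specific_margin)
        ]
        for exp in hits.index:
            rows.append(
                (gene, exp, float(f.loc[gene, exp]), float(t.loc[gene, exp]), pct95)
            )
    if skipped:
        logger.info("specific_phenotypes: skipped %d gene(s) with < %d measured experiments",
                    skipped, config.specific_min_experiments)
    return pd.DataFrame(rows, columns=["gene_id", "experiment", "f", "t", "pct95_abs_f"])


def _pairwise_block(
    xz: np.ndarray, m: np.ndarray, xz2: np.ndarray, rows: slice
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r between genes in ``rows`` and all genes."""
    mb, xb, x2b = m[rows], xz[rows], xz2[rows]
    n = mb @ m.T
    sx = xb @ m.T
    sy = mb @ xz.T
    sxx = x2b @ m.T
    syy = mb @ xz2.T
    sxy = xb @ xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx ** 2
        vy = n * syy - sy ** 2
        r = cov / np.sqrt(vx * vy)
    r[(vx <= 1e-12) | (vy <= 1e-12)] = np.nan
    return r, n


def cofitness(
    f: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
    report_floor: float | None = None,
    block_size: int = 512,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cofitness pairs and per-gene best partners.

    Pearson correlation is computed over each pair's shared non-NA
    experiments (pairwise-complete); pairs with fewer than
    ``min(config.cofit_min_overlap, n_experiments)`` shared experiments, or
    with a zero-variance member, are suppressed.  Returns ``(pairs,
    per_gene)``: ``pairs`` lists unordered pairs with r >= ``report_floor``
    (default: the high-cofitness threshold) flagged via ``high_cofit``;
    ``per_gene`` gives each gene's maximum-r partner.
    """
    if report_floor is None:
        report_floor = config.cofit_threshold
    n_exp = f.shape[1]
    min_overlap = min(config.cofit_min_overlap, n_exp)
    keep = f.notna().sum(axis=1) > 0
    fk = f.loc[keep]
    genes = fk.index.to_numpy()
    x = fk.to_numpy(dtype=float)
    m = np.isfinite(x)
    xz = np.where(m, x, 0.0)
    xz2 = xz ** 2
    mf = m.astype(float)

    pair_rows = []
    best_partner = np.full(len(genes), None, dtype=object)
    best_r = np.full(len(genes), -np.inf)
    n_genes = len(genes)
    n_zero_var = 0
    for start in range(0, n_genes, block_size):
        rows = slice(start, min(start + block_size, n_genes))
        r, n = _pairwise_block(xz, mf, xz2, rows)
        valid = (n >= min_overlap) & np.isfinite(r)
        idx = np.arange(rows.start, rows.stop)
        valid[np.arange(len(idx)), idx] = False  # drop self-pairs
        r_masked = np.where(valid, r, -np.inf)
        arg = np.argmax(r_masked, axis=1)
        rmax = r_masked[np.arange(len(idx)), arg]
        upd = rmax > best_r[idx]
        best_r[idx[upd]] = rmax[upd]
        best_partner[idx[upd]] = genes[arg[upd]]
        # unordered pairs above the reporting floor (upper triangle only)
        hit_i, hit_j = np.nonzero(valid & (r >= report_floor))
        keep_ut = idx[hit_i] < hit_j
        for i, j in zip(hit_i[keep_ut], hit_j[keep_ut]):
            pair_rows.append(
                (genes[idx[i]], genes[j], float(r[i, j]), int(n[i, j]))
            )
        n_zero_var += int(np.isnan(r).all(axis=1).sum())

    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "r", "n_overlap"])
    pairs["high_cofit"] = pairs["r"] >= config.cofit_threshold
    pairs = pairs.sort_values("r", ascending=False).reset_index(drop=True)
    per_gene = pd.DataFrame(
        {
            "best_partner": best_partner,
            "best_r": np.where(np.isfinite(best_r), best_r, np.nan),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    if n_zero_var:
        logger.info("cofitness: %d gene(s) had no valid pair (zero variance or low overlap)",
                    n_zero_var)
    return pairs, per_gene
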