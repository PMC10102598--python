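"""Gene fitness estimation from BarSeq counts.

The model follows standard RB-TnSeq practice.  For each condition sample,
the Time0 samples of its group are summed into one reference vector, and
each strain's fitness is the normalized log2 ratio of its (pseudocounted)
relative abundance after versus before selection:

    r_s = log2((n_cond,s + ps) / D_cond) - log2((n_t0,s + ps) / D_t0)

where D is the sample's total reads plus one pseudocount per strain.  A
strain is usable when its insertion lies in the central 10–90% of a gene
and it has enough Time0 reads.  Gene fitness is the inverse-variance
weighted average of usable strain ratios, with the count-based variance

    v_s = (1/(n_cond,s + ps) + 1/(n_t0,s + ps)) / (ln 2)^2 ,  w_s = 1/v_s .

Because replicating regions near the origin are over-represented in
growing cells, fitness is then normalized positionally: a centered running
median along the main chromosome (window 251 genes) is subtracted, small
replicons are centered on their plain median, and finally the mode of the
main-chromosome values (Gaussian KDE, Silverman bandwidth) is subtracted
from all genes so that a typical gene has fitness 0.

The significance statistic is t = f / sqrt(sigma0^2 + Vg) with
Vg = max(Vcount, Vspread), Vcount = 1 / sum(w_s), and Vspread the weighted
sample variance of strain ratios about the gene mean divided by the number
of strains; sigma0 is a variance floor (default 0.1) that keeps |t| honest
for very deeply sequenced genes.

The user-facing surface is :class:`FitnessModel` / :class:`FitnessResults`
in the statsmodels style; the stage functions below are the building
blocks and remain directly callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .config import DEFAULT_CONFIG, AnalysisConfig, ValidationError
from .design import ExperimentDesign
from .genome import GenomeModel, InsertionPool

LN2_SQ = np.log(2.0) ** 2


def _check_counts(counts: pd.DataFrame, design: ExperimentDesign) -> None:
    missing = [s for s in design.samples if s not in counts.columns]
    if missing:
        raise ValidationError(f"counts table lacks sample column(s): {missing}")
    if (counts[design.samples].to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")


def strain_log_ratios(
    counts: pd.DataFrame,
    design: ExperimentDesign,
    pool: InsertionPool,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-(strain, condition sample) log2 ratios and weights.

    Returns a long DataFrame with columns ``barcode, experiment, gene_id,
    gene_fraction, t0_reads, ratio, weight, usable``.
    """
    if not pool.is_annotated:
        raise ValidationError("pool must be annotated against a genome")
    _check_counts(counts, design)
    strains = pool.strains.set_index("barcode")
    missing = counts.index.difference(strains.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} barcode(s) in counts are absent from the pool "
            f"(first: {missing[0]!r})"
        )
    strains = strains.reindex(counts.index)
    ps = config.pseudocount
    n = len(counts)

    t0_sum: dict[str, np.ndarray] = {}
    for group in set(design.frame["time0_group"]):
        t0_samples = design.time0_of_group(group)
        if t0_samples:
            t0_sum[group] = counts[t0_samples].to_numpy(dtype=float).sum(axis=1)

    central = (
        strains["gene_id"].notna()
        & (strains["gene_fraction"] >= config.central_lo)
        & (strains["gene_fraction"] <= config.central_hi)
    ).to_numpy()

    frames = []
    for _, row in design.condition_samples.iterrows():
        sample, group = row["sample"], row["time0_group"]
        if group not in t0_sum:
            raise ValidationError(f"condition sample {sample!r}: Time0 group {group!r} is empty")
        n_c = counts[sample].to_numpy(dtype=float)
        n_0 = t0_sum[group]
        if n_c.sum() == 0:
            raise ValidationError(f"sample {sample!r} has no reads")
        if n_0.sum() == 0:
            raise ValidationError(f"Time0 group {group!r} has no reads")
        d_c = n_c.sum() + ps * n
        d_0 = n_0.sum() + ps * n
        ratio = np.log2((n_c + ps) / d_c) - np.log2((n_0 + ps) / d_0)
        weight = LN2_SQ / (1.0 / (n_c + ps) + 1.0 / (n_0 + ps))
        usable = central & (n_0 >= config.min_t0_reads)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": counts.index,
                    "experiment": sample,
                    "gene_id": strains["gene_id"].to_numpy(),
                    "gene_fraction": strains["gene_fraction"].to_numpy(),
                    "t0_reads": n_0,
                    "ratio": ratio,
                    "weight": weight,
                    "usable": usable,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["barcode", "experiment", "gene_id", "gene_fraction",
                     "t0_reads", "ratio", "weight", "usable"]
        )
    return pd.concat(frames, ignore_index=True)


def gene_fitness_unnormalized(
    strain_fitness: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted-average raw gene fitness per experiment.

    Returns ``(f_raw, gene_stats)``: ``f_raw`` is a gene x experiment
    DataFrame (NaN where the gene lacked sufficient Time0 abundance), and
    ``gene_stats`` a long DataFrame with the per-gene sums needed by the t
    statistic (``n_strains, sum_w, sum_wr, sum_wr2, t0_reads, f_raw,
    has_fitness``).
    """
    use = strain_fitness[strain_fitness["usable"] & strain_fitness["gene_id"].notna()].copy()
    if len(use) == 0:
        return pd.DataFrame(), pd.DataFrame(
            columns=["experiment", "gene_id", "n_strains", "sum_w", "sum_wr",
                     "sum_wr2", "t0_reads", "f_raw", "has_fitness"]
        )
    use["wr"] = use["weight"] * use["ratio"]
    use["wr2"] = use["weight"] * use["ratio"] ** 2
    g = use.groupby(["experiment", "gene_id"], sort=True, observed=True)
    stats = g.agg(
        n_strains=("ratio", "size"),
        sum_w=("weight", "sum"),
        sum_wr=("wr", "sum"),
        sum_wr2=("wr2", "sum"),
        t0_reads=("t0_reads", "sum"),
    ).reset_index()
    stats["f_raw"] = stats["sum_wr"] / stats["sum_w"]
    stats["has_fitness"] = stats["t0_reads"] >= config.min_gene_t0_reads
    kept = stats[stats["has_fitness"]]
    f_raw = kept.pivot(index="gene_id", columns="experiment", values="f_raw")
    return f_raw, stats


def estimate_mode(
    values: np.ndarray, step: float = 0.01, pad: float = 0.5
) -> float:
    """Mode of a sample via Gaussian KDE (Silverman bandwidth) on a fixed
    grid aligned to multiples of ``step``; ties resolved toward 0."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return 0.0
    if len(v) < 2 or np.std(v) == 0:
        return float(np.median(v))
    k0 = int(np.floor((v.min() - pad) / step))
    k1 = int(np.ceil((v.max() + pad) / step))
    grid = np.arange(k0, k1 + 1, dtype=float) * step
    density = gaussian_kde(v, bw_method="silverman")(grid)
    near_max = grid[density >= density.max() - 1e-12]
    return float(near_max[np.argmin(np.abs(near_max))])


def positional_normalize(
    f_raw: pd.DataFrame | pd.Series,
    genome: GenomeModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame | pd.Series:
    """Remove positional (copy-number) trends and center the mode at 0.

    For replicons with at least ``config.min_replicon_genes`` genes a
    centered running median (window ``config.window`` genes, truncated at
    the replicon ends) is subtracted from each gene; smaller replicons are
    centered on their plain median.  The mode of the main-chromosome values
    is then subtracted from all genes.  Input rows are reindexed to the
    genome's positional gene order; NA entries stay NA.
    """
    squeeze = isinstance(f_raw, pd.Series)
    mat = f_raw.to_frame() if squeeze else f_raw
    order = genome.genes_sorted()
    unknown = mat.index.difference(order["gene_id"])
    if len(unknown):
        raise ValidationError(f"fitness rows for unknown gene(s), first: {unknown[0]!r}")
    mat = mat.reindex(order["gene_id"])
    out = mat.copy()
    gene_replicon = order.set_index("gene_id")["replicon"]
    main = genome.main_chromosome
    for rep in genome.replicons:
        sel = gene_replicon == rep.id
        block = mat.loc[sel.to_numpy()]
        if len(block) == 0:
            continue
        if len(block) >= config.min_replicon_genes:
            trend = block.rolling(config.window, center=True, min_periods=1).median()
        else:
            trend = block.median(axis=0)
        out.loc[sel.to_numpy()] = block - trend
    if main is not None:
        on_main = (gene_replicon == main.id).to_numpy()
        for col in out.columns:
            mode = estimate_mode(
                out.loc[on_main, col].to_numpy(), config.mode_grid_step, config.mode_pad
            )
            out[col] = out[col] - mode
    return out.iloc[:, 0] if squeeze else out


def t_statistics(
    f: pd.DataFrame,
    gene_stats: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """t-like significance statistic, aligned with the fitness matrix."""
    gs = gene_stats[gene_stats["has_fitness"]].copy()
    v_count = 1.0 / gs["sum_w"]
    spread = (gs["sum_wr2"] / gs["sum_w"]) - gs["f_raw"] ** 2
    v_spread = spread.clip(lower=0.0) / gs["n_strains"]
    v_spread[gs["n_strains"] < 2] = np.nan
    gs["v_g"] = np.fmax(v_count, v_spread)  # NaN Vspread -> Vcount alone
    v = gs.pivot(index="gene_id", columns="experiment", values="v_g")
    v = v.reindex(index=f.index, columns=f.columns)
    return f / np.sqrt(config.sigma0 ** 2 + v)


def _half_fitness(
    strain_fitness: pd.DataFrame,
    genome: GenomeModel,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene fitness recomputed from the first-half vs second-half insertions
    (gene_fraction in [0.1, 0.5) vs [0.5, 0.9]); used for the cor12/mad12
    QC metrics."""
    halves = []
    mid = 0.5
    for lo, hi in ((config.central_lo, mid), (mid, config.central_hi)):
        if lo == mid:
            sel = strain_fitness["gene_fraction"] >= mid
        else:
            sel = strain_fitness["gene_fraction"] < mid
        sub = strain_fitness[strain_fitness["usable"] & sel]
        half_cfg = config.replace(min_gene_t0_reads=max(1, config.min_gene_t0_reads // 2))
        f_raw, _ = gene_fitness_unnormalized(sub, half_cfg)
        if f_raw.empty:
            halves.append(pd.DataFrame())
        else:
            halves.append(positional_normalize(f_raw, genome, config))
    return halves[0], halves[1]


@dataclass
class QCReport:
    experiment: str
    gmed: float
    cor12: float
    mad12: float
    passed: bool


def compute_qc(
    strain_fitness: pd.DataFrame,
    gene_stats: pd.DataFrame,
    genome: GenomeModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-experiment quality control.

    ``gmed`` is the median summed Time0 reads over genes with fitness;
    ``cor12``/``mad12`` compare gene fitness recomputed from insertions in
    the first vs second half of each gene.
    """
    h1, h2 = _half_fitness(strain_fitness, genome, config)
    rows = []
    for exp in sorted(strain_fitness["experiment"].unique()):
        gs = gene_stats[(gene_stats["experiment"] == exp) & gene_stats["has_fitness"]]
        gmed = float(gs["t0_reads"].median()) if len(gs) else 0.0
        cor12, mad12 = np.nan, np.nan
        if not h1.empty and not h2.empty and exp in h1.columns and exp in h2.columns:
            both = pd.concat([h1[exp].rename("a"), h2[exp].rename("b")], axis=1).dropna()
            if len(both) >= 3:
                cor12 = float(both["a"].corr(both["b"]))
                mad12 = float((both["a"] - both["b"]).abs().median())
        passed = bool(
            gmed >= config.qc_min_gmed
            and np.isfinite(cor12)
            and cor12 >= config.qc_min_cor12
            and np.isfinite(mad12)
            and mad12 <= config.qc_max_mad12
        )
        rows.append(QCReport(exp, gmed, cor12, mad12, passed))
    return pd.DataFrame([r.__dict__ for r in rows])


class FitnessModel:
    """Pooled-fitness model for one BarSeq counts table.

    Parameters
    ----------
    counts : DataFrame
        Barcode x sample read counts (index = barcode).
    design : ExperimentDesign
        Sample roles, Time0 groups and condition names.
    pool : InsertionPool
        Barcode -> insertion mapping (annotated against ``genome`` if not
        already).
    genome : GenomeModel
    config : AnalysisConfig, optional

    ``fit()`` returns a :class:`FitnessResults` with the gene x experiment
    fitness and t matrices, per-experiment QC, and phenotype analytics.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: ExperimentDesign,
        pool: InsertionPool,
        genome: GenomeModel,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ):
        self.counts = counts
        self.design = design
        self.genome = genome
        self.config = config
        self.pool = pool if pool.is_annotated else pool.annotate(genome)
        _check_counts(counts, design)

    @classmethod
    def from_tables(
        cls,
        counts: pd.DataFrame,
        design_frame: pd.DataFrame,
        pool_frame: pd.DataFrame,
        genome: GenomeModel,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ) -> "FitnessModel":
        return cls(counts, ExperimentDesign(design_frame), InsertionPool(pool_frame), genome, config)

    def fit(self, compute_quality: bool = True) -> "FitnessResults":
        sf = strain_log_ratios(self.counts, self.design, self.pool, self.config)
        f_raw, gene_stats = gene_fitness_unnormalized(sf, self.config)
        exp_order = [s for s in self.design.condition_samples["sample"]]
        if f_raw.empty:
            order = self.genome.genes_sorted()["gene_id"]
            f = pd.DataFrame(np.nan, index=order, columns=exp_order)
            t = f.copy()
            qc = pd.DataFrame(columns=["experiment", "gmed", "cor12", "mad12", "passed"])
        else:
            f = positional_normalize(f_raw, self.genome, self.config)
            f = f.reindex(columns=exp_order)
            t = t_statistics(f, gene_stats, self.config)
            qc = (
                compute_qc(sf, gene_stats, self.genome, self.config)
                if compute_quality
                else pd.DataFrame(columns=["experiment", "gmed", "cor12", "mad12", "passed"])
            )
        return FitnessResults(
            fitness=f, t=t, qc=qc, gene_stats=gene_stats, strain_fitness=sf,
            model=self,
        )


class FitnessResults:
    """Fitted gene fitness matrix with significance and QC.

    Attributes
    ----------
    fitness, t : DataFrame
        Gene x experiment matrices (NaN where the gene lacked sufficient
        Time0 abundance); rows follow genome order.
    qc : DataFrame
        Per-experiment ``gmed, cor12, mad12, passed``.
    gene_stats, strain_fitness : DataFrame
        Per-gene and per-strain intermediates.
    """

    def __init__(self, fitness, t, qc, gene_stats, strain_fitness, model):
        self.fitness = fitness
        self.t = t
        self.qc = qc
        self.gene_stats = gene_stats
        self.strain_fitness = strain_fitness
        self.model = model
        self.config = model.config

    @property
    def experiments(self) -> list[str]:
        return list(self.fitness.columns)

    @property
    def gene_has_fitness(self) -> pd.Series:
        """Whether each gene has at least one measured fitness value; this
        feeds the essentiality caller's has_fitness flag."""
        return self.fitness.notna().any(axis=1)

    # phenotype analytics (delegating to the phenotypes module)
    def significant(self) -> pd.DataFrame:
        from . import phenotypes

        return phenotypes.significant_phenotypes(self.fitness, self.t, self.config)

    def significant_summary(self) -> pd.DataFrame:
        from . import phenotypes

        return phenotypes.significant_summary(self.fitness, self.t, self.config)

    def specific_phenotypes(self) -> pd.DataFrame:
        from . import phenotypes

        return phenotypes.specific_phenotypes(self.fitness, self.t, self.config)

    def cofitness(self, report_floor: float | None = None):
        from . import phenotypes

        return phenotypes.cofitness(self.fitness, self.config, report_floor=report_floor)

    def summary(self) -> str:
        n_genes = int(self.gene_has_fitness.sum())
        n_exp = len(self.experiments)
        sig = self.significant()
        n_sig_genes = int(sig.groupby("gene_id")["significant"].any().sum()) if len(sig) else 0
        lines = [
            "Pooled fitness analysis",
            "=" * 55,
            f"genes with fitness:        {n_genes} / {len(self.fitness)}",
            f"condition experiments:     {n_exp}",
            f"experiments passing QC:    {int(self.qc['passed'].sum()) if len(self.qc) else 0}"
            f" / {len(self.qc)}",
            f"genes with a significant phenotype (|f| > {self.config.sig_min_abs_f},"
            f" |t| > {self.config.sig_min_abs_t}): {n_sig_genes}",
            "",
            "Per-experiment QC",
            "-" * 55,
        ]
        if len(self.qc):
            lines.append(self.qc.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        return "\n".join(lines)


def run_fitness_analysis(
    counts: pd.DataFrame,
    pool: InsertionPool,
    genome: GenomeModel,
    design: ExperimentDesign,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> FitnessResults:
    """Functional wrapper: build a :class:`FitnessModel` and fit it."""
    return FitnessModel(counts, design, pool, genome, config).fit()


def time0_null_fitness(
    counts: pd.DataFrame,
    design: ExperimentDesign,
    pool: InsertionPool,
    genome: GenomeModel,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out Time0-vs-Time0 comparisons.

    Each Time0 sample in a group with >= 2 Time0 samples is treated as a
    condition sample against the sum of the remaining Time0 samples of its
    group.  Because no selection separates the two, any significant
    phenotype here is a false positive; these comparisons calibrate the
    empirical FDR.  Returns (f, t) matrices with one column per held-out
    sample.
    """
    if not pool.is_annotated:
        pool = pool.annotate(genome)
    f_cols, t_cols = [], []
    for group, sub in design.time0_samples.groupby("time0_group", sort=True):
        samples = list(sub["sample"])
        if len(samples) < 2:
            continue
        for held in samples:
            rows = [(s, "Time0", group, "Time0", i + 1)
                    for i, s in enumerate(samples) if s != held]
            rows.append((held, "condition", group, "Time0_null", 1))
            sub_design = ExperimentDesign(
                pd.DataFrame(rows, columns=["sample", "role", "time0_group", "condition", "replicate"])
            )
            res = FitnessModel(
                counts[samples], sub_design, pool, genome, config
            ).fit(compute_quality=False)
            f_cols.append(res.fitness[held])
            t_cols.append(res.t[held])
    if not f_cols:
        raise ValidationError("no Time0 group has >= 2 Time0 samples; cannot form null comparisons")
    f = pd.concat(f_cols, axis=1)
    t = pd.concat(t_cols, axis=1)
    return f, t
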