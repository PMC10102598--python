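"""Synthetic RB-TnSeq data with known ground truth.

The generator emulates a two-replicon sulfate-reducer-like genome (a main
chromosome plus a plasmid), a barcoded transposon insertion pool in which
essential genes carry no central (10–90% of gene length) insertions, and
pooled-growth BarSeq counts: per Time0 group, strain abundances are drawn
from a heavy-tailed log-normal, condition samples multiply each disrupted
strain's abundance by 2**f_true(gene, condition), and sequencing is a
multinomial draw at a fixed per-sample depth (optionally Dirichlet-
multinomial for overdispersion).

Every stochastic function takes an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ValidationError
from .design import ExperimentDesign
from .genome import GENE_COLUMNS, GenomeModel, InsertionPool, Replicon

MAIN_REPLICON = "chromosome"
PLASMID_REPLICON = "plasmid"
BARCODE_LENGTH = 20
_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimTruth:
    """Ground truth of a simulation.

    ``essential`` flags genes devoid of viable central-insertion mutants
    (their ``f_true`` rows are NaN — no strains exist to measure).
    ``f_true`` is the expected final normalized log2 fitness ratio per
    (gene, condition).  ``modules`` labels co-regulated gene groups planted
    to carry shared fitness patterns; ``specific`` records planted
    condition-specific effects.
    """

    essential: pd.Series
    f_true: pd.DataFrame
    modules: pd.Series
    specific: set = field(default_factory=set)
    max_abs_fitness: float = 4.0

    @property
    def conditions(self) -> list[str]:
        return list(self.f_true.columns)

    def add_conditions(self, names: list[str]) -> None:
        for name in names:
            if name not in self.f_true.columns:
                self.f_true[name] = np.where(self.essential.to_numpy(), np.nan, 0.0)

    def _set(self, gene_id: str, condition: str, value: float) -> None:
        if self.essential.get(gene_id, False):
            raise ValidationError(f"cannot plant fitness on essential gene {gene_id!r}")
        v = float(np.clip(value, -self.max_abs_fitness, self.max_abs_fitness))
        self.f_true.loc[gene_id, condition] = v


def simulate_genome(
    n_genes: int,
    essential_fraction: float = 0.12,
    plasmid_gene_fraction: float = 0.06,
    seed: int = 0,
    mean_gene_nt: float = 950.0,
    min_gene_nt: int = 200,
    mean_gap_nt: float = 120.0,
    gc_mean: float = 0.63,
    repeat_gene_fraction: float = 0.01,
) -> tuple[GenomeModel, SimTruth]:
    """Simulate a two-replicon genome with flagged essential genes.

    Gene lengths are gamma distributed (minimum ``min_gene_nt``), genes are
    laid head-to-tail with exponential gaps, and per-gene GC follows an
    AR(1) walk around ``gc_mean`` so that GC is positionally autocorrelated
    as in real genomes.  A small fraction of genes gets a reduced
    non-repetitive length (some below the 100-nt analyzability cutoff).
    Exactly ``round(essential_fraction * n_genes)`` genes are flagged
    essential.
    """
    if n_genes < 1:
        raise ValidationError("empty genome: n_genes must be >= 1")
    for name, frac in (
        ("essential_fraction", essential_fraction),
        ("plasmid_gene_fraction", plasmid_gene_fraction),
        ("repeat_gene_fraction", repeat_gene_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    lengths = (min_gene_nt + rng.gamma(3.0, (mean_gene_nt - min_gene_nt) / 3.0, n_genes)).astype(
        np.int64
    )
    gaps = rng.exponential(mean_gap_nt, n_genes).astype(np.int64) + 1
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

    gc = np.empty(n_genes)
    gc[0] = gc_mean + rng.normal(0.0, 0.03)
    for i in range(1, n_genes):
        gc[i] = gc_mean + 0.8 * (gc[i - 1] - gc_mean) + rng.normal(0.0, 0.02)
    gc = np.clip(gc, 0.25, 0.85)

    nonrep = lengths.copy()
    n_repeat = int(round(repeat_gene_fraction * n_genes))
    if n_repeat:
        rep_idx = rng.choice(n_genes, size=n_repeat, replace=False)
        nonrep[rep_idx] = (lengths[rep_idx] * rng.uniform(0.0, 0.6, n_repeat)).astype(np.int64)

    n_plasmid = int(round(plasmid_gene_fraction * n_genes))
    replicon_of = np.array([MAIN_REPLICON] * (n_genes - n_plasmid) + [PLASMID_REPLICON] * n_plasmid)

    rows = []
    cursor = {MAIN_REPLICON: 0, PLASMID_REPLICON: 0}
    for i in range(n_genes):
        rep = replicon_of[i]
        begin = cursor[rep] + gaps[i]
        end = begin + lengths[i] - 1
        cursor[rep] = end
        rows.append((f"g{i:05d}", rep, begin, end, strands[i], round(float(gc[i]), 4),
                     int(nonrep[i]), "simulated protein-coding gene"))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)

    replicons = [Replicon(MAIN_REPLICON, cursor[MAIN_REPLICON] + int(mean_gap_nt) + 1, True)]
    if n_plasmid or cursor[PLASMID_REPLICON]:
        replicons.append(
            Replicon(PLASMID_REPLICON, max(cursor[PLASMID_REPLICON] + int(mean_gap_nt) + 1, 1), False)
        )
    genome = GenomeModel(replicons, genes)

    n_essential = int(round(essential_fraction * n_genes))
    essential = np.zeros(n_genes, dtype=bool)
    if n_essential:
        essential[rng.choice(n_genes, size=n_essential, replace=False)] = True
    truth = SimTruth(
        essential=pd.Series(essential, index=genes["gene_id"], name="essential"),
        f_true=pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id")),
        modules=pd.Series(pd.NA, index=genes["gene_id"], name="module", dtype="object"),
    )
    return genome, truth


def _random_barcodes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unique random 20-nt ACGT barcodes (collision-checked)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), BARCODE_LENGTH))
        codes = _ALPHABET[draw].view(f"S{BARCODE_LENGTH}").ravel().astype(str)
        for c in codes:
            if c not in seen:
                seen.add(c)
                out.append(c)
    return np.array(out, dtype=object)


def simulate_pool(
    genome: GenomeModel,
    truth: SimTruth,
    n_strains: int,
    seed: int = 0,
    leakage: float = 0.0,
    mean_tnseq_reads: float = 20.0,
    tnseq_dispersion: float = 2.0,
) -> InsertionPool:
    """Simulate a barcoded insertion pool.

    Positions are uniform over the summed replicon lengths; a draw landing
    in the central 10–90% of an essential gene is rejected and redrawn,
    except with probability ``leakage`` (modelling rare escapers retained
    at tiny abundance).  Tn-seq read counts are negative binomial with mean
    ``mean_tnseq_reads`` (minimum 1).
    """
    if n_strains < 0:
        raise ValidationError("n_strains must be >= 0")
    if not 0.0 <= leakage <= 1.0:
        raise ValidationError("leakage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reps = genome.replicons
    rep_len = np.array([r.length for r in reps], dtype=np.float64)
    rep_ids = np.array([r.id for r in reps], dtype=object)
    rep_prob = rep_len / rep_len.sum()

    ess = truth.essential

    def draw(n: int) -> pd.DataFrame:
        which = rng.choice(len(reps), size=n, p=rep_prob)
        pos = (rng.random(n) * rep_len[which]).astype(np.int64) + 1
        loc = genome.locate(rep_ids[which], pos)
        df = pd.DataFrame({"replicon": rep_ids[which], "pos": pos})
        df["gene_id"] = loc["gene_id"].to_numpy()
        df["gene_fraction"] = loc["gene_fraction"].to_numpy()
        return df

    accepted: list[pd.DataFrame] = []
    leaked_flags: list[np.ndarray] = []
    remaining = n_strains
    while remaining > 0:
        cand = draw(remaining)
        in_gene = cand["gene_id"].notna().to_numpy()
        central = in_gene & (cand["gene_fraction"] >= 0.1) & (cand["gene_fraction"] <= 0.9)
        is_ess = np.zeros(len(cand), dtype=bool)
        if in_gene.any():
            is_ess[in_gene] = ess.reindex(cand.loc[in_gene, "gene_id"]).to_numpy(dtype=bool)
        lethal = central.to_numpy() & is_ess
        leak = lethal & (rng.random(len(cand)) < leakage)
        keep = ~lethal | leak
        accepted.append(cand[keep])
        leaked_flags.append(leak[keep])
        remaining -= int(keep.sum())

    if n_strains == 0:
        strains = pd.DataFrame(columns=["barcode", "replicon", "strand", "pos", "n_reads",
                                        "gene_id", "gene_fraction"])
        strains["pos"] = strains["pos"].astype(np.int64)
        strains["n_reads"] = strains["n_reads"].astype(np.int64)
        return InsertionPool(strains, genome=genome)

    hits = pd.concat(accepted, ignore_index=True)
    leaked = np.concatenate(leaked_flags)
    p = tnseq_dispersion / (tnseq_dispersion + (mean_tnseq_reads - 1.0))
    strains = pd.DataFrame(
        {
            "barcode": _random_barcodes(n_strains, rng),
            "replicon": hits["replicon"].to_numpy(),
            "strand": np.where(rng.random(n_strains) < 0.5, "+", "-"),
            "pos": hits["pos"].to_numpy(),
            "n_reads": 1 + rng.negative_binomial(tnseq_dispersion, p, n_strains),
            "gene_id": hits["gene_id"].to_numpy(),
            "gene_fraction": hits["gene_fraction"].to_numpy(),
        }
    )
    pool = InsertionPool(strains, genome=genome)
    pool.leaked = pd.Series(leaked, index=strains["barcode"].to_numpy())
    return pool


def simulate_counts(
    pool: InsertionPool,
    truth: SimTruth,
    design: ExperimentDesign,
    doublings: float = 5.0,
    depth: int = 1_000_000,
    seed: int = 0,
    abundance_sigma: float = 1.0,
    abundances: np.ndarray | None = None,
    dirichlet_alpha0: float | None = None,
    drift_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate BarSeq counts for every sample in the design.

    Initial abundances (log-normal, sigma ``abundance_sigma``, normalized to
    sum 1) are drawn once per Time0 group and shared by all of the group's
    samples.  For a condition sample, the abundance of each strain with a
    central insertion in a non-essential gene is multiplied by
    ``2**f_true[gene, condition]``; intergenic and non-central strains keep
    f_true = 0, and escaper strains in essential genes start at 1% of their
    drawn abundance.  Counts are multinomial at ``depth`` per sample (or
    Dirichlet-multinomial when ``dirichlet_alpha0`` is finite).  ``doublings``
    only scales the optional log-normal within-experiment drift term
    (``drift_sd`` per doubling, default 0): f_true is defined as the expected
    final log2 ratio, not a per-doubling rate.

    ``abundances`` overrides the random initial abundances (one value per
    strain, any positive scale); intended for calibration studies.
    """
    if doublings <= 0:
        raise ValidationError("doublings must be > 0")
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    if not pool.is_annotated:
        raise ValidationError("pool must be annotated against a genome")
    rng = np.random.default_rng(seed)
    strains = pool.strains
    n = len(strains)
    barcodes = strains["barcode"].to_numpy()

    unknown = set(design.condition_samples["condition"]) - set(truth.conditions)
    if unknown:
        raise ValidationError(f"unknown condition id(s) in design: {sorted(unknown)}")

    central = pool.central_mask().to_numpy()
    gene_ids = strains["gene_id"].to_numpy(dtype=object)
    is_ess = np.zeros(n, dtype=bool)
    in_gene = strains["gene_id"].notna().to_numpy()
    if in_gene.any():
        is_ess[in_gene] = truth.essential.reindex(gene_ids[in_gene]).to_numpy(dtype=bool)
    escaper = central & is_ess

    # per-condition log2 effect per strain
    effect: dict[str, np.ndarray] = {}
    for cond in set(design.condition_samples["condition"]):
        e = np.zeros(n)
        sel = central & ~is_ess & in_gene
        if sel.any():
            vals = truth.f_true[cond].reindex(gene_ids[sel]).to_numpy(dtype=float)
            e[sel] = np.nan_to_num(vals, nan=0.0)
        effect[cond] = e

    columns: dict[str, np.ndarray] = {}
    for group, sub in design.frame.groupby("time0_group", sort=True):
        if abundances is not None:
            a0 = np.asarray(abundances, dtype=float)
            if len(a0) != n:
                raise ValidationError("abundances must have one value per strain")
            if (a0 <= 0).any():
                raise ValidationError("abundances must be positive")
        else:
            a0 = rng.lognormal(0.0, abundance_sigma, n)
        a0 = a0.astype(float).copy()
        a0[escaper] *= 0.01
        a0 = a0 / a0.sum()
        for _, row in sub.iterrows():
            if row["role"] == "Time0":
                w = a0
            else:
                w = a0 * np.exp2(effect[row["condition"]])
            if drift_sd > 0:
                w = w * rng.lognormal(0.0, drift_sd * np.sqrt(doublings), n)
            p = w / w.sum()
            if dirichlet_alpha0 is not None and np.isfinite(dirichlet_alpha0):
                p = rng.dirichlet(dirichlet_alpha0 * p)
            columns[row["sample"]] = rng.multinomial(int(depth), p)

    counts = pd.DataFrame(columns, index=pd.Index(barcodes, name="barcode"))
    return counts[design.samples]


# ---------------------------------------------------------------------------
# planting helpers: define the per-condition true effects


def plant_random_effects(
    truth: SimTruth,
    conditions: list[str],
    fraction: float = 0.2,
    low: float = -3.0,
    high: float = 1.0,
    seed: int = 0,
) -> None:
    """Give a random subset of non-essential genes condition-wide effects
    drawn uniformly from [low, high] (same effect in every listed condition)."""
    rng = np.random.default_rng(seed)
    truth.add_conditions(conditions)
    candidates = truth.essential.index[~truth.essential.to_numpy()]
    n_pick = int(round(fraction * len(candidates)))
    picked = rng.choice(candidates, size=n_pick, replace=False)
    effects = rng.uniform(low, high, n_pick)
    for g, e in zip(picked, effects):
        for cond in conditions:
            truth._set(g, cond, e)


def plant_modules(
    truth: SimTruth,
    conditions: list[str],
    n_modules: int = 6,
    genes_per_module: int = 8,
    signal_sd: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> None:
    """Plant co-regulated modules: genes of a module share a per-condition
    signal (N(0, signal_sd^2)) plus independent gene-level noise."""
    rng = np.random.default_rng(seed)
    truth.add_conditions(conditions)
    free = truth.essential.index[~truth.essential.to_numpy() & truth.modules.isna().to_numpy()]
    picked = rng.choice(free, size=n_modules * genes_per_module, replace=False)
    for m in range(n_modules):
        label = f"mod{m:02d}"
        members = picked[m * genes_per_module:(m + 1) * genes_per_module]
        signal = rng.normal(0.0, signal_sd, len(conditions))
        for g in members:
            truth.modules.loc[g] = label
            noise = rng.normal(0.0, noise_sd, len(conditions))
            for cond, s, eps in zip(conditions, signal, noise):
                truth._set(g, cond, s + eps)


def plant_specific_effects(
    truth: SimTruth,
    conditions: list[str],
    n_genes: int = 25,
    magnitude: float = -2.0,
    seed: int = 0,
) -> None:
    """Plant condition-specific effects: each chosen gene gets |f_true| =
    |magnitude| in exactly one condition and 0 elsewhere."""
    rng = np.random.default_rng(seed)
    truth.add_conditions(conditions)
    free = truth.essential.index[~truth.essential.to_numpy() & truth.modules.isna().to_numpy()]
    picked = rng.choice(free, size=n_genes, replace=False)
    for g in picked:
        cond = conditions[int(rng.integers(0, len(conditions)))]
        truth._set(g, cond, magnitude)
        truth.specific.add((g, cond))


def truth_table(truth: SimTruth) -> pd.DataFrame:
    """Long-format ground-truth table (gene_id, essential, condition, f_true)."""
    rows = []
    ess = truth.essential
    if truth.conditions:
        long = truth.f_true.reset_index().melt(
            id_vars="gene_id", var_name="condition", value_name="f_true"
        )
        long["essential"] = long["gene_id"].map(ess).astype(int)
        rows = long[["gene_id", "essential", "condition", "f_true"]]
        return rows.sort_values(["gene_id", "condition"]).reset_index(drop=True)
    out = pd.DataFrame({"gene_id": ess.index, "essential": ess.to_numpy().astype(int)})
    out["condition"] = "NA"
    out["f_true"] = np.nan
    return out
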