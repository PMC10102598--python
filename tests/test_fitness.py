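"""Fitness engine: formula oracles, normalization behaviour, t statistics, QC."""

import numpy as np
import pandas as pd
import pytest

import barseqfit as bf
from barseqfit.config import AnalysisConfig, ValidationError
from barseqfit.fitness import LN2_SQ, compute_qc

from conftest import make_genome, make_pool


def _two_sample_design():
    return bf.ExperimentDesign(pd.DataFrame(
        [("T0", "Time0", "g1", "Time0", 1), ("C", "condition", "g1", "cond", 1)],
        columns=["sample", "role", "time0_group", "condition", "replicate"],
    ))


def _counts(barcodes, t0, cond):
    return pd.DataFrame({"T0": t0, "C": cond},
                        index=pd.Index(barcodes, name="barcode"))


class TestStrainLogRatios:
    def test_equal_counts_equal_depths_give_zero(self):
        genome = make_genome(1)
        pool = make_pool(genome, [("chromosome", 500, 5), ("chromosome", 600, 5)])
        counts = _counts(pool.strains["barcode"], [40, 60], [40, 60])
        sf = bf.strain_log_ratios(counts, _two_sample_design(), pool)
        np.testing.assert_allclose(sf["ratio"], 0.0, atol=1e-12)

    def test_pseudocount_arithmetic(self):
        """ps = 1, equal depths, n_t0 = 3, n_cond = 15 -> ratio = log2(16/4) = 2."""
        genome = make_genome(1)
        pool = make_pool(genome, [("chromosome", 500, 5), ("chromosome", 600, 5)])
        counts = _counts(pool.strains["barcode"], [3, 97], [15, 85])
        sf = bf.strain_log_ratios(counts, _two_sample_design(), pool)
        assert np.isclose(sf["ratio"].iloc[0], 2.0, atol=1e-12)
        # weight follows the stated count-variance formula
        expect_w = LN2_SQ / (1 / 16 + 1 / 4)
        assert np.isclose(sf["weight"].iloc[0], expect_w, rtol=1e-12)

    def test_usability_requires_central_position_and_t0_reads(self):
        genome = make_genome(1)
        begin = genome.genes.loc[0, "begin"]
        pool = make_pool(genome, [
            ("chromosome", begin + 500, 5),   # central, enough T0 reads
            ("chromosome", begin + 500, 5),   # central, too few T0 reads
            ("chromosome", begin + 20, 5),    # within 5' 10% of the gene
            ("chromosome", 50, 5),            # intergenic
        ])
        counts = _counts(pool.strains["barcode"], [50, 2, 50, 50], [10, 10, 10, 10])
        sf = bf.strain_log_ratios(counts, _two_sample_design(), pool)
        assert sf["usable"].tolist() == [True, False, False, False]

    def test_depth_change_leaves_ratios_stable(self):
        """Doubling every condition count changes ratios by < 0.01 for
        strains with >= 50 reads (direct recomputation oracle)."""
        genome = make_genome(1)
        rng = np.random.default_rng(5)
        n = 300
        pool = make_pool(genome, [("chromosome", 50, 5)] * n)
        t0 = rng.poisson(100, n) + 1
        cond = rng.poisson(100, n) + 1
        sf1 = bf.strain_log_ratios(
            _counts(pool.strains["barcode"], t0, cond), _two_sample_design(), pool
        )
        sf2 = bf.strain_log_ratios(
            _counts(pool.strains["barcode"], t0, 2 * cond), _two_sample_design(), pool
        )
        big = (cond >= 50) & (t0 >= 50)
        assert np.max(np.abs(sf1["ratio"][big] - sf2["ratio"][big])) < 0.01

    def test_zero_depth_sample_rejected(self):
        genome = make_genome(1)
        pool = make_pool(genome, [("chromosome", 500, 5)])
        counts = _counts(pool.strains["barcode"], [10], [0])
        with pytest.raises(ValidationError, match="no reads"):
            bf.strain_log_ratios(counts, _two_sample_design(), pool)

    def test_unknown_barcode_rejected(self):
        genome = make_genome(1)
        pool = make_pool(genome, [("chromosome", 500, 5)])
        counts = _counts(["NOTINPOOL" + "A" * 11], [10], [10])
        with pytest.raises(ValidationError, match="absent from the pool"):
            bf.strain_log_ratios(counts, _two_sample_design(), pool)


def _strain_frame(gene, ratios, weights, t0=50):
    n = len(ratios)
    return pd.DataFrame({
        "barcode": [f"B{i}" for i in range(n)],
        "experiment": "C",
        "gene_id": gene,
        "gene_fraction": 0.5,
        "t0_reads": float(t0),
        "ratio": ratios,
        "weight": weights,
        "usable": True,
    })


class TestGeneFitness:
    def test_single_strain_passes_through(self):
        f_raw, stats = bf.gene_fitness_unnormalized(_strain_frame("g", [1.7], [2.0]))
        assert np.isclose(f_raw.loc["g", "C"], 1.7)

    def test_equal_weights_average(self):
        f_raw, _ = bf.gene_fitness_unnormalized(_strain_frame("g", [1.0, 3.0], [2.0, 2.0]))
        assert np.isclose(f_raw.loc["g", "C"], 2.0, atol=1e-12)

    def test_unequal_weights_match_brute_force(self):
        rng = np.random.default_rng(8)
        r = rng.normal(0, 1, 5)
        w = rng.uniform(0.5, 5, 5)
        f_raw, _ = bf.gene_fitness_unnormalized(_strain_frame("g", r, w))
        assert np.isclose(f_raw.loc["g", "C"], np.sum(w * r) / np.sum(w), atol=1e-12)

    def test_insufficient_time0_reads_give_na(self):
        sf = _strain_frame("g", [1.0, 1.0], [1.0, 1.0], t0=10)  # sums to 20 < 30
        f_raw, stats = bf.gene_fitness_unnormalized(sf)
        assert f_raw.empty
        assert not stats["has_fitness"].any()


class TestPositionalNormalize:
    def test_constant_zero_is_fixed_point(self):
        genome, _ = bf.simulate_genome(300, seed=5)
        f = pd.Series(0.0, index=genome.genes["gene_id"])
        out = bf.positional_normalize(f, genome)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-9)

    def test_additive_constant_removed(self):
        genome, _ = bf.simulate_genome(400, seed=6)
        rng = np.random.default_rng(7)
        f = pd.Series(rng.normal(0, 0.2, 400), index=genome.genes["gene_id"])
        a = bf.positional_normalize(f, genome)
        b = bf.positional_normalize(f + 3.7, genome)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_planted_gradient_removed(self):
        """A linear positional trend of 0.5 per Mb is removed: the running
        median of the normalized values is ~0 in every window (recomputed
        here as the oracle)."""
        genome, _ = bf.simulate_genome(1000, plasmid_gene_fraction=0.0, seed=8)
        g = genome.genes_sorted()
        rng = np.random.default_rng(9)
        trend = 0.5e-6 * g["begin"].to_numpy()
        f = pd.Series(trend + rng.normal(0, 0.1, len(g)),
                      index=g["gene_id"])
        out = bf.positional_normalize(f, genome)
        run_med = out.rolling(251, center=True, min_periods=1).median()
        assert np.nanmax(np.abs(run_med.to_numpy())) < 0.05

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            AnalysisConfig(window=250)


class TestTStatistics:
    def _toy(self, ratios, weights):
        sf = _strain_frame("g", ratios, weights)
        f_raw, stats = bf.gene_fitness_unnormalized(sf)
        t = bf.t_statistics(f_raw, stats)
        return float(f_raw.loc["g", "C"]), float(t.loc["g", "C"]), stats

    def test_zero_fitness_gives_zero_t(self):
        _, t, _ = self._toy([0.5, -0.5], [2.0, 2.0])
        assert t == 0.0

    def test_hand_evaluated_formula(self):
        """Three strains with listed ratios/weights: t must equal a direct
        evaluation of f / sqrt(sigma0^2 + max(Vcount, Vspread))."""
        r = np.array([0.8, 1.2, 1.6])
        w = np.array([3.0, 1.0, 2.0])
        f, t, _ = self._toy(r, w)
        fr = np.sum(w * r) / np.sum(w)
        v_count = 1.0 / np.sum(w)
        v_spread = (np.sum(w * (r - fr) ** 2) / np.sum(w)) / 3
        expect = fr / np.sqrt(0.1 ** 2 + max(v_count, v_spread))
        assert np.isclose(f, fr, atol=1e-12)
        assert np.isclose(t, expect, atol=1e-12)

    def test_single_strain_uses_count_variance_alone(self):
        _, t, _ = self._toy([1.0], [4.0])
        assert np.isclose(t, 1.0 / np.sqrt(0.01 + 0.25), atol=1e-12)

    def test_more_counts_increase_significance(self):
        """Scaling every weight up (more reads) shrinks Vcount and, with f
        and strain spread fixed, strictly increases |t| until the sigma0
        floor dominates."""
        r = [0.4, 0.6]
        _, t1, _ = self._toy(r, [2.0, 2.0])
        _, t10, _ = self._toy(r, [20.0, 20.0])
        assert abs(t10) > abs(t1)


class TestAntisymmetry:
    def test_swapping_roles_negates_f_and_t(self):
        """Relabelling the Time0 sample as the condition (and vice versa)
        negates every fitness value and every t score."""
        sim = bf.simulate_genome(300, plasmid_gene_fraction=0.0, seed=21)
        genome, truth = sim
        pool = bf.simulate_pool(genome, truth, 6000, seed=22)
        truth.add_conditions(["c"])
        design_ab = _two_sample_design()
        design_ba = bf.ExperimentDesign(pd.DataFrame(
            [("C", "Time0", "g1", "Time0", 1), ("T0", "condition", "g1", "cond", 1)],
            columns=["sample", "role", "time0_group", "condition", "replicate"],
        ))
        d0 = bf.ExperimentDesign.build(["c"], n_time0=1, replicates=1)
        counts = bf.simulate_counts(pool, truth, d0, depth=300_000, seed=23)
        counts.columns = ["T0", "C"]
        cfg = bf.AnalysisConfig(min_t0_reads=0, min_gene_t0_reads=0)
        res_ab = bf.FitnessModel(counts, design_ab, pool, genome, cfg).fit(compute_quality=False)
        res_ba = bf.FitnessModel(counts, design_ba, pool, genome, cfg).fit(compute_quality=False)
        f1 = res_ab.fitness["C"]
        f2 = res_ba.fitness["T0"]
        np.testing.assert_allclose(f1.dropna().to_numpy(), -f2.dropna().to_numpy(), atol=1e-9)
        np.testing.assert_allclose(
            res_ab.t["C"].dropna().to_numpy(), -res_ba.t["T0"].dropna().to_numpy(), atol=1e-9
        )


class TestFullAnalysis:
    def test_matrix_shape_and_na_mask(self, sim_small_results):
        res = sim_small_results
        assert res.fitness.shape == res.t.shape
        assert res.fitness.isna().equals(res.t.isna())
        assert res.fitness.shape[1] == 2

    def test_mode_and_running_median_invariants(self, sim_small_results):
        res = sim_small_results
        genome = res.model.genome
        main_genes = genome.genes_sorted()
        on_main = main_genes["replicon"] == genome.main_chromosome.id
        for exp in res.experiments:
            vals = res.fitness[exp].reindex(main_genes["gene_id"])[on_main.to_numpy()]
            assert abs(bf.estimate_mode(vals.to_numpy())) <= 0.05
            run_med = vals.rolling(251, center=True, min_periods=1).median()
            assert np.nanmax(np.abs(run_med.to_numpy())) <= 0.05

    def test_time0_null_mostly_within_half_unit(self, sim_small):
        f0, _ = bf.time0_null_fitness(
            sim_small["counts"], sim_small["design"], sim_small["pool"], sim_small["genome"]
        )
        assert f0.shape[1] == 3  # leave-one-out over three Time0 samples
        vals = f0.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert (np.abs(vals) < 0.5).mean() >= 0.99

    def test_qc_pass_flag_follows_thresholds(self, sim_small_results):
        qc = sim_small_results.qc
        expect = (
            (qc["gmed"] >= 50) & (qc["cor12"] >= 0.5) & (qc["mad12"] <= 0.5)
        )
        assert qc["passed"].equals(expect)

    def test_low_depth_experiment_fails_qc(self, sim_small):
        counts = bf.simulate_counts(sim_small["pool"], sim_small["truth"],
                                    sim_small["design"], depth=1_500, seed=99)
        res = bf.FitnessModel(counts, sim_small["design"], sim_small["pool"],
                              sim_small["genome"]).fit()
        assert (res.qc["gmed"] < 50).all()
        assert not res.qc["passed"].any()

    def test_condition_without_time0_group_rejected(self):
        frame = pd.DataFrame(
            [("A", "condition", "gX", "cond", 1)],
            columns=["sample", "role", "time0_group", "condition", "replicate"],
        )
        with pytest.raises(ValidationError, match="'A'"):
            bf.ExperimentDesign(frame)
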