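"""Breeding-cycle simulator: calibration, meiosis, selection dynamics."""

import numpy as np
import pytest

from quadindex.covariance import estimate_P_G
from quadindex.indices import EconomicWeights
from quadindex.response import truncation_select
from quadindex.simulate import (
    GenomeConfig,
    advance_cycle,
    build_genome,
    found_population,
    mvn_generator,
    phenotype,
    run_recurrent_selection,
)


@pytest.fixture(scope="module")
def maize_genome():
    return build_genome(GenomeConfig.simulated_maize(), seed=11)


@pytest.fixture(scope="module")
def founders(maize_genome):
    return found_population(maize_genome, n=2000, seed=12)


def small_config(**kw):
    defaults = dict(
        n_chromosomes=3,
        n_markers=90,
        n_qtl=40,
        qtl_per_trait=(30, 20),
        target_genetic_corr=np.array([[1.0, -0.4], [-0.4, 1.0]]),
        target_h2=(0.5, 0.5),
    )
    defaults.update(kw)
    return GenomeConfig(**defaults)


class TestBuildGenome:
    def test_default_design_builds_and_calibrates(self, maize_genome):
        cfg = maize_genome.config
        assert maize_genome.is_qtl.sum() == cfg.n_qtl
        assert (~maize_genome.is_qtl).sum() == cfg.n_markers
        off = ~np.eye(4, dtype=bool)
        assert np.abs(maize_genome.expected_corr - cfg.target_genetic_corr)[off].max() < 0.05

    def test_positions_nondecreasing_within_chromosomes(self, maize_genome):
        for loci in maize_genome.chromosome_slices():
            assert np.all(np.diff(maize_genome.pos_cM[loci]) >= 0)

    def test_disjoint_qtl_sets_give_near_zero_correlation(self):
        cfg = small_config(
            n_qtl=50, qtl_per_trait=(30, 20), target_genetic_corr=np.eye(2)
        )
        genome = build_genome(cfg, seed=5)
        pop = found_population(genome, n=2000, seed=6)
        c = np.corrcoef(pop.true_genetic_values, rowvar=False)
        assert abs(c[0, 1]) < 0.05

    def test_single_locus_variance_closed_form(self):
        cfg = GenomeConfig(
            n_chromosomes=1, n_markers=10, n_qtl=1, qtl_per_trait=(1,),
            target_genetic_corr=np.eye(1), target_h2=(0.5,),
        )
        genome = build_genome(cfg, seed=7)
        pop = found_population(genome, n=100_000, seed=8)
        effect = genome.qtl_effects[0, 0]
        expected = 2 * 0.5 * 0.5 * effect**2
        assert pop.true_genetic_values.var() == pytest.approx(expected, rel=0.05)

    def test_infeasible_when_fewer_qtl_than_traits(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_genome(
                small_config(qtl_per_trait=(25, 1), n_qtl=25), seed=0
            )


class TestFounders:
    def test_marker_frequencies_near_half(self, founders):
        freqs = founders.marker_codes().mean(axis=0) / 2
        assert abs(freqs.mean() - 0.5) < 0.01
        assert np.abs(freqs - 0.5).max() < 0.06

    def test_target_correlations_recovered(self, founders):
        c = np.corrcoef(founders.true_genetic_values, rowvar=False)
        assert c[0, 1] == pytest.approx(-0.5, abs=0.05)
        target = founders.genome.config.target_genetic_corr
        off = ~np.eye(4, dtype=bool)
        assert np.abs(c - target)[off].max() < 0.06

    def test_zero_effects_give_zero_genetic_values(self, maize_genome):
        import copy

        genome = copy.deepcopy(maize_genome)
        genome.qtl_effects = np.zeros_like(genome.qtl_effects)
        pop = found_population(genome, n=50, seed=1)
        assert np.all(pop.true_genetic_values == 0)


class TestPhenotype:
    def test_full_heritability_reproduces_genetic_values(self, founders):
        panel = phenotype(founders, n_reps=2, h2=np.ones(4), seed=3)
        means = panel.entry_means().to_numpy()
        assert np.allclose(means, founders.true_genetic_values, atol=1e-10)

    def test_round_trip_h2_recovery(self, maize_genome):
        """Plot-basis h2 = 0.5 implies entry-mean-basis h2 = hr/(hr+1-h) = 0.8
        at r = 4, which is what the covariance estimator reports."""
        pop = found_population(maize_genome, n=500, seed=21)
        panel = phenotype(pop, n_reps=4, seed=22)  # default plot-basis h2 = 0.5
        covs = estimate_P_G(panel)
        h, r = 0.5, 4
        assert np.abs(covs.h2 - h * r / (h * r + 1 - h)).max() < 0.05

    def test_error_variance_follows_h2_formula(self, founders):
        s2g = founders.true_genetic_values.var(axis=0)
        p1 = phenotype(founders, n_reps=2, h2=np.full(4, 0.5), seed=4)
        p2 = phenotype(founders, n_reps=2, h2=np.full(4, 1 / 3), seed=4)
        for panel, h2 in ((p1, 0.5), (p2, 1 / 3)):
            resid = panel.data.groupby("genotype")[list(panel.traits)].transform("mean")
            e = panel.data[list(panel.traits)] - resid
            ratio = e.to_numpy().var(axis=0) * 2 / (s2g * (1 - h2) / h2)  # 2 reps: within-var = s2e/2
            assert np.abs(ratio - 1).max() < 0.1

    def test_zero_h2_rejected(self, founders):
        with pytest.raises(ValueError):
            phenotype(founders, h2=np.zeros(4), seed=0)


class TestMeiosis:
    def test_gamete_alleles_copied_from_parents(self, maize_genome):
        pop = found_population(maize_genome, n=20, seed=31)
        child = advance_cycle(pop, np.arange(20), seed=32, n_offspring=10)
        # every child haplotype allele must appear in at least one parent
        # haplotype at that locus (conservation through meiosis)
        parents = pop.haplotypes
        union = parents.max(axis=(0, 1))
        inter = parents.min(axis=(0, 1))
        assert np.all(child.haplotypes <= union)
        assert np.all(child.haplotypes >= inter)

    def test_crossover_count_mean_matches_map_length(self):
        cfg = small_config()
        genome = build_genome(cfg, seed=41)
        rng = np.random.default_rng(0)
        from quadindex.simulate import _gamete

        hap = np.zeros((2, genome.n_loci), dtype=np.uint8)
        hap[1] = 1  # strand identity visible as allele value
        loci = genome.chromosome_slices()
        switches = 0
        n_gam = 4000
        for _ in range(n_gam):
            g = _gamete(hap, genome, loci, rng)
            for lo in loci:
                switches += np.count_nonzero(np.diff(g[lo]))
        per_chrom = switches / (n_gam * len(loci))
        assert per_chrom == pytest.approx(1.0, abs=0.1)  # 100 cM -> 1 crossover

    def test_two_parents_required(self, maize_genome):
        pop = found_population(maize_genome, n=10, seed=51)
        with pytest.raises(ValueError):
            advance_cycle(pop, np.array([3]), seed=0)

    def test_seeded_determinism(self, maize_genome):
        pop = found_population(maize_genome, n=30, seed=61)
        a = advance_cycle(pop, np.arange(10), seed=62)
        b = advance_cycle(pop, np.arange(10), seed=62)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.true_genetic_values, b.true_genetic_values)


class TestSelectionDynamics:
    def test_directional_selection_raises_trait_mean(self):
        cfg = small_config()
        genome = build_genome(cfg, seed=71)
        wins = 0
        for s in range(10):
            pop = found_population(genome, n=200, seed=100 + s)
            start = pop.true_genetic_values[:, 0].mean()
            for c in range(3):
                chosen = truncation_select(pop.true_genetic_values[:, 0], 0.2)
                pop = advance_cycle(pop, chosen, seed=200 + 10 * s + c)
            wins += pop.true_genetic_values[:, 0].mean() > start
        assert wins >= 8

    def test_neutral_drift_is_small(self):
        cfg = small_config()
        genome = build_genome(cfg, seed=81)
        deltas = []
        for s in range(8):
            pop = found_population(genome, n=300, seed=300 + s)
            start = pop.true_genetic_values[:, 0].mean()
            nxt = advance_cycle(pop, np.arange(300), seed=400 + s)
            deltas.append(nxt.true_genetic_values[:, 0].mean() - start)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 0.05


class TestRecurrentSelection:
    def test_qgsi_with_zero_W_equals_lgsi_line_for_line(self):
        cfg = small_config()
        weights = EconomicWeights(w=[1.0, -1.0])
        a = run_recurrent_selection(cfg, "QGSI", weights, cycles=3, n=120, seed=5)
        b = run_recurrent_selection(cfg, "LGSI", weights, cycles=3, n=120, seed=5)
        for ra, rb in zip(a, b):
            assert ra.R == rb.R
            assert np.allclose(ra.gains, rb.gains)

    def test_ten_cycle_run_emits_one_row_per_cycle(self):
        cfg = small_config()
        weights = EconomicWeights.rank1([1.0, -1.0])
        rows = run_recurrent_selection(cfg, "QGSI", weights, cycles=10, n=120, seed=9)
        assert [r.cycle for r in rows] == list(range(1, 11))
        assert all(r.index_kind == "QGSI" for r in rows)

    def test_phenotypic_path_runs(self):
        cfg = small_config()
        weights = EconomicWeights(w=[1.0, -1.0])
        rows = run_recurrent_selection(cfg, "LPSI", weights, cycles=2, n=120, seed=13)
        assert len(rows) == 2 and np.isfinite([r.R for r in rows]).all()

    def test_response_declines_as_variance_erodes(self):
        """Selection depletes genetic variance: later-cycle response is below
        the first cycle's in most seeds."""
        cfg = small_config()
        weights = EconomicWeights(w=[1.0, -1.0])
        wins = 0
        for s in range(6):
            rows = run_recurrent_selection(cfg, "LGSI", weights, cycles=6, n=150, seed=500 + s)
            early = np.mean([rows[0].R, rows[1].R])
            late = np.mean([rows[-2].R, rows[-1].R])
            wins += late < early
        assert wins >= 4


class TestMVNGenerator:
    def test_sample_covariance_matches_P(self):
        G = np.array([[1.0, 0.4], [0.4, 1.0]])
        P = G + np.eye(2)
        g, y = mvn_generator(G, P, n=200_000, seed=3)
        assert np.abs(np.cov(y, rowvar=False) - P).max() < 0.03

    def test_G_equal_P_gives_y_equal_g(self):
        G = np.eye(2)
        g, y = mvn_generator(G, G, n=100, seed=4)
        assert np.allclose(g, y)

    def test_per_trait_correlation_closed_form(self):
        G = np.diag([1.0, 2.0])
        P = np.diag([2.0, 2.5])
        g, y = mvn_generator(G, P, n=200_000, seed=5)
        for t in range(2):
            expected = np.sqrt(G[t, t] / P[t, t])
            assert np.corrcoef(g[:, t], y[:, t])[0, 1] == pytest.approx(expected, abs=0.01)

    def test_invalid_residual_covariance_raises(self):
        with pytest.raises(ValueError, match="semi-definite"):
            mvn_generator(np.eye(2) * 2, np.eye(2), n=10, seed=0)
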