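"""Meiosis, phenotype, pooling and pooled-sequencing simulator."""

import numpy as np
import pytest
from scipy.stats import binom

from bsamap.cross import (
    INFERIOR,
    SUPERIOR,
    CrossConfig,
    PhenotypeModel,
    QtlEffect,
    apply_downgrade,
    assign_phenotype,
    genetic_value,
    pool_allele_frequencies,
    select_and_pool,
    sequence_pool,
    simulate_cross,
    simulate_meiosis,
    simulate_segregants,
)
from bsamap.genome import Chromosome, ConfigurationError, GenomeLayout


def layout_1m(morgans=1.0, markers=(100, 500_000, 999_999)):
    chrom = Chromosome("chr1", 1_000_000, morgans)
    return GenomeLayout([chrom], markers={"chr1": np.array(markers)})


class TestMeiosis:
    def test_zero_genetic_length_gives_single_parental_block(self, rng):
        layout = layout_1m(morgans=0.0)
        for _ in range(20):
            g = simulate_meiosis(layout, rng)
            origins = g.origin_at("chr1", layout.markers["chr1"])
            assert len(set(origins.tolist())) == 1

    def test_mean_crossover_count_matches_genetic_length(self, rng):
        layout = layout_1m(morgans=1.0)
        counts = [
            len(simulate_meiosis(layout, rng).blocks["chr1"][0]) for _ in range(10_000)
        ]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 1.0) < 3 * se
        assert all(c >= 0 for c in counts)

    def test_marginal_segregation_is_one_to_one(self, rng):
        layout = layout_1m()
        genomes = simulate_segregants(layout, 2_000, rng)
        freq = np.mean([g.origin_at("chr1", 500_000)[0] for g in genomes])
        # binomial sampling error at n=2000: 3 sigma ~ 0.034
        assert abs(freq - 0.5) < 0.04

    def test_unselected_frequencies_within_exact_binomial_interval(self, rng):
        """Marker-wise superior-allele frequency over N unselected segregants
        is Binomial(N, 1/2); >= 98% of markers fall in the exact 99% CI."""
        n, n_markers = 200, 50
        positions = np.linspace(1, 999_999, n_markers).astype(int)
        layout = layout_1m(markers=tuple(positions))
        genomes = simulate_segregants(layout, n, rng)
        counts = sum(g.origin_at("chr1", positions) for g in genomes)
        lo, hi = binom.ppf(0.005, n, 0.5), binom.ppf(0.995, n, 0.5)
        inside = np.mean((counts >= lo) & (counts <= hi))
        assert inside >= 0.98


class TestPhenotype:
    def model(self, mask=False):
        qtls = [
            QtlEffect("a", "chr1", 100, 2.0),
            QtlEffect("b", "chr1", 500_000, 1.0, epistatic_mask="a" if mask else None),
        ]
        return PhenotypeModel(qtls=qtls, baseline=1.0, noise_sd=0.0)

    def genome(self, origins):
        from bsamap.cross import SegregantGenome

        # piecewise genome: breakpoint between the two loci when they differ
        first = origins[0]
        bps = np.array([]) if origins[0] == origins[1] else np.array([250_000.0])
        return SegregantGenome(blocks={"chr1": (bps, first)})

    def test_additive_sum_all_superior(self, rng):
        g = self.genome((SUPERIOR, SUPERIOR))
        assert assign_phenotype(g, self.model(), rng) == pytest.approx(1.0 + 2.0 + 1.0)

    def test_masked_effect_contributes_nothing_when_masker_superior(self, rng):
        model = self.model(mask=True)
        with_b = assign_phenotype(self.genome((SUPERIOR, SUPERIOR)), model, rng)
        without_b = assign_phenotype(self.genome((SUPERIOR, INFERIOR)), model, rng)
        assert with_b - without_b == pytest.approx(0.0)

    def test_masked_effect_active_when_masker_inferior(self, rng):
        model = self.model(mask=True)
        with_b = assign_phenotype(self.genome((INFERIOR, SUPERIOR)), model, rng)
        without_b = assign_phenotype(self.genome((INFERIOR, INFERIOR)), model, rng)
        assert with_b - without_b == pytest.approx(1.0)

    def test_negative_effect_rewards_inferior_allele(self, rng):
        model = PhenotypeModel(
            qtls=[QtlEffect("a", "chr1", 100, -2.0)], noise_sd=0.0
        )
        inf = assign_phenotype(self.genome((INFERIOR, INFERIOR)), model, rng)
        sup = assign_phenotype(self.genome((SUPERIOR, SUPERIOR)), model, rng)
        assert inf - sup == pytest.approx(2.0)

    def test_cyclic_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            PhenotypeModel(
                qtls=[
                    QtlEffect("a", "chr1", 1, 1.0, epistatic_mask="b"),
                    QtlEffect("b", "chr1", 2, 1.0, epistatic_mask="a"),
                ]
            )

    def test_locus_off_map_raises(self, rng):
        model = PhenotypeModel(qtls=[QtlEffect("a", "chrX", 1, 1.0)], noise_sd=0.0)
        with pytest.raises(ConfigurationError):
            assign_phenotype(self.genome((0, 0)), model, rng)


class TestSelection:
    def test_pool_size_equal_to_n_selects_all(self, rng):
        cfg = CrossConfig(n_segregants=10, pool_size=10)
        selected, _ = select_and_pool(np.arange(10.0), cfg, rng)
        assert sorted(selected.tolist()) == list(range(10))

    def test_top_k_order_statistic(self, rng):
        cfg = CrossConfig(n_segregants=100, pool_size=58)
        phen = np.arange(1.0, 101.0)
        selected, _ = select_and_pool(phen, cfg, rng)
        assert phen[selected].min() == 43

    def test_threshold_shortfall_raises(self, rng):
        cfg = CrossConfig(
            n_segregants=100, pool_size=58, selection="phenotype-threshold",
            phenotype_threshold=90.0,
        )
        with pytest.raises(ConfigurationError, match="11"):
            select_and_pool(np.arange(1.0, 101.0), cfg, rng)

    def test_strong_selection_drives_qtl_allele_to_fixation(self, rng):
        layout = layout_1m(morgans=1.0)
        model = PhenotypeModel(
            qtls=[QtlEffect("a", "chr1", 500_000, 100.0)], noise_sd=1.0
        )
        genomes = simulate_segregants(layout, 400, rng)
        phen = np.array([assign_phenotype(g, model, rng) for g in genomes])
        cfg = CrossConfig(n_segregants=400, pool_size=58)
        selected, _ = select_and_pool(phen, cfg, rng)
        freq = np.mean([genomes[i].origin_at("chr1", 500_000)[0] for i in selected])
        assert freq == 1.0


class TestSequencing:
    def test_no_error_all_superior_gives_fraction_one(self, rng):
        layout = layout_1m(morgans=0.0)
        cfg = CrossConfig(
            n_segregants=5, pool_size=5, mean_coverage=100, sequencing_error=0.0
        )
        genomes = []
        while len(genomes) < 5:
            g = simulate_meiosis(layout, rng)
            if g.origin_at("chr1", 100)[0] == SUPERIOR:
                genomes.append(g)
        counts = sequence_pool(genomes, layout, cfg, rng)
        assert (counts["variant_count"] == counts["total_count"]).all()

    def test_sequencing_error_flips_expected_fraction(self, rng):
        layout = layout_1m(morgans=0.0, markers=tuple(range(1000, 500_000, 1000)))
        e = 0.1
        cfg = CrossConfig(
            n_segregants=5, pool_size=5, mean_coverage=200, sequencing_error=e
        )
        genomes = []
        while len(genomes) < 5:
            g = simulate_meiosis(layout, rng)
            if g.origin_at("chr1", 1000)[0] == SUPERIOR:
                genomes.append(g)
        counts = sequence_pool(genomes, layout, cfg, rng)
        frac = counts["variant_count"].sum() / counts["total_count"].sum()
        assert frac == pytest.approx(1 - e, abs=0.01)

    def test_empty_pool_raises(self, rng):
        with pytest.raises(ConfigurationError):
            pool_allele_frequencies([], layout_1m())


class TestDowngrade:
    def test_unknown_id_raises(self):
        model = PhenotypeModel(qtls=[QtlEffect("a", "chr1", 1, 1.0)])
        with pytest.raises(ConfigurationError):
            apply_downgrade(model, ["nope"])

    def test_downgrade_halves_mean_genetic_value(self, rng):
        layout = layout_1m(morgans=1.0)
        model = PhenotypeModel(
            qtls=[QtlEffect("a", "chr1", 500_000, 2.0)], noise_sd=0.0
        )
        genomes = simulate_segregants(layout, 2_000, rng)
        before = np.mean([genetic_value(g, model) for g in genomes])
        after = np.mean(
            [genetic_value(g, apply_downgrade(model, ["a"])) for g in genomes]
        )
        # random segregants carry the beneficial allele half the time
        assert before - after == pytest.approx(0.5 * 2.0, abs=0.1)

    def test_downgrading_masker_releases_masked_qtl(self, rng):
        model = PhenotypeModel(
            qtls=[
                QtlEffect("a", "chr1", 100, -2.0),
                QtlEffect("b", "chr1", 900_000, 1.0, epistatic_mask="a"),
            ],
            noise_sd=0.0,
        )
        from bsamap.cross import SegregantGenome

        g_ib = SegregantGenome(blocks={"chr1": (np.array([500_000.0]), INFERIOR)})
        g_ii = SegregantGenome(blocks={"chr1": (np.array([]), INFERIOR)})
        # masker beneficial (inferior) allele present: b masked
        assert genetic_value(g_ib, model) == genetic_value(g_ii, model)
        dg = apply_downgrade(model, ["a"])
        # downgraded masker: b's effect visible again
        assert genetic_value(g_ib, dg) - genetic_value(g_ii, dg) == pytest.approx(1.0)


class TestDeterminism:
    def test_same_seed_reproduces_cross_exactly(self, one_chrom_layout):
        model = PhenotypeModel(
            qtls=[QtlEffect("a", "chr1", 500_000, 2.0)], noise_sd=1.0
        )
        cfg = CrossConfig(n_segregants=60, pool_size=20, seed=99)
        r1 = simulate_cross(one_chrom_layout, model, cfg)
        r2 = simulate_cross(one_chrom_layout, model, cfg)
        assert np.array_equal(r1.phenotypes, r2.phenotypes)
        assert r1.selected_counts.equals(r2.selected_counts)
        assert r1.genotypes.equals(r2.genotypes)
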