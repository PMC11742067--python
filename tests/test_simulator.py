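"""Generative-model checks for the read-level methylome simulator."""

import numpy as np
import pytest

from cpgformer.simulate import (
    MethylomeSimulator,
    SimConfig,
    mix_pseudobulk,
    sample_region_level,
    sem_of_region,
)
from cpgformer.simulate import SimRegion, _scenario_probs
from cpgformer.types import MethylRead


def _region(d, n_cpgs=20, scenario="region_level", start=1000, spacing=10):
    """Stand-alone region used for pure probability-table checks."""
    pos = np.arange(start, start + n_cpgs * spacing, spacing)
    return SimRegion(region_index=0, chrom="chrS", start=start,
                     end=start + n_cpgs * spacing + 2, cpg_positions=pos,
                     d=d, probs=_scenario_probs(d, n_cpgs, scenario))


def _with_level(sim_region, d, scenario="region_level"):
    """The simulator's own region (real genome CpG layout) with a chosen
    tumour mean methylation level."""
    return SimRegion(
        region_index=sim_region.region_index, chrom=sim_region.chrom,
        start=sim_region.start, end=sim_region.end,
        cpg_positions=sim_region.cpg_positions, d=d,
        probs=_scenario_probs(d, sim_region.n_cpgs, scenario))


class TestBetaSampling:
    @pytest.mark.parametrize("alpha", [0.1, 1.0, 2.0, 3.0])
    def test_moments_match_beta_distribution(self, alpha, rng):
        n = 50_000
        d = sample_region_level(alpha, 5.0, rng, size=n)
        mean = alpha / (alpha + 5.0)
        var = alpha * 5.0 / ((alpha + 5.0) ** 2 * (alpha + 6.0))
        se_mean = np.sqrt(var / n)
        assert abs(d.mean() - mean) < 3 * se_mean
        # SE of the sample variance via the fourth central moment
        m4 = np.mean((d - d.mean()) ** 4)
        se_var = np.sqrt(max(m4 - var**2, 0.0) / n)
        assert abs(d.var() - var) < 4 * se_var

    def test_symmetric_case(self, rng):
        d = sample_region_level(5.0, 5.0, rng, size=50_000)
        assert abs(d.mean() - 0.5) < 3 * np.sqrt(d.var() / 50_000)

    def test_rejects_nonpositive_shape(self, rng):
        with pytest.raises(ValueError):
            sample_region_level(0.0, 5.0, rng)

    def test_seeded_reproducibility(self):
        a = sample_region_level(1.0, 5.0, np.random.default_rng(7), size=100)
        b = sample_region_level(1.0, 5.0, np.random.default_rng(7), size=100)
        np.testing.assert_array_equal(a, b)


class TestReadSimulation:
    def _simulator(self, **kw):
        kw.setdefault("n_regions", 4)
        kw.setdefault("seed", 3)
        return MethylomeSimulator(SimConfig(**kw))

    def test_degenerate_tumour_fully_methylated(self, rng):
        sim = self._simulator()
        region = _with_level(sim.sim_regions[0], 1.0)
        reads = sim.reads_for_region(region, "Tumour", coverage=20, rng=rng)
        for r in reads:
            assert all(m for _, m in r.cpg_calls)

    def test_degenerate_normal_fully_unmethylated(self, rng):
        sim = self._simulator()
        region = _with_level(sim.sim_regions[0], 1.0)
        reads = sim.reads_for_region(region, "Normal", coverage=20, rng=rng)
        for r in reads:
            assert not any(m for _, m in r.cpg_calls)

    def test_binomial_mean_recovery(self, rng):
        sim = self._simulator(read_length=150)
        region = _with_level(sim.sim_regions[0], 0.8)
        reads = sim.reads_for_region(region, "Tumour", coverage=200, rng=rng)
        states = np.concatenate([[m for _, m in r.cpg_calls] for r in reads])
        se = np.sqrt(0.8 * 0.2 / len(states))
        assert abs(states.mean() - 0.8) < 3 * se

    def test_full_determinism_under_seed(self):
        cfg = SimConfig(alpha=1.0, n_regions=3, coverage=4, seed=42)
        a = MethylomeSimulator(cfg).simulate()
        b = MethylomeSimulator(cfg).simulate()
        assert a.keys() == b.keys()
        for ct in a:
            for ra, rb in zip(a[ct], b[ct]):
                assert ra.start == rb.start
                assert ra.sequence == rb.sequence
                assert list(ra.cpg_calls) == list(rb.cpg_calls)

    def test_genome_cpgs_are_exactly_the_planted_ones(self, small_sim):
        genome = small_sim.genome["chrS"]
        found = {i for i in range(len(genome) - 1)
                 if genome[i : i + 2] == "CG"}
        assert found == set(small_sim._all_cpgs.tolist())

    def test_complexity_ordering_of_tumour_normal_gap(self):
        """E|p_T - p_N| = E|1 - 2 d| shrinks as alpha grows at beta = 5."""
        rng = np.random.default_rng(5)
        gaps = []
        for alpha in (0.1, 1.0, 2.0, 3.0):
            d = sample_region_level(alpha, 5.0, rng, size=50_000)
            gaps.append(np.abs(1.0 - 2.0 * d).mean())
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestCpgSpecificScenario:
    def test_phases_alternate_and_region_means_match(self, rng):
        d = 0.05
        region = _region(d, n_cpgs=20, scenario="cpg_specific")
        t, n = region.probs["Tumour"], region.probs["Normal"]
        # 1-based odd CpGs carry d on tumour reads
        assert np.allclose(t[::2], d) and np.allclose(t[1::2], 1 - d)
        np.testing.assert_allclose(t + n, 1.0)
        # balanced odd/even counts -> identical expected region means
        assert abs(t.mean() - n.mean()) < 1e-12
        assert np.abs(t - n).mean() == pytest.approx(0.9)

    def test_half_level_is_indistinguishable_noise(self):
        region = _region(0.5, scenario="cpg_specific")
        assert np.allclose(region.probs["Tumour"], 0.5)
        assert np.allclose(region.probs["Normal"], 0.5)

    def test_odd_cpg_degenerate_tumour(self, rng):
        sim = MethylomeSimulator(SimConfig(n_regions=2, seed=0,
                                           scenario="cpg_specific"))
        region = _with_level(sim.sim_regions[0], 1.0, "cpg_specific")
        reads = sim.reads_for_region(region, "Tumour", coverage=30, rng=rng)
        odd_pos = set(region.cpg_positions[::2].tolist())
        for r in reads:
            for off, m in r.cpg_calls:
                if r.start + off in odd_pos:
                    assert m

    def test_empirical_region_means_coincide_but_cpgs_differ(self, rng):
        cfg = SimConfig(alpha=0.1, n_regions=2, coverage=300, seed=9,
                        scenario="cpg_specific", read_length=490)
        sim = MethylomeSimulator(cfg)
        region = sim.sim_regions[0]
        t_reads = sim.reads_for_region(region, "Tumour", rng=rng)
        n_reads = sim.reads_for_region(region, "Normal", rng=rng)
        t_mean = np.mean([r.mean_methylation() for r in t_reads])
        n_mean = np.mean([r.mean_methylation() for r in n_reads])
        assert abs(t_mean - n_mean) < 3 * np.sqrt(2 * 0.25 / 300)
        # yet per-CpG means are far apart when d is extreme
        gap = np.abs(region.probs["Tumour"] - region.probs["Normal"]).mean()
        assert gap > 0.5


class TestPseudobulk:
    def test_exact_fraction_counts(self, small_pools, rng):
        mix, truth = mix_pseudobulk(small_pools["Tumour"],
                                    small_pools["Normal"], 0.2, 40, rng)
        labels = [r.cell_label for r in mix]
        assert labels.count("Tumour") == 8 == truth["n_tumour"]
        assert labels.count("Normal") == 32

    def test_zero_fraction_all_normal(self, small_pools, rng):
        mix, truth = mix_pseudobulk(small_pools["Tumour"],
                                    small_pools["Normal"], 0.0, 30, rng)
        assert all(r.cell_label == "Normal" for r in mix)
        assert truth["tumour_fraction"] == 0.0

    def test_ctdna_regime_counts(self, rng):
        tumour = [MethylRead(f"t{i}", "c", 0, "TACGT", [(2, True)],
                             cell_label="Tumour") for i in range(400)]
        normal = [MethylRead(f"n{i}", "c", 0, "TACGT", [(2, False)],
                             cell_label="Normal") for i in range(10_000)]
        mix, truth = mix_pseudobulk(tumour, normal, 0.03, 10_000, rng,
                                    replace=True)
        assert truth["n_tumour"] == 300

    def test_overdraw_without_replacement_errors(self, small_pools, rng):
        with pytest.raises(ValueError, match="exceed pool"):
            mix_pseudobulk(small_pools["Tumour"][:3], small_pools["Normal"],
                           1.0, 10, rng)


class TestSem:
    def _read(self, states):
        calls = [(2 + 3 * i, bool(s)) for i, s in enumerate(states)]
        seq = "TA" + "CGA" * len(states) + "TT"
        return MethylRead("r", "c", 0, seq, calls)

    def test_identical_reads_zero_sem(self):
        reads = [self._read([1, 1, 1]) for _ in range(5)]
        assert sem_of_region(reads) == 0.0

    def test_two_extreme_reads(self):
        reads = [self._read([0, 0]), self._read([1, 1])]
        assert sem_of_region(reads) == pytest.approx(0.5)

    def test_sem_shrinks_with_coverage(self, small_sim, rng):
        region = small_sim.sim_regions[0]
        low = small_sim.reads_for_region(region, "Tumour", 10, rng)
        high = small_sim.reads_for_region(region, "Tumour", 1000, rng)
        assert sem_of_region(high) < sem_of_region(low)

    def test_requires_two_reads(self):
        with pytest.raises(ValueError):
            sem_of_region([self._read([1])])
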