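"""Generative model: occupancy geometry, expected matrices, pair sampling,
time courses and ChIP tracks."""

import numpy as np
import pytest
from scipy import stats as sps

from armalign import presets, simulate
from armalign.chipseq import enrichment_ratio
from armalign.genome import GenomeSpec
from armalign.hic import VALID, bin_pairs
from armalign.simulate import (Barrier, SimConfig, barriers_from_genes,
                               expected_matrix, occupancy, occupancy_at,
                               sample_pairs, simulate_chip, simulate_timecourse,
                               synthetic_fragment_map)


@pytest.fixture(scope="module")
def wt_cfg(genome):
    return presets.scenario("wt", n_pairs=50_000, seed=6)


class TestOccupancy:
    def test_maximal_at_loading_site(self, wt_cfg):
        O = occupancy_at(wt_cfg, np.array([0.0]), np.array([0.0]))
        assert O[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_full_unload_barrier_zeroes_beyond(self, genome):
        cfg = presets.scenario(
            "wt", barriers=(Barrier("left", 100.0, 1.0, "unload"),))
        d = np.arange(0, 500, 10.0)
        O = occupancy_at(cfg, d, d)
        assert np.all(O[d > 100, :] == 0)
        assert O[(d > 30) & (d < 100), :].max() > 0

    def test_stall_barrier_pins_left_arm_while_right_continues(self, genome):
        cfg = presets.scenario("flip25")  # stall at 70 kb, beta 0.9, lam 420
        surf = occupancy(cfg, grid_kb=5.0)
        # right arm keeps substantial occupancy far beyond the barrier
        right_far = np.interp(300, surf.dR_kb, surf.marginal_right)
        left_far = np.interp(300, surf.dL_kb, surf.marginal_left)
        assert right_far > 5 * left_far
        # the pinned ridge sits at the barrier offset on the left arm
        col = surf.values[:, np.searchsorted(surf.dR_kb, 300)]
        assert abs(surf.dL_kb[np.argmax(col)] - 70) <= 15

    def test_finite_time_fronts_truncate(self, genome):
        cfg = presets.scenario("timecourse", t_min=10.0)
        d = np.arange(0, 800, 10.0)
        O = occupancy_at(cfg, d, d)
        # beyond v*t (190 kb left, 160 kb right) occupancy collapses
        assert O[d > 220, :].max() < 1e-3
        assert O[:, d > 220].max() < 1e-3
        assert O[(d > 50) & (d < 150), :].max() > 0.3

    def test_invariant_zero_beyond_fronts_surface(self, genome):
        cfg = presets.scenario("timecourse", t_min=5.0)
        surf = occupancy(cfg, grid_kb=5.0)
        assert np.all(surf.values >= 0)
        near = surf.dL_kb > cfg.v_left * 5 + 30   # logistic edge tail
        far = surf.dL_kb > cfg.v_left * 5 + 60
        assert surf.values[near, :].max() < 1e-3
        assert surf.values[far, :].max() < 1e-6


class TestExpectedMatrix:
    def test_probability_normalisation(self, wt_cfg):
        em = expected_matrix(wt_cfg)
        upper = (em.values.sum() + np.trace(em.values)) / 2
        assert upper == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(em.values, em.values.T)

    def test_no_tether_means_flat_secondary_diagonal(self, genome):
        cfg = presets.scenario("dsmc")
        em = expected_matrix(cfg)
        n = em.n_bins
        b = em.bin_of(genome.ori_bp)
        k = np.arange(10, n // 2 - 10)
        diag = em.values[(b - k) % n, (b + k) % n]
        decay = (np.minimum(2 * k * 10.0, genome.length_bp / 1000 - 2 * k * 10.0)
                 + cfg.s0_kb) ** (-cfg.alpha) + cfg.epsilon
        r = np.corrcoef(diag, decay)[0, 1]
        assert r > 0.999  # pure distance decay, no inter-arm band

    def test_arm_reflection_symmetry_for_symmetric_config(self):
        g = GenomeSpec(name="sym", length_bp=1_000_000, ori_bp=0, parS_bp=0)
        cfg = SimConfig(genome=g, v_left=17.0, v_right=17.0, bin_size=10_000)
        em = expected_matrix(cfg)
        n = em.n_bins
        idx = np.arange(n)
        refl = n - 1 - idx  # mirror about the ori/parS bin boundary
        assert np.allclose(em.values, em.values[np.ix_(refl, refl)], rtol=1e-9)


class TestSamplePairs:
    def test_exact_counts_and_label_fractions(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=1000, seed=1)
        pairs = sample_pairs(cfg, frag)
        assert len(pairs) == 1000
        counts = pairs["label"].value_counts()
        assert counts["valid"] == 700
        assert counts["self_ligation"] == 150
        assert counts["non_ligation"] == 150

    def test_same_seed_byte_identical(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=5000, seed=77)
        a = sample_pairs(cfg, frag).to_csv(index=False)
        b = sample_pairs(cfg, frag).to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self, genome, frag):
        a = sample_pairs(presets.scenario("wt", n_pairs=5000, seed=1), frag)
        b = sample_pairs(presets.scenario("wt", n_pairs=5000, seed=2), frag)
        assert not a.equals(b)

    def test_binned_valid_pairs_match_expected_matrix(self, genome, frag):
        """Goodness of fit of the sampled contact map against the generative
        probabilities (chi-square over well-populated cells)."""
        cfg = presets.scenario("wt", n_pairs=1_000_000, seed=13)
        pairs = sample_pairs(cfg, frag)
        m = bin_pairs(pairs, genome)
        n_valid = int((pairs["label"] == VALID).sum())
        em = expected_matrix(cfg)
        iu, ju = np.triu_indices(m.n_bins)
        obs = m.values[iu, ju]
        expect = em.values[iu, ju] * n_valid
        # cells whose whole genomic span lies inside one restriction fragment
        # cannot host a valid (different-fragment) pair; the smooth expected
        # matrix deliberately ignores fragment geometry, so condition the
        # goodness-of-fit on feasible cells
        from armalign.hic import assign_fragments
        bs = m.bin_size
        L = genome.length_bp
        f_lo = assign_fragments(iu * bs, frag)
        f_hi = assign_fragments(np.minimum((ju + 1) * bs, L) - 1, frag)
        keep = (expect >= 10) & (f_lo != f_hi)
        # renormalise over the kept cells for a valid chi-square
        obs_k, exp_k = obs[keep], expect[keep]
        exp_k = exp_k * obs_k.sum() / exp_k.sum()
        stat, p = sps.chisquare(obs_k, exp_k)
        assert p > 0.01


class TestTimecourse:
    def test_t0_has_no_band_and_extent_grows(self, genome, frag):
        from armalign.armstats import alignment_extent, arm_marginal
        from armalign.hic import iterative_correction, log_map
        cfg = presets.scenario("timecourse", n_pairs=100_000, seed=8)
        data = simulate_timecourse(cfg, [0, 15, 30], frag)
        extents = []
        for t, pairs in data:
            lg = log_map(iterative_correction(bin_pairs(pairs, genome)))
            est = alignment_extent(arm_marginal(lg, genome, arm="left"))
            extents.append(est.extent_kb)
        assert extents[0] < 150  # only the intra-arm decay shoulder at t=0
        assert extents[0] < extents[1] < extents[2]

    def test_front_ground_truth_grows_linearly(self, genome):
        cfg = presets.scenario("timecourse")
        for t in (5.0, 10.0, 20.0):
            cfg_t = SimConfig(**{**cfg.__dict__, "t_min": t})
            d = np.arange(0, 900, 5.0)
            O = occupancy_at(cfg_t, d, d)
            left_front = d[np.nonzero(O.max(axis=1) > 0.5 * O.max())[0][-1]]
            assert left_front == pytest.approx(min(cfg.v_left * t, cfg.lam_kb), abs=25)

    def test_negative_time_errors(self, genome, frag):
        cfg = presets.scenario("timecourse", n_pairs=100)
        with pytest.raises(ValueError):
            simulate_timecourse(cfg, [-1.0], frag)


class TestSimulateChip:
    def test_ratio_peaks_at_parS(self, genome):
        cfg = presets.scenario("wt", seed=5)
        tagged, untagged = simulate_chip(cfg)
        ratio = enrichment_ratio(tagged, untagged, pseudocount=0.5)
        peak_bp = np.argmax(ratio.values) * ratio.bin_size
        assert abs(peak_bp - genome.parS_bp) < 30_000 or \
            abs(peak_bp - genome.parS_bp) > genome.length_bp - 30_000

    def test_stall_scenario_adds_ratio_peak_at_barrier(self, genome):
        cfg = presets.scenario("flip25", seed=5)  # stall at 70 kb on left arm
        tagged, untagged = simulate_chip(cfg)
        ratio = enrichment_ratio(tagged, untagged, pseudocount=0.5)
        barrier_bp = (genome.parS_bp - 70_000) % genome.length_bp
        b = barrier_bp // ratio.bin_size
        local = ratio.values[b - 10: b + 10].max()
        # distal left-arm baseline, beyond the stalled front
        distal_bp = (genome.parS_bp - 600_000) % genome.length_bp
        d = distal_bp // ratio.bin_size
        distal = np.median(ratio.values[d - 50: d + 50])
        assert local > 1.5 * distal

    def test_deterministic_per_seed(self, genome):
        cfg = presets.scenario("wt", seed=9)
        a = simulate_chip(cfg)
        b = simulate_chip(cfg)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_dsmc_has_no_parS_occupancy_signal(self, genome):
        tagged, untagged = simulate_chip(presets.scenario("dsmc", seed=5))
        ratio = enrichment_ratio(tagged, untagged, pseudocount=0.5)
        # loading peak remains (ParB-bound parS), but no arm-wide decay:
        # compare mid-arm (150 kb) level against distal background
        mid = np.median(ratio.values[(genome.parS_bp - 160_000) // 1000:
                                     (genome.parS_bp - 140_000) // 1000])
        far = np.median(ratio.values[(genome.parS_bp - 900_000) // 1000:
                                     (genome.parS_bp - 800_000) // 1000])
        assert abs(mid - far) < 0.2


class TestBarriersFromGenes:
    def test_head_on_highly_expressed_become_barriers(self, genome):
        from armalign.chipseq import make_gene_table
        genes = make_gene_table([
            ("ho", 3_900_000, 3_905_000, "+", 100.0),   # left arm, head-on
            ("co", 3_800_000, 3_805_000, "-", 100.0),   # left arm, co-directional
            ("weak", 3_700_000, 3_702_000, "+", 1.0),   # head-on but weak
        ])
        bars = barriers_from_genes(genes, genome, min_weight=50.0)
        assert len(bars) == 1
        assert bars[0].arm == "left"
        assert bars[0].offset_kb == pytest.approx(132.4, abs=1.0)


class TestConfigValidation:
    def test_bad_fractions(self, genome):
        with pytest.raises(ValueError):
            SimConfig(genome=genome, class_fractions=(0.5, 0.2, 0.2))

    def test_bad_barrier(self):
        with pytest.raises(ValueError):
            Barrier("left", 50.0, 1.5, "stall")
        with pytest.raises(ValueError):
            Barrier("middle", 50.0, 0.5, "stall")

    def test_fragment_map_properties(self, genome, frag):
        assert frag.fragment_lengths().sum() == genome.length_bp
        assert np.all(np.diff(frag.cuts) > 0)
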