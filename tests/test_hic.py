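"""Fragment assignment, pair classification, binning and matrix balancing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from armalign import presets, simulate
from armalign.genome import FragmentMap, GenomeSpec
from armalign.hic import (NON_LIGATION, SELF_LIGATION, VALID, ContactMatrix,
                          ReadPair, assign_fragment, assign_fragments, bin_pairs,
                          classify_pair, classify_pairs, iterative_correction,
                          log_map, ori_center)


@pytest.fixture()
def circle100():
    g = GenomeSpec(name="c100", length_bp=100)
    return FragmentMap(cuts=np.array([11, 51]), genome=g)


@pytest.fixture()
def two_fragments():
    g = GenomeSpec(name="c2000", length_bp=2000)
    return FragmentMap(cuts=np.array([0, 1000]), genome=g)


class TestAssignFragment:
    def test_interior_and_wraparound(self, circle100):
        assert assign_fragment(20, circle100) == 0   # [11, 51)
        assert assign_fragment(5, circle100) == 1    # wrap fragment [51, 11)
        assert assign_fragment(51, circle100) == 1
        assert assign_fragment(11, circle100) == 0

    def test_against_linear_scan_oracle(self, circle100, rng):
        pos = rng.integers(0, 100, size=1000)

        def scan(p):
            cuts = circle100.cuts
            for i in range(len(cuts)):
                start, end = cuts[i], cuts[(i + 1) % len(cuts)]
                if (start <= p < end) if start < end else (p >= start or p < end):
                    return i
            raise AssertionError

        expect = np.array([scan(p) for p in pos])
        assert np.array_equal(assign_fragments(pos, circle100), expect)

    def test_out_of_range(self, circle100):
        with pytest.raises(ValueError):
            assign_fragment(100, circle100)


class TestClassifyPair:
    def test_stated_geometry_rules(self, two_fragments):
        assert classify_pair(ReadPair(100, "+", 800, "-"), two_fragments) == NON_LIGATION
        assert classify_pair(ReadPair(100, "-", 800, "+"), two_fragments) == SELF_LIGATION
        assert classify_pair(ReadPair(100, "+", 1500, "-"), two_fragments) == VALID

    def test_mate_order_irrelevant(self, two_fragments):
        assert classify_pair(ReadPair(800, "-", 100, "+"), two_fragments) == NON_LIGATION
        assert classify_pair(ReadPair(800, "+", 100, "-"), two_fragments) == SELF_LIGATION

    def test_wrap_fragment_orientation(self):
        g = GenomeSpec(name="g", length_bp=100)
        frag = FragmentMap(cuts=np.array([11, 51]), genome=g)
        # both mates on the wrap fragment [51, 11): 95 precedes 5 within it
        assert classify_pair(ReadPair(95, "+", 5, "-"), frag) == NON_LIGATION
        assert classify_pair(ReadPair(95, "-", 5, "+"), frag) == SELF_LIGATION

    def test_malformed_strand_errors(self, two_fragments):
        df = pd.DataFrame({"read_id": ["r"], "pos1": [1], "strand1": ["*"],
                           "pos2": [2], "strand2": ["+"]})
        with pytest.raises(ValueError, match="strand"):
            classify_pairs(df, two_fragments)

    def test_simulator_labels_recovered_exactly(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=20_000, seed=9)
        pairs = simulate.sample_pairs(cfg, frag)
        assert (classify_pairs(pairs, frag) == pairs["label"]).all()


class TestBinPairs:
    def test_zero_pairs(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        m = bin_pairs(pd.DataFrame(columns=["read_id", "pos1", "strand1", "pos2", "strand2"]), g)
        assert m.values.sum() == 0 and m.stage == "raw"

    def test_single_pair_symmetric_increment(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        df = pd.DataFrame({"read_id": ["r"], "pos1": [5_000], "strand1": ["+"],
                           "pos2": [25_000], "strand2": ["-"]})
        m = bin_pairs(df, g)
        assert m.values[0, 2] == 1 and m.values[2, 0] == 1
        assert m.values.sum() == 2

    def test_upper_triangle_conserves_valid_count(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=10_000, seed=2)
        pairs = simulate.sample_pairs(cfg, frag)
        m = bin_pairs(pairs, genome)
        n_valid = int((pairs["label"] == VALID).sum())
        assert np.triu(m.values).sum() == n_valid
        assert np.allclose(m.values, m.values.T)

    def test_diagonal_counted_once(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        df = pd.DataFrame({"read_id": ["a", "b"], "pos1": [1_000, 2_000],
                           "strand1": ["+", "+"], "pos2": [3_000, 29_000],
                           "strand2": ["-", "-"]})
        m = bin_pairs(df, g)
        assert m.values[0, 0] == 1  # same-bin pair
        assert np.triu(m.values).sum() == 2


def _sinkhorn_oracle(W, iters=200):
    """Independent alternating-scaling limit (row then column exact scaling)."""
    W = W.astype(float).copy()
    for _ in range(iters):
        r = W.sum(axis=1)
        W = W / r[:, None]
        c = W.sum(axis=0)
        W = W / c[None, :]
    return W / W.sum()


class TestIterativeCorrection:
    def test_uniform_matrix_is_fixed_point(self):
        g = GenomeSpec(name="g", length_bp=40_000)
        W = np.ones((4, 4)) - np.eye(4)
        m = ContactMatrix(values=W, bin_size=10_000, stage="raw", genome=g)
        bal = iterative_correction(m)
        assert np.allclose(bal.values, W, rtol=1e-9)
        assert bal.converged

    def test_matches_independent_sinkhorn_limit(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        W = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 1.0], [3.0, 1.0, 0.0]])
        m = ContactMatrix(values=W, bin_size=10_000, stage="raw", genome=g)
        bal = iterative_correction(m, tol=1e-12, max_iter=2000)
        expect = _sinkhorn_oracle(W) * W.sum()  # same total mass
        assert np.allclose(bal.values, expect, rtol=1e-6)

    def test_postconditions_on_simulated_matrix(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=50_000, seed=4)
        pairs = simulate.sample_pairs(cfg, frag)
        raw = bin_pairs(pairs, genome)
        bal = iterative_correction(raw)
        live = ~bal.mask
        s = np.nansum(bal.values[np.ix_(live, live)], axis=1)
        assert s.std() / s.mean() < 1e-6
        assert abs(np.nansum(bal.values) - raw.values[np.ix_(live, live)].sum()) \
            <= 1e-6 * raw.values.sum()
        assert np.allclose(bal.values, bal.values.T, equal_nan=True)

    def test_idempotent(self, genome, frag):
        cfg = presets.scenario("wt", n_pairs=50_000, seed=4)
        raw = bin_pairs(simulate.sample_pairs(cfg, frag), genome)
        bal = iterative_correction(raw)
        again = iterative_correction(bal)
        both = ~bal.mask & ~again.mask
        assert np.allclose(again.values[np.ix_(both, both)],
                           bal.values[np.ix_(both, both)], rtol=1e-5)

    def test_all_masked_errors(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        m = ContactMatrix(values=np.zeros((3, 3)), bin_size=10_000, stage="raw", genome=g)
        with pytest.raises(ValueError, match="masked"):
            iterative_correction(m)

    def test_nonconvergence_flagged_not_silent(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        W = np.array([[0.0, 5.0, 1.0], [5.0, 0.0, 0.5], [1.0, 0.5, 0.0]])
        m = ContactMatrix(values=W, bin_size=10_000, stage="raw", genome=g)
        with pytest.warns(RuntimeWarning, match="did not reach"):
            bal = iterative_correction(m, tol=1e-15, max_iter=1)
        assert not bal.converged


class TestLogMap:
    def _balanced(self, values):
        g = GenomeSpec(name="g", length_bp=10_000 * values.shape[0])
        return ContactMatrix(values=values, bin_size=10_000, stage="balanced", genome=g)

    def test_pseudocount_complement_gives_zero(self):
        m = self._balanced(np.full((3, 3), 0.9))
        out = log_map(m, pseudocount=0.1)
        assert np.allclose(out.values, 0.0)

    def test_symmetry_and_monotonicity(self, rng):
        W = rng.random((5, 5))
        W = (W + W.T) / 2
        out = log_map(self._balanced(W), pseudocount=0.01)
        assert np.allclose(out.values, out.values.T)
        flat_in, flat_out = W.ravel(), out.values.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)

    def test_stage_and_pseudocount_errors(self):
        g = GenomeSpec(name="g", length_bp=30_000)
        raw = ContactMatrix(values=np.ones((3, 3)), bin_size=10_000, stage="raw", genome=g)
        with pytest.raises(ValueError):
            log_map(raw)
        with pytest.raises(ValueError):
            log_map(self._balanced(np.ones((3, 3))), pseudocount=0.0)


class TestOriCenter:
    def test_ori_bin_moves_to_centre_and_total_unchanged(self, rng):
        g = GenomeSpec(name="g", length_bp=100_000, ori_bp=5_000)
        W = rng.random((10, 10))
        W = (W + W.T) / 2
        m = ContactMatrix(values=W, bin_size=10_000, stage="raw", genome=g)
        W[0, 0] = 7.7  # mark the ori bin
        c = ori_center(m)
        assert c.values[5, 5] == m.values[0, 0]
        assert c.bin_of(g.ori_bp) == 5
        assert np.isclose(c.values.sum(), m.values.sum())

    def test_double_rotation_identity(self, rng):
        g = GenomeSpec(name="g", length_bp=100_000, ori_bp=45_000)
        W = rng.random((10, 10))
        m = ContactMatrix(values=(W + W.T) / 2, bin_size=10_000, stage="raw", genome=g)
        once = ori_center(m)
        twice = ori_center(once)  # already centred: rotation is a no-op
        assert np.allclose(once.values, twice.values)
        assert once.bin_shift == twice.bin_shift
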