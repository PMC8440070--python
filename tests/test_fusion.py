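"""Dempster's rule against a brute-force power-set oracle, plus the belief /
plausibility identities for singleton-focused assignments."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecgfuse.fusion import TotalConflictError, bel_pls, combine, decide, fuse_streams
from ecgfuse.types import CLASSES


def dempster_powerset_oracle(m1, m2):
    """Full power-set combination over the 5-class frame.

    Masses are carried on all 2^5 subsets (here nonzero only on singletons);
    the fused mass of a set A sums products over all intersecting pairs with
    intersection exactly A, renormalised by one minus the conflict mass.
    """
    frame = range(5)
    subsets = [frozenset(s) for r in range(6) for s in itertools.combinations(frame, r)]
    M1 = {s: 0.0 for s in subsets}
    M2 = {s: 0.0 for s in subsets}
    for k in frame:
        M1[frozenset([k])] = m1[k]
        M2[frozenset([k])] = m2[k]
    fused = {s: 0.0 for s in subsets}
    conflict = 0.0
    for a in subsets:
        for b in subsets:
            p = M1[a] * M2[b]
            inter = a & b
            if inter:
                fused[inter] += p
            else:
                conflict += p
    if conflict >= 1.0:
        raise ZeroDivisionError
    return np.array([fused[frozenset([k])] / (1 - conflict) for k in frame])


def random_mass(rng):
    m = rng.dirichlet(np.ones(5))
    return m / m.sum()


class TestCombine:
    def test_uniform_pair(self):
        u = np.full(5, 0.2)
        res = combine(u, u)
        np.testing.assert_allclose(res.fused, u)
        assert res.conflict == pytest.approx(0.8)

    def test_certainty_absorbs(self):
        res = combine(np.array([1, 0, 0, 0, 0.0]), np.array([0.5, 0.5, 0, 0, 0.0]))
        np.testing.assert_allclose(res.fused, [1, 0, 0, 0, 0])
        assert res.conflict == pytest.approx(0.5)
        assert res.decided == "N"

    def test_partial_agreement(self):
        m1 = np.array([0.6, 0.4, 0, 0, 0.0])
        m2 = np.array([0.5, 0.5, 0, 0, 0.0])
        res = combine(m1, m2)
        np.testing.assert_allclose(res.fused, [0.6, 0.4, 0, 0, 0])
        assert res.conflict == pytest.approx(0.5)
        np.testing.assert_allclose(res.fused, dempster_powerset_oracle(m1, m2))

    def test_total_conflict_raises(self):
        with pytest.raises(TotalConflictError):
            combine(np.array([1, 0, 0, 0, 0.0]), np.array([0, 1, 0, 0, 0.0]))

    def test_matches_powerset_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m1, m2 = random_mass(rng), random_mass(rng)
            res = combine(m1, m2)
            expected = dempster_powerset_oracle(m1, m2)
            assert np.max(np.abs(res.fused - expected)) < 1e-12

    def test_commutative(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m1, m2 = random_mass(rng), random_mass(rng)
            np.testing.assert_array_equal(combine(m1, m2).fused, combine(m2, m1).fused)

    def test_uniform_is_neutral(self):
        rng = np.random.default_rng(8)
        u = np.full(5, 0.2)
        for _ in range(100):
            m = random_mass(rng)
            assert np.max(np.abs(combine(m, u).fused - m)) < 1e-12

    def test_shared_argmax_survives_fusion(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 200:
            m1, m2 = random_mass(rng), random_mass(rng)
            if np.argmax(m1) != np.argmax(m2):
                continue
            res = combine(m1, m2)
            assert np.argmax(res.fused) == np.argmax(m1)
            checked += 1


class TestBelPls:
    def test_singleton_identity(self):
        m = np.array([0.6, 0.4, 0, 0, 0.0])
        assert bel_pls(m, {"N"}) == (pytest.approx(0.6), pytest.approx(0.6))

    def test_whole_frame(self):
        m = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert bel_pls(m, set(CLASSES)) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_empty_set(self):
        m = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert bel_pls(m, set()) == (0.0, pytest.approx(0.0))

    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
           st.sets(st.sampled_from(list(CLASSES))))
    def test_bel_never_exceeds_pls(self, raw, subset):
        m = np.asarray(raw) / np.sum(raw)
        bel, pls = bel_pls(m, subset)
        assert bel <= pls + 1e-12


class TestDecide:
    def test_argmax(self):
        assert decide(np.array([0.1, 0.7, 0.1, 0.05, 0.05])) == "L"

    def test_tie_breaks_to_canonical_order(self):
        assert decide(np.full(5, 0.2)) == "N"

    def test_follows_combine(self):
        res = combine(np.array([1, 0, 0, 0, 0.0]), np.array([0.5, 0.5, 0, 0, 0.0]))
        assert decide(res.fused) == "N"


def test_fuse_streams_falls_back_on_total_conflict():
    cnn = np.array([[1, 0, 0, 0, 0.0], [0.5, 0.5, 0, 0, 0.0]])
    svr = np.array([[0, 1, 0, 0, 0.0], [0.5, 0.5, 0, 0, 0.0]])
    fused, labels, fallbacks = fuse_streams(cnn, svr)
    assert fallbacks == 1
    np.testing.assert_allclose(fused[0], cnn[0])  # CNN mass kept
    assert labels[0] == "N"
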