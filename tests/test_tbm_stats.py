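"""Voxel statistics: Welch t, pooled-null permutation FDR, budget formula."""
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuropheno.tbm_stats import (
    TbmDesign,
    min_permutations,
    permutation_fdr,
    welch_t,
    welch_t_map,
)


def test_identical_groups_give_zero_t():
    x = np.random.default_rng(0).normal(size=(4, 20))
    t, deg = welch_t(x, x.copy())
    assert np.allclose(t, 0.0)


def test_welch_hand_value():
    """A={1,2,3}, B={2,3,4}: t = (2-3)/sqrt(1/3+1/3) = -1.2247."""
    t, _ = welch_t(np.array([[1.0], [2.0], [3.0]]), np.array([[2.0], [3.0], [4.0]]))
    assert t[0] == pytest.approx(-1.224744871, abs=1e-8)


def test_group_swap_flips_sign():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=(5, 30)), rng.normal(size=(6, 30))
    t1, _ = welch_t(a, b)
    t2, _ = welch_t(b, a)
    assert np.allclose(t1, -t2)


def test_zero_variance_voxel_flagged_and_zeroed():
    a = np.ones((3, 2))
    b = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
    t, deg = welch_t(a, b)
    assert deg[0] and t[0] == 0.0
    assert not deg[1] and t[1] != 0.0


def test_welch_t_map_respects_mask():
    mask = np.zeros((4, 4), bool)
    mask[1:3, 1:3] = True
    maps_a = [np.full((4, 4), v) + np.eye(4) * 0.1 for v in (1.0, 1.2, 0.9)]
    maps_b = [np.full((4, 4), v) + np.eye(4) * 0.1 for v in (2.0, 2.1, 1.8)]
    timg = welch_t_map(maps_a, maps_b, mask)
    assert np.isnan(timg[0, 0]) and np.isfinite(timg[1, 1])


def test_min_permutations_formula():
    assert min_permutations(42000, 0.05) == 840000
    assert min_permutations(100, 0.05) == 2000
    assert min_permutations(1, 1.0) == 1


def exhaustive_pooled_p(a, b):
    """Independent oracle: enumerate all label splits, pool |t| across
    splits and voxels, plus-one p-values."""
    pooled = np.vstack([a, b])
    n, na = pooled.shape[0], a.shape[0]
    t_obs, _ = welch_t(a, b)
    null = []
    for idx in combinations(range(n), na):
        idx = list(idx)
        rest = [i for i in range(n) if i not in idx]
        null.append(np.abs(welch_t(pooled[idx], pooled[rest])[0]))
    null = np.concatenate(null)
    return np.array([(1 + (null >= abs(t)).sum()) / (1 + null.size) for t in t_obs])


def test_two_vs_two_matches_exhaustive_enumeration():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, (2, 15))
    b = rng.normal(0.5, 1, (2, 15))
    with pytest.warns(RuntimeWarning):
        tm = permutation_fdr(a, b, TbmDesign(n_permutations=100, seed=0))
    assert tm.exhaustive
    assert math.comb(4, 2) == 6
    assert np.allclose(tm.p, exhaustive_pooled_p(a, b))


def test_null_any_discovery_rate_controlled():
    """Pure-noise data: share of repeats with any discovery <= q + 2 SE."""
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        a = rng.normal(size=(8, 100))
        b = rng.normal(size=(8, 100))
        tm = permutation_fdr(a, b, TbmDesign(q=0.05, n_permutations=30, seed=rep))
        hits += int(tm.mask.any())
    assert hits / n_rep <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_rep)


def test_pooled_p_valid_under_label_exchange():
    """P(p <= alpha) <= alpha + discretisation on null data."""
    rng = np.random.default_rng(9)
    a = rng.normal(size=(10, 400))
    b = rng.normal(size=(10, 400))
    tm = permutation_fdr(a, b, TbmDesign(n_permutations=40, seed=1))
    for alpha in (0.01, 0.05, 0.1):
        assert (tm.p <= alpha).mean() <= alpha + 0.02


def test_planted_blob_recovered():
    rng = np.random.default_rng(5)
    a = rng.normal(1.0, 0.05, (10, 300))
    b = rng.normal(1.0, 0.05, (10, 300))
    b[:, :60] -= 0.2  # planted atrophy block
    tm = permutation_fdr(a, b, TbmDesign(q=0.05, n_permutations=100, seed=2))
    truth = np.zeros(300, bool)
    truth[:60] = True
    inter = (tm.mask & truth).sum()
    dice = 2 * inter / (tm.mask.sum() + truth.sum())
    assert dice > 0.5


@settings(derandomize=True, max_examples=20)
@given(seed=st.integers(0, 1000))
def test_mask_monotone_in_q(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (5, 50))
    b = rng.normal(0.8, 1, (5, 50))
    m1 = permutation_fdr(a, b, TbmDesign(q=0.01, n_permutations=40, seed=1)).mask
    m2 = permutation_fdr(a, b, TbmDesign(q=0.10, n_permutations=40, seed=1)).mask
    assert not (m1 & ~m2).any()


def test_p_values_never_zero():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 0.01, (6, 40)) + 5.0
    b = rng.normal(0, 0.01, (6, 40))
    tm = permutation_fdr(a, b, TbmDesign(n_permutations=60, seed=0))
    assert (tm.p > 0).all()


def test_stratified_shuffles_respect_strata():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(6, 30))
    b = rng.normal(size=(6, 30))
    strata = np.array([0, 0, 0, 1, 1, 1] * 2)
    tm = permutation_fdr(a, b, TbmDesign(n_permutations=50, seed=3,
                                         stratify=strata))
    assert tm.pool_size == 50 * 30
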