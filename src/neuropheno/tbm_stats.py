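"""Voxel-wise group statistics on Jacobian maps.

A two-sample unequal-variance (Welch) t statistic is computed at each
masked voxel. Significance is assessed non-parametrically: group labels
are permuted across subjects, the |t| statistics of every permutation at
every voxel are pooled into a single null distribution (so the effective
null size is n_permutations x n_voxels, which is how a desk-scale run
reaches the ~n_voxels/q pooled-null size a voxel-wise FDR needs), and
Benjamini-Hochberg at level q converts the pooled-null p-values into a
significance mask.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .types import ConfigurationError, InsufficientDataError


@dataclass(frozen=True)
class TbmDesign:
    """Permutation-FDR design: group sizes, FDR level, permutation budget."""

    q: float = 0.05
    n_permutations: int = 100
    seed: int = 0
    stratify: np.ndarray | None = None  # e.g. sex labels for stratified shuffles
    two_tailed: bool = True

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ConfigurationError("q must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ConfigurationError("need at least one permutation")


@dataclass
class TMap:
    """Welch t, pooled-null p, BH q-values and the significance mask."""

    t: np.ndarray
    p: np.ndarray
    q_values: np.ndarray
    mask: np.ndarray
    degenerate: np.ndarray = field(default=None)
    pool_size: int = 0
    exhaustive: bool = False


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t per column: (mean_a - mean_b)/sqrt(s2a/na + s2b/nb).

    Returns ``(t, degenerate)`` where degenerate flags voxels with zero
    variance in both groups (t there is 0 by convention).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(se2)
    t = np.where(degenerate, 0.0, t)
    return t, degenerate


def welch_t_map(jacobians_a, jacobians_b, mask: np.ndarray):
    """Welch t at every voxel of ``mask`` from stacked Jacobian maps
    (subject-first arrays); returns a t image (NaN outside the mask)."""
    a = np.stack([np.asarray(j)[mask] for j in jacobians_a])
    b = np.stack([np.asarray(j)[mask] for j in jacobians_b])
    t, _ = welch_t(a, b)
    out = np.full(mask.shape, np.nan)
    out[mask] = t
    return out


def min_permutations(n_voxels: int, q: float) -> int:
    """Required pooled-null size, ceil(n_voxels / q).

    At 42,000 brain voxels and q = 0.05 this is 840,000 -- reached at desk
    scale by pooling across voxels (n_permutations x n_voxels), not by
    840,000 label shuffles.
    """
    if n_voxels < 1 or not 0.0 < q <= 1.0:
        raise ConfigurationError("need n_voxels >= 1 and q in (0, 1]")
    return int(math.ceil(n_voxels / q * (1.0 - 1e-12)))


def _label_splits(n_total: int, n_a: int):
    """All distinct assignments of n_a 'group A' slots (exhaustive mode)."""
    for idx in combinations(range(n_total), n_a):
        yield np.array(idx, dtype=int)


def permutation_fdr(
    data_a: np.ndarray,
    data_b: np.ndarray,
    design: TbmDesign = TbmDesign(),
) -> TMap:
    """Pooled-null permutation test with BH-FDR mask.

    ``data_a``/``data_b`` are (n_subjects, n_voxels) arrays of Jacobian
    values at masked voxels. Per permutation the group labels are shuffled
    across all subjects (optionally within strata), t is recomputed at
    every voxel, and |t| values from all permutations and all voxels form
    one pooled null. Voxel p-values use the plus-one correction
    ``p = (1 + #{null >= |t|}) / (1 + pool_size)`` so they are never
    exactly zero. If fewer distinct label splits exist than requested
    permutations, all splits are enumerated exhaustively (with a warning).
    """
    a = np.atleast_2d(np.asarray(data_a, float))
    b = np.atleast_2d(np.asarray(data_b, float))
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    n = na + nb
    t_obs, degenerate = welch_t(a, b)

    n_distinct = math.comb(n, na)
    exhaustive = n_distinct <= design.n_permutations
    if exhaustive and design.stratify is None:
        if n_distinct < design.n_permutations:
            warnings.warn(
                f"only {n_distinct} distinct label splits; enumerating exhaustively",
                RuntimeWarning)
        splits = list(_label_splits(n, na))
        null_t = [welch_t(pooled[idx], np.delete(pooled, idx, axis=0))[0]
                  for idx in splits]
    else:
        rng = np.random.default_rng(design.seed)
        strata = (np.asarray(design.stratify) if design.stratify is not None
                  else np.zeros(n, dtype=int))
        null_t = []
        order = np.arange(n)
        for _ in range(design.n_permutations):
            perm = order.copy()
            for s in np.unique(strata):
                sel = np.where(strata == s)[0]
                perm[sel] = rng.permutation(perm[sel])
            shuffled = pooled[perm]
            null_t.append(welch_t(shuffled[:na], shuffled[na:])[0])

    null_pool = np.sort(np.abs(np.concatenate(null_t)).ravel())
    pool_size = null_pool.size
    stat = np.abs(t_obs) if design.two_tailed else t_obs
    n_ge = pool_size - np.searchsorted(null_pool, stat, side="left")
    p = (1.0 + n_ge) / (1.0 + pool_size)
    reject, q_values, _, _ = multipletests(p, alpha=design.q, method="fdr_bh")
    return TMap(t=t_obs, p=p, q_values=q_values, mask=reject,
                degenerate=degenerate, pool_size=pool_size,
                exhaustive=exhaustive)


def cluster_table(mask_img: np.ndarray, t_img: np.ndarray):
    """Connected components of a significance mask with size and peak |t|;
    returns a list of dicts (CSV-ready)."""
    from scipy import ndimage

    lab, n = ndimage.label(mask_img)
    rows = []
    for k in range(1, n + 1):
        sel = lab == k
        tt = t_img[sel]
        rows.append({
            "cluster": k,
            "n_voxels": int(sel.sum()),
            "peak_t": float(tt[np.nanargmax(np.abs(tt))]),
        })
    return rows
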