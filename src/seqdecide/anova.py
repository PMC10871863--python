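"""Omega-squared percent explained variance (PEV) from a one-way ANOVA.

omega^2 = 100 * (SS_effect - df_effect * MS_error) / (MS_error + SS_total)

is a bias-corrected effect size: unlike eta^2 it is approximately unbiased
under the null, so values may be negative; negative values are retained.
The module provides a scalar reference implementation plus vectorized paths
over time windows and balanced trial subsamples, which the sliding-window
selectivity analysis and its permutation nulls are built on.
"""

from __future__ import annotations

import numpy as np


def omega_squared(groups) -> float:
    """PEV (percent) of a one-way grouping.

    Parameters
    ----------
    groups
        Sequence of 1-D arrays, one per factor level.

    Returns 0.0 when the total sum of squares is zero.  May be negative.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 factor levels")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    n = sum(g.size for g in groups)
    k = len(groups)
    if n <= k:
        raise ValueError("need more observations than levels")
    data = np.concatenate(groups)
    codes = np.repeat(np.arange(k), [g.size for g in groups])
    return float(omega_squared_matrix(data[:, None], codes)[0])


def omega_squared_matrix(data: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """PEV per column of ``data`` (observations x windows) for integer level codes."""
    data = np.asarray(data, dtype=float)
    codes = np.asarray(codes)
    n, _ = data.shape
    levels, codes = np.unique(codes, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need at least 2 factor levels")
    counts = np.bincount(codes, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty group")
    onehot = np.zeros((k, n))
    onehot[codes, np.arange(n)] = 1.0
    gsum = onehot @ data  # k x W
    total = data.sum(axis=0)
    sstot = (data**2).sum(axis=0) - total**2 / n
    sseff = (gsum**2 / counts[:, None]).sum(axis=0) - total**2 / n
    return _omega_from_ss(sseff, sstot, k, n)


def _omega_from_ss(sseff, sstot, k: int, n: int) -> np.ndarray:
    sserr = sstot - sseff
    mserr = sserr / (n - k)
    denom = mserr + sstot
    with np.errstate(divide="ignore", invalid="ignore"):
        w2 = 100.0 * (sseff - (k - 1) * mserr) / denom
    return np.where(sstot <= 1e-300, 0.0, w2)


def balanced_subsample_pev(
    data: np.ndarray,
    codes: np.ndarray,
    n_subsamples: int,
    rng: np.random.Generator,
    subsample_size: int | None = None,
    reduce: bool = True,
) -> np.ndarray:
    """Mean PEV per window over balanced random subsamples.

    Per subsample, ``subsample_size`` trials (default: the minimum level
    count) are drawn without replacement within each level; PEV is computed on
    that balanced table and averaged over subsamples.

    Parameters
    ----------
    data
        Observations x windows firing-rate matrix.
    codes
        Integer (or label) level code per observation.
    reduce
        If False, return the full (n_subsamples, windows) array.
    """
    data = np.asarray(data, dtype=float)
    _, codes = np.unique(codes, return_inverse=True)
    k = codes.max() + 1
    level_idx = [np.flatnonzero(codes == g) for g in range(k)]
    m = min(len(ix) for ix in level_idx)
    if subsample_size is not None:
        if subsample_size > m:
            raise ValueError("subsample_size exceeds the smallest level count")
        m = subsample_size
    if m < 2:
        raise ValueError("need at least 2 trials per level")

    data2 = data**2
    n = k * m
    gsum = np.empty((k, n_subsamples, data.shape[1]))
    gsq = np.empty_like(gsum)
    for g, ix in enumerate(level_idx):
        # (n_subsamples, m) draws without replacement: m smallest random keys
        if m == ix.size:
            draws = np.broadcast_to(ix, (n_subsamples, m))
        else:
            keys = rng.random((n_subsamples, ix.size))
            draws = ix[np.argpartition(keys, m, axis=1)[:, :m]]
        gsum[g] = data[draws].sum(axis=1)
        gsq[g] = data2[draws].sum(axis=1)
    total = gsum.sum(axis=0)
    sstot = gsq.sum(axis=0) - total**2 / n
    sseff = (gsum**2).sum(axis=0) / m - total**2 / n
    w2 = _omega_from_ss(sseff, sstot, k, n)
    return w2.mean(axis=0) if reduce else w2
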