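"""Number-decision subspace geometry of the population state space.

Trials are sorted into 6 conditions (3 numerosities x same/different
decision), their mean-centered population vectors form a 6 x n_neurons matrix
X, and PCA of X (via SVD) yields a K = 3 dimensional basis.  The three
numerosity vertices of each decision span a triangle; its area measures
number coding strength and the cosine of the angle between the two decision
planes (normalized scalar product of their normals) measures the geometric
separation of same and different states.  Dimensionality reduction uses a
training half of trials; vertices are projected from the held-out half,
bootstrapped over random splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DECODING_GRID, SpikeData, WindowGrid, bin_counts, smooth_rates
from .design import TaskDesign

logger = logging.getLogger("seqdecide")

PAIRINGS = {"num1": "first_num", "num2": "second_num"}


def condition_cells(trials: pd.DataFrame, pairing: str, design: TaskDesign):
    """Ordered (numerosity, decision) cells and their trial positions."""
    col = PAIRINGS[pairing]
    cells = []
    for num in design.numerosities:
        for dec in ("same", "different"):
            ix = np.flatnonzero((trials[col] == num) & (trials["decision"] == dec))
            if ix.size == 0:
                raise ValueError(f"empty condition cell ({num}, {dec}) for pairing {pairing}")
            cells.append(((num, dec), ix))
    return cells


def condition_mean_matrix(rates_w: np.ndarray, cell_indices) -> tuple[np.ndarray, np.ndarray]:
    """Centered condition-mean matrix X (6 x neurons) and the grand mean.

    ``rates_w`` is neurons x trials (one time window); ``cell_indices`` the
    per-cell trial positions.  Rows are condition means minus the unweighted
    mean across the 6 conditions, so column means are zero.
    """
    R = np.stack([rates_w[:, ix].mean(axis=1) for _, ix in cell_indices])  # 6 x n
    rbar = R.mean(axis=0)
    return R - rbar, rbar


@dataclass
class SubspaceBasis:
    """Top-K eigenvectors of the condition-mean covariance."""

    components: np.ndarray  # neurons x K, orthonormal columns
    eigenvalues: np.ndarray  # all nonzero-rank eigenvalues, descending
    variance_explained: np.ndarray  # per component fraction, descending

    @property
    def k(self) -> int:
        return self.components.shape[1]


def pca_basis(X: np.ndarray, K: int = 3) -> SubspaceBasis:
    """PCA of the centered condition matrix via SVD.

    Raises if ``K`` exceeds the rank of ``X`` (at most rows - 1 = 5 for the
    6-condition matrix).
    """
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if K > rank:
        raise ValueError(f"K={K} exceeds matrix rank {rank}")
    evals = s**2 / (X.shape[0] - 1)
    var = s**2 / (s**2).sum()
    return SubspaceBasis(vt[:K].T, evals, var)


@dataclass
class PlaneGeometry:
    """Projected number-decision vertices and derived plane quantities."""

    vertices: dict  # (numerosity, decision) -> K-vector
    area_same: float
    area_different: float
    cos_theta: float  # nan when either plane is degenerate

    @classmethod
    def from_vertices(cls, verts_same: np.ndarray, verts_different: np.ndarray) -> "PlaneGeometry":
        """Build from 3 x K vertex arrays ordered by ascending numerosity."""
        verts_same = np.asarray(verts_same, dtype=float)
        verts_different = np.asarray(verts_different, dtype=float)

        def span(v):
            return v[1] - v[0], v[2] - v[0]

        def tri_area(a, b):
            g = np.dot(a, a) * np.dot(b, b) - np.dot(a, b) ** 2
            return 0.5 * np.sqrt(max(g, 0.0))

        s1, s2 = span(verts_same)
        d1, d2 = span(verts_different)
        a_s, a_d = tri_area(s1, s2), tri_area(d1, d2)
        cos = float("nan")
        if verts_same.shape[1] == 3 and a_s > 1e-12 and a_d > 1e-12:
            ns = np.cross(s1, s2)
            nd = np.cross(d1, d2)
            cos = float(np.dot(ns, nd) / (np.linalg.norm(ns) * np.linalg.norm(nd)))
        verts = {}
        return cls(verts, float(a_s), float(a_d), cos)


def project_plane_geometry(
    basis: SubspaceBasis,
    R_test: np.ndarray,
    rbar_train: np.ndarray,
    cell_keys,
) -> PlaneGeometry:
    """Project held-out condition means onto the basis and measure the planes.

    ``R_test`` holds uncentered 6 x neurons test-half condition means in the
    order of ``cell_keys``; centering reuses the training-half grand mean.
    """
    z = (R_test - rbar_train) @ basis.components  # 6 x K
    verts = {key: z[i] for i, key in enumerate(cell_keys)}
    nums = sorted({k[0] for k in verts})
    vs = np.stack([verts[(n, "same")] for n in nums])
    vd = np.stack([verts[(n, "different")] for n in nums])
    geom = PlaneGeometry.from_vertices(vs, vd)
    geom.vertices = verts
    return geom


@dataclass
class SubspaceResults:
    """Bootstrap time courses of plane areas, inter-plane cosine and variance."""

    pairing: str
    times: np.ndarray
    area_same: np.ndarray  # n_boot x windows
    area_different: np.ndarray
    cos_theta: np.ndarray  # n_boot x windows, nan for degenerate resamples
    variance_explained: np.ndarray  # n_boot x windows, top-K fraction
    design: TaskDesign
    n_dropped: int = 0

    def area_mean(self, decision: str = "same") -> np.ndarray:
        a = self.area_same if decision == "same" else self.area_different
        return a.mean(axis=0)

    def area_se(self, decision: str = "same") -> np.ndarray:
        a = self.area_same if decision == "same" else self.area_different
        if a.shape[0] < 2:
            return np.full(a.shape[1], np.nan)
        return a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])

    @property
    def cos_mean(self) -> np.ndarray:
        return np.nanmean(self.cos_theta, axis=0)

    @property
    def cos_var(self) -> np.ndarray:
        return np.nanvar(self.cos_theta, axis=0, ddof=1)

    def baseline_band(self, n_sd: float = 3.0) -> tuple[float, float, float]:
        """(mean, lower, upper) of per-window mean cosine before number 2.

        The band is mean ± ``n_sd`` standard deviations of the bootstrap-mean
        cosine over windows that end before the second number appears.
        """
        pre = self.times <= self.design.number2_onset + 1e-9
        vals = self.cos_mean[pre]
        mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals))
        return mu, mu - n_sd * sd, mu + n_sd * sd

    def summary(self) -> str:
        mu, lo, hi = self.baseline_band()
        peak = int(np.nanargmax(self.area_mean("same") + self.area_mean("different")))
        post = self.times > self.design.number2_onset
        lines = [
            f"Number-decision subspace ({self.pairing}), {self.times.size} windows, "
            f"{self.area_same.shape[0]} bootstrap splits",
            f"  mean top-K variance explained: {100 * np.nanmean(self.variance_explained):.1f}%",
            f"  peak summed plane area at {self.times[peak]:.2f} s",
            f"  pre-number-2 cos(theta) baseline {mu:.3f} (band [{lo:.3f}, {hi:.3f}]); "
            f"min post-onset cos(theta) {np.nanmin(self.cos_mean[post]):.3f}",
        ]
        if self.n_dropped:
            lines.append(f"  degenerate resamples dropped: {self.n_dropped}")
        return "\n".join(lines)


class NumberDecisionSubspace:
    """Model: number-decision condition geometry of a population over time.

    Parameters
    ----------
    trials, spikes
        The dataset; correct trials only by default.
    pairing
        ``num1`` (first number x decision) or ``num2`` (second number x
        decision).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spikes: SpikeData,
        pairing: str = "num1",
        grid: WindowGrid = DECODING_GRID,
        sigma: float = 1.0,
        K: int = 3,
        include_errors: bool = False,
        design: TaskDesign | None = None,
    ):
        if pairing not in PAIRINGS:
            raise ValueError(f"pairing must be one of {sorted(PAIRINGS)}")
        self.design = design or TaskDesign()
        self.pairing = pairing
        self.K = K
        if not include_errors:
            trials = trials.loc[trials["correct"].astype(bool)].reset_index(drop=True)
        self.trials = trials
        binned = bin_counts(spikes, grid, trial_ids=trials["trial_id"].to_numpy())
        self.rates = smooth_rates(binned, sigma) if sigma > 0 else binned
        self.cells = condition_cells(trials, pairing, self.design)

    def fit(
        self,
        n_boot: int = 1000,
        seed: int | None = None,
        windows: np.ndarray | None = None,
    ) -> SubspaceResults:
        """Bootstrap split-half geometry across windows.

        Per resample, each condition cell is subsampled to the minimum cell
        count and split half/half into training (PCA) and testing
        (projection) trials; this balances the unequal cell occupancies of
        the counterbalanced design.
        """
        rng = np.random.default_rng(seed)
        grid = self.rates.grid
        win = np.arange(grid.n_windows) if windows is None else np.atleast_1d(windows)
        data = self.rates.rates[:, :, win]  # neurons x trials x W
        keys = [k for k, _ in self.cells]
        m = min(ix.size for _, ix in self.cells)
        if m < 2:
            raise ValueError("need at least 2 trials per condition cell")
        m_train = m // 2
        m_test = m - m_train

        W = win.size
        shape = (n_boot, W)
        area_s = np.full(shape, np.nan)
        area_d = np.full(shape, np.nan)
        cos = np.full(shape, np.nan)
        varexp = np.full(shape, np.nan)
        dropped = 0
        for b in range(n_boot):
            Rtr = np.empty((6, data.shape[0], W))
            Rte = np.empty_like(Rtr)
            for i, (_, ix) in enumerate(self.cells):
                pick = rng.permutation(ix)[:m]
                Rtr[i] = data[:, pick[:m_train], :].mean(axis=1)
                Rte[i] = data[:, pick[m_train:], :].mean(axis=1)
            rbar = Rtr.mean(axis=0)  # neurons x W
            X = Rtr - rbar
            for w in range(W):
                try:
                    basis = pca_basis(X[:, :, w], self.K)
                except ValueError:
                    dropped += 1
                    continue
                geom = project_plane_geometry(basis, Rte[:, :, w], rbar[:, w], keys)
                area_s[b, w] = geom.area_same
                area_d[b, w] = geom.area_different
                cos[b, w] = geom.cos_theta
                varexp[b, w] = basis.variance_explained[: self.K].sum()
        if dropped:
            logger.info("subspace fit: %d degenerate window-resamples dropped", dropped)
        return SubspaceResults(
            self.pairing, grid.times[win], area_s, area_d, cos, varexp,
            self.design, dropped,
        )


def area_timecourse(
    trials, spikes, pairing="num1", n_boot: int = 1000, seed=None, **kwargs
) -> SubspaceResults:
    """Bootstrap mean ± SE plane area per window (convenience wrapper)."""
    return NumberDecisionSubspace(trials, spikes, pairing, **kwargs).fit(n_boot, seed)


def plane_angle_timecourse(
    trials, spikes, pairing="num1", n_boot: int = 1000, seed=None, **kwargs
) -> SubspaceResults:
    """Bootstrap cos(theta) mean/variance per window (convenience wrapper)."""
    return NumberDecisionSubspace(trials, spikes, pairing, **kwargs).fit(n_boot, seed)
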