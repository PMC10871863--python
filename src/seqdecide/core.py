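"""Spike containers, sliding-window binning, smoothing, and inclusion filters."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .design import TaskDesign, ValidationError


@dataclass(frozen=True)
class WindowGrid:
    """A sliding boxcar window grid on the trial clock.

    Windows are half-open ``[left, left + length)``; a spike exactly on a
    boundary belongs to the later window.  Each window is labeled by its
    *right* edge (``times``), matching the convention that selectivity latency
    is the end of the first significant window.
    """

    length: float
    step: float
    start: float = 0.0
    end: float = 3.7

    def __post_init__(self):
        if self.length <= 0 or self.step <= 0:
            raise ValueError("length and step must be positive")
        if self.end - self.start < self.length:
            raise ValueError("grid span shorter than window length")

    @property
    def n_windows(self) -> int:
        # 1e-9 guards against float representation of e.g. (3.7-0.2)/0.02
        return int(np.floor((self.end - self.start - self.length) / self.step + 1e-9)) + 1

    @property
    def lefts(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_windows)

    @property
    def rights(self) -> np.ndarray:
        return self.lefts + self.length

    @property
    def times(self) -> np.ndarray:
        """Window timestamps (right edges)."""
        return self.rights

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of windows fully contained in ``[t0, t1]``."""
        return (self.lefts >= t0 - 1e-9) & (self.rights <= t1 + 1e-9)


#: the default sliding grid for explained-variance analyses: 200 ms / 20 ms
PEV_GRID = WindowGrid(length=0.2, step=0.02)
#: the default decoding grid: contiguous 50 ms bins
DECODING_GRID = WindowGrid(length=0.05, step=0.05)


class SpikeData:
    """Per-neuron, per-trial spike times on the common trial clock.

    Parameters
    ----------
    trains
        Mapping ``neuron_id -> {trial_id -> sorted float array of spike
        times}``; seconds from fixation onset.
    """

    def __init__(self, trains: dict[int, dict[int, np.ndarray]]):
        self._trains = {
            int(n): {int(t): np.asarray(ts, dtype=float) for t, ts in d.items()}
            for n, d in trains.items()
        }

    @property
    def neuron_ids(self) -> list[int]:
        return list(self._trains)

    @property
    def n_neurons(self) -> int:
        return len(self._trains)

    def trial_ids(self, neuron_id: int) -> list[int]:
        return list(self._trains[neuron_id])

    def train(self, neuron_id: int, trial_id: int) -> np.ndarray:
        return self._trains[neuron_id].get(trial_id, np.empty(0))

    def subset(self, neuron_ids) -> "SpikeData":
        return SpikeData({n: self._trains[n] for n in neuron_ids})

    def validate(self, trials: pd.DataFrame, design: TaskDesign | None = None) -> None:
        """Check sortedness, time bounds, and trial-id referential integrity."""
        design = design or TaskDesign()
        known = set(trials["trial_id"].astype(int))
        end = design.analysis_end
        for n, d in self._trains.items():
            extra = set(d) - known
            if extra:
                raise ValidationError(
                    f"neuron {n}: spike trial id {min(extra)} not in trial table"
                )
            for t, ts in d.items():
                if ts.size and (np.any(np.diff(ts) < 0)):
                    raise ValidationError(f"neuron {n}, trial {t}: spike times not sorted")
                if ts.size and (ts[0] < 0 or ts[-1] > end + 1e-9):
                    raise ValidationError(
                        f"neuron {n}, trial {t}: spike time outside [0, {end}]"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeData):
            return NotImplemented
        if self._trains.keys() != other._trains.keys():
            return False
        for n in self._trains:
            a, b = self._trains[n], other._trains[n]
            if a.keys() != b.keys():
                return False
            for t in a:
                if not np.array_equal(a[t], b[t]):
                    return False
        return True


@dataclass
class BinnedRates:
    """Firing-rate tensor ``neuron x trial x window`` in Hz plus its grid."""

    rates: np.ndarray
    grid: WindowGrid
    neuron_ids: list[int]
    trial_ids: np.ndarray
    smoothing_sigma: float = 0.0  # Gaussian sigma in window units; 0 = none

    def __post_init__(self):
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        expect = (len(self.neuron_ids), len(self.trial_ids), self.grid.n_windows)
        if self.rates.shape != expect:
            raise ValueError(f"rate tensor shape {self.rates.shape} != {expect}")

    def trial_index(self, trial_ids) -> np.ndarray:
        """Positions of the given trial ids along the trial axis."""
        lookup = {t: i for i, t in enumerate(self.trial_ids)}
        return np.array([lookup[int(t)] for t in trial_ids], dtype=int)


def bin_counts(
    spikes: SpikeData,
    grid: WindowGrid,
    trial_ids=None,
    neuron_ids=None,
) -> BinnedRates:
    """Boxcar-bin spike trains into firing rates (Hz) on a sliding grid.

    Entry ``(n, t, w)`` is the spike count of neuron ``n`` on trial ``t``
    inside the half-open window ``[left_w, left_w + length)`` divided by the
    window length.
    """
    if grid.n_windows < 1:
        raise ValueError("empty window grid")
    neuron_ids = list(neuron_ids) if neuron_ids is not None else spikes.neuron_ids
    if trial_ids is None:
        seen: dict[int, None] = {}
        for n in neuron_ids:
            for t in spikes.trial_ids(n):
                seen.setdefault(t)
        trial_ids = np.array(sorted(seen), dtype=int)
    else:
        trial_ids = np.asarray(trial_ids, dtype=int)

    lefts, rights = grid.lefts, grid.rights
    out = np.zeros((len(neuron_ids), len(trial_ids), grid.n_windows))
    for i, n in enumerate(neuron_ids):
        for j, t in enumerate(trial_ids):
            ts = spikes.train(n, t)
            if ts.size:
                out[i, j] = np.searchsorted(ts, rights, side="left") - np.searchsorted(
                    ts, lefts, side="left"
                )
    out /= grid.length
    return BinnedRates(out, grid, neuron_ids, trial_ids)


def smooth_rates(rates: BinnedRates, sigma: float, truncate: float = 4.0) -> BinnedRates:
    """Gaussian-smooth rate series along the window axis.

    ``sigma`` is in window units (sigma = 1 on the 50 ms decoding grid means
    one bin).  The kernel is truncated at ``±truncate·sigma`` and renormalized
    at the series edges, so constant series are preserved exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(rates, rates=rates.rates.copy())
    radius = max(1, int(np.ceil(truncate * sigma)))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    num = convolve1d(rates.rates, kernel, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(
        np.ones(rates.rates.shape[-1]), kernel, mode="constant", cval=0.0
    )
    return replace(rates, rates=num / den, smoothing_sigma=float(sigma))


def trial_mean_rates(spikes: SpikeData, t0: float, t1: float) -> dict[int, np.ndarray]:
    """Per-neuron vector of mean firing rates (Hz) over ``[t0, t1)`` per trial."""
    span = t1 - t0
    out = {}
    for n in spikes.neuron_ids:
        tids = spikes.trial_ids(n)
        v = np.empty(len(tids))
        for j, t in enumerate(tids):
            ts = spikes.train(n, t)
            v[j] = np.count_nonzero((ts >= t0) & (ts < t1)) / span
        out[n] = v
    return out


def filter_neurons(
    trials: pd.DataFrame,
    spikes: SpikeData,
    min_rate: float = 0.5,
    min_trials: int = 30,
    design: TaskDesign | None = None,
) -> SpikeData:
    """Apply the standard inclusion criteria, preserving neuron order.

    A neuron is kept if its mean firing rate from fixation to rule onset
    (0 to 3.5 s) is at least ``min_rate`` Hz and it was recorded on at least
    ``min_trials`` completed trials.
    """
    design = design or TaskDesign()
    completed = set(trials["trial_id"].astype(int))
    keep = []
    for n in spikes.neuron_ids:
        tids = [t for t in spikes.trial_ids(n) if t in completed]
        if len(tids) < min_trials:
            continue
        total = sum(
            np.count_nonzero(spikes.train(n, t) < design.rule_onset) for t in tids
        )
        rate = total / (len(tids) * design.rule_onset)
        if rate >= min_rate:
            keep.append(n)
    return spikes.subset(keep)
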