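"""Time-resolved omega-squared selectivity of single neurons.

For each neuron and task factor, PEV is computed in sliding 200 ms windows
stepped by 20 ms, averaged over balanced trial subsamples, and tested against
the 99th percentile of a label-permutation null per window.  A neuron is
called selective for the factor when its PEV stays above threshold for a
minimum number of consecutive windows (10 by default); the latency is the end
of the first supra-threshold window and the preferred level is the mode, over
the longest significant run, of the level with the highest firing rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import balanced_subsample_pev
from .core import PEV_GRID, BinnedRates, SpikeData, WindowGrid, bin_counts
from .design import FACTOR_COLUMNS

logger = logging.getLogger("seqdecide")


def factor_codes(trials: pd.DataFrame, factor: str):
    """(integer codes, ordered levels) for a task factor of a trial table."""
    col = FACTOR_COLUMNS.get(factor, factor)
    values = trials[col].to_numpy()
    levels = np.unique(values)
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in values]), levels


def sliding_pev(
    data: np.ndarray,
    codes: np.ndarray,
    n_subsamples: int = 100,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-window mean PEV over balanced subsamples for one neuron.

    ``data`` is trials x windows; ``codes`` the factor level per trial.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return balanced_subsample_pev(data, codes, n_subsamples, rng)


def permutation_null(
    data: np.ndarray,
    codes: np.ndarray,
    n_perm: int = 1000,
    percentile: float = 99.0,
    n_subsamples: int = 100,
    rng: np.random.Generator | int | None = None,
    return_null: bool = False,
):
    """Per-window PEV threshold from label-shuffled permutations.

    Labels are permuted across trials (time structure intact) and the same
    subsample-averaged statistic recomputed, so observed and null values are
    exchangeable under the no-effect hypothesis.
    """
    if n_perm < 100:
        logger.warning("permutation_null: n_perm=%d < 100; thresholds will be coarse", n_perm)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    null = np.empty((n_perm, data.shape[1]))
    for p in range(n_perm):
        null[p] = balanced_subsample_pev(data, rng.permutation(codes), n_subsamples, rng)
    thr = np.percentile(null, percentile, axis=0)
    return (thr, null) if return_null else thr


@dataclass
class SelectivityCall:
    """Verdict for one neuron x factor."""

    selective: bool
    latency_s: float  # nan when never supra-threshold
    preferred_level: object  # factor level, or None
    longest_run: int
    peak_pev: float
    peak_time_s: float


def _runs(mask: np.ndarray):
    """(start, length) of each run of True."""
    out = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j < mask.size and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def classify_selectivity(
    pev: np.ndarray,
    threshold: np.ndarray,
    times: np.ndarray,
    data: np.ndarray,
    codes: np.ndarray,
    levels: np.ndarray,
    min_run: int = 10,
) -> SelectivityCall:
    """Apply the consecutive-window rule and extract latency/preference.

    Ties between preferred levels are broken toward the smaller level (logged).
    """
    if pev.shape != threshold.shape:
        raise ValueError("PEV series and threshold grids differ")
    above = pev > threshold
    runs = _runs(above)
    longest = max((ln for _, ln in runs), default=0)
    selective = longest >= min_run
    # latency: end of the first window of the first run satisfying the rule
    latency = float("nan")
    if selective:
        first = next(s for s, ln in runs if ln >= min_run)
        latency = float(times[first])

    preferred = None
    if selective:
        start, ln = max(runs, key=lambda r: r[1])
        k = levels.size
        counts = np.bincount(codes, minlength=k).astype(float)
        onehot = np.zeros((k, data.shape[0]))
        onehot[codes, np.arange(data.shape[0])] = 1.0
        means = (onehot @ data[:, start : start + ln]) / counts[:, None]
        winners = np.argmax(means, axis=0)  # argmax takes the first = smallest level on ties
        tally = np.bincount(winners, minlength=k)
        best = tally.max()
        tied = np.flatnonzero(tally == best)
        if tied.size > 1:
            logger.info("preferred-level tie broken toward smaller level %s", levels[tied[0]])
        preferred = levels[tied[0]]
    peak = int(np.argmax(pev))
    return SelectivityCall(
        selective=bool(selective),
        latency_s=latency,
        preferred_level=preferred,
        longest_run=int(longest),
        peak_pev=float(pev[peak]),
        peak_time_s=float(times[peak]),
    )


class SelectivityModel:
    """Sliding-window PEV selectivity of a population for one task factor.

    Parameters
    ----------
    rates
        Binned firing rates on the analysis grid (200 ms / 20 ms by default).
    trials
        Trial table aligned with ``rates.trial_ids``.
    factor
        One of ``first_num``, ``second_num``, ``decision``, ``protocol``,
        ``rule``, ``action``.
    include_errors
        Factor analyses use correct trials only unless set.
    """

    def __init__(
        self,
        rates: BinnedRates,
        trials: pd.DataFrame,
        factor: str,
        n_subsamples: int = 100,
        include_errors: bool = False,
    ):
        self.rates = rates
        self.factor = factor
        self.n_subsamples = n_subsamples
        trials = trials.set_index("trial_id").loc[rates.trial_ids].reset_index()
        keep = np.ones(len(trials), dtype=bool)
        if not include_errors:
            keep = trials["correct"].to_numpy(dtype=bool)
        self.trial_mask = keep
        self.trials = trials.loc[keep].reset_index(drop=True)
        self.codes, self.levels = factor_codes(self.trials, factor)
        if self.levels.size < 2:
            raise ValueError(f"factor {factor!r} has a single level in these trials")

    @classmethod
    def from_spikes(
        cls,
        trials: pd.DataFrame,
        spikes: SpikeData,
        factor: str,
        grid: WindowGrid = PEV_GRID,
        **kwargs,
    ) -> "SelectivityModel":
        rates = bin_counts(spikes, grid, trial_ids=trials["trial_id"].to_numpy())
        return cls(rates, trials, factor, **kwargs)

    def fit(
        self,
        n_perm: int = 1000,
        percentile: float = 99.0,
        min_run: int = 10,
        null_subsamples: int | None = None,
        seed: int | None = None,
    ) -> "SelectivityResults":
        """Compute PEV series, permutation thresholds and selectivity calls."""
        null_subsamples = self.n_subsamples if null_subsamples is None else null_subsamples
        grid = self.rates.grid
        n_neurons, w = len(self.rates.neuron_ids), grid.n_windows
        pev = np.empty((n_neurons, w))
        thr = np.empty((n_neurons, w))
        calls = []
        streams = np.random.SeedSequence(seed).spawn(n_neurons)
        for i in range(n_neurons):
            rng = np.random.default_rng(streams[i])
            data = self.rates.rates[i][self.trial_mask]
            pev[i] = sliding_pev(data, self.codes, self.n_subsamples, rng)
            thr[i] = permutation_null(
                data, self.codes, n_perm, percentile, null_subsamples, rng
            )
            calls.append(
                classify_selectivity(
                    pev[i], thr[i], grid.times, data, self.codes, self.levels, min_run
                )
            )
        table = pd.DataFrame(
            {
                "neuron_id": self.rates.neuron_ids,
                "selective": [c.selective for c in calls],
                "latency_s": [c.latency_s for c in calls],
                "preferred_level": [c.preferred_level for c in calls],
                "longest_run": [c.longest_run for c in calls],
                "peak_pev": [c.peak_pev for c in calls],
                "peak_time_s": [c.peak_time_s for c in calls],
            }
        )
        return SelectivityResults(self.factor, grid, pev, thr, table, self.levels)


@dataclass
class SelectivityResults:
    """Per-neuron PEV series, null thresholds and selectivity calls for a factor."""

    factor: str
    grid: WindowGrid
    pev: np.ndarray  # neurons x windows, mean over subsamples
    threshold: np.ndarray  # neurons x windows, null percentile
    calls: pd.DataFrame
    levels: np.ndarray

    @property
    def n_selective(self) -> int:
        return int(self.calls["selective"].sum())

    def normalized_pev(self) -> np.ndarray:
        """Each neuron's series divided by its maximum PEV for this factor."""
        peak = self.pev.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(peak > 0, self.pev / peak, 0.0)
        return out

    def summary(self) -> str:
        n = len(self.calls)
        lines = [
            f"Selectivity for factor {self.factor!r}",
            f"  neurons: {n}; selective: {self.n_selective} "
            f"({100 * self.n_selective / max(n, 1):.1f}%)",
        ]
        sel = self.calls[self.calls["selective"]]
        if len(sel):
            lines.append(
                f"  median latency: {sel['latency_s'].median():.3f} s; "
                f"median peak PEV: {sel['peak_pev'].median():.2f}%"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-window PEV and threshold table."""
        times = self.grid.times
        rows = []
        for i, nid in enumerate(self.calls["neuron_id"]):
            rows.append(
                pd.DataFrame(
                    {
                        "neuron_id": nid,
                        "factor": self.factor,
                        "time_s": times,
                        "pev": self.pev[i],
                        "threshold": self.threshold[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# population-level summaries


@dataclass
class PopulationSummary:
    pev_mean: pd.DataFrame  # window time x factor
    pev_se: pd.DataFrame
    ranksum_p: dict  # (factor a, factor b) -> per-window p-values
    cumulative: pd.DataFrame  # window time x factor: # neurons with latency <= t
    overlap: pd.DataFrame  # per-neuron selectivity flags per factor
    alpha: float = 0.01

    def overlap_counts(self) -> pd.Series:
        """Counts of neurons per selectivity pattern (Venn cells)."""
        flags = self.overlap.drop(columns="neuron_id")
        pattern = flags.apply(lambda r: "+".join(c for c in flags.columns if r[c]) or "none", axis=1)
        return pattern.value_counts()


def population_summary(
    results: dict[str, SelectivityResults],
    alpha: float = 0.01,
    normalize: bool = False,
) -> PopulationSummary:
    """Across-neuron PEV summaries, factor comparisons and latency accumulation.

    Rank-sum comparisons between the per-neuron PEV distributions of factor
    pairs are computed per window at ``alpha``; the cumulative curve counts
    neurons whose selectivity latency for a factor is at or before each
    timestamp.
    """
    factors = list(results)
    if not factors:
        raise ValueError("no factors given")
    any_res = results[factors[0]]
    if any_res.pev.shape[0] < 2:
        raise ValueError("population summary needs at least 2 neurons")
    times = any_res.grid.times

    series = {
        f: (r.normalized_pev() if normalize else r.pev) for f, r in results.items()
    }
    mean = pd.DataFrame({f: s.mean(axis=0) for f, s in series.items()}, index=times)
    se = pd.DataFrame(
        {f: s.std(axis=0, ddof=1) / np.sqrt(s.shape[0]) for f, s in series.items()},
        index=times,
    )

    ranksum = {}
    for i, a in enumerate(factors):
        for b in factors[i + 1 :]:
            sa, sb = series[a], series[b]
            if np.allclose(sa, sb):
                ranksum[(a, b)] = np.ones(times.size)
                continue
            p = np.empty(times.size)
            for w in range(times.size):
                p[w] = stats.ranksums(sa[:, w], sb[:, w]).pvalue
            ranksum[(a, b)] = p

    cum = {}
    for f, r in results.items():
        lat = r.calls.loc[r.calls["selective"], "latency_s"].to_numpy()
        cum[f] = np.array([(lat <= t + 1e-9).sum() for t in times])
    cumulative = pd.DataFrame(cum, index=times)

    overlap = pd.DataFrame({"neuron_id": any_res.calls["neuron_id"]})
    for f, r in results.items():
        overlap[f] = r.calls["selective"].to_numpy()
    return PopulationSummary(mean, se, ranksum, cumulative, overlap, alpha)


def split_half_tiling(
    rates: BinnedRates,
    trials: pd.DataFrame,
    factor: str,
    n_subsamples: int = 100,
    seed: int | None = None,
    include_errors: bool = False,
):
    """Split-half control for sequential tiling of selectivity.

    Trials are split at random into halves (stratified by factor level), PEV
    is computed per half, neurons are ordered by the training-half peak time,
    and the Spearman correlation between train and test peak times is
    returned.

    Returns
    -------
    order : ndarray
        Neuron ordering by training-half peak time.
    train, test : ndarray
        Neurons x windows PEV matrices, rows in original neuron order.
    rho, p : float
        Spearman correlation between train and test peak times.
    """
    if len(rates.neuron_ids) < 2:
        raise ValueError("tiling requires at least 2 neurons")
    rng = np.random.default_rng(seed)
    trials = trials.set_index("trial_id").loc[rates.trial_ids].reset_index()
    mask = np.ones(len(trials), bool) if include_errors else trials["correct"].to_numpy(bool)
    codes, _ = factor_codes(trials.loc[mask].reset_index(drop=True), factor)

    half_a = np.zeros(codes.size, dtype=bool)
    for g in np.unique(codes):
        ix = np.flatnonzero(codes == g)
        if ix.size < 4:
            raise ValueError(f"level {g} has fewer than 2 trials per half")
        pick = rng.permutation(ix)[: ix.size // 2]
        half_a[pick] = True

    data_all = rates.rates[:, mask, :]
    n_neurons, w = data_all.shape[0], data_all.shape[2]
    train = np.empty((n_neurons, w))
    test = np.empty((n_neurons, w))
    streams = np.random.SeedSequence(rng.integers(2**31)).spawn(n_neurons)
    for i in range(n_neurons):
        r = np.random.default_rng(streams[i])
        train[i] = sliding_pev(data_all[i][half_a], codes[half_a], n_subsamples, r)
        test[i] = sliding_pev(data_all[i][~half_a], codes[~half_a], n_subsamples, r)
    t_train = rates.grid.times[np.argmax(train, axis=1)]
    t_test = rates.grid.times[np.argmax(test, axis=1)]
    order = np.argsort(t_train, kind="stable")
    rho, p = stats.spearmanr(t_train, t_test)
    return order, train, test, float(rho), float(p)


def selectivity_groups(results: dict[str, SelectivityResults]) -> pd.DataFrame:
    """Standard neuron subgroups from first/second-number and decision calls."""
    first = results["first_num"].calls["selective"].to_numpy()
    second = results["second_num"].calls["selective"].to_numpy()
    dec = results["decision"].calls["selective"].to_numpy()
    return pd.DataFrame(
        {
            "neuron_id": results["first_num"].calls["neuron_id"],
            "first_only": first & ~second,
            "second_only": second & ~first,
            "both_numbers": first & second,
            "non_number": ~first & ~second,
            "decision_pure": dec & ~first & ~second,
            "decision_mixed": dec & (first | second),
        }
    )


def effect_size_correlations(
    results: dict[str, SelectivityResults],
    normalize: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of per-neuron peak PEV between factor pairs.

    Computed within the standard subgroups (first-only, second-only,
    both-numbers, non-number; decision pure/mixed).  Subgroups smaller than 3
    or with constant effect sizes are omitted with a log entry.
    """
    groups = selectivity_groups(results)

    def peaks(factor):
        src = results[factor]
        arr = src.normalized_pev() if normalize else src.pev
        return arr.max(axis=1)

    peak = {f: peaks(f) for f in ("first_num", "second_num", "decision")}
    num_peak = np.maximum(peak["first_num"], peak["second_num"])
    spec_pairs = [
        ("first_only", "first_num", "second_num"),
        ("second_only", "first_num", "second_num"),
        ("both_numbers", "first_num", "second_num"),
        ("non_number", "first_num", "second_num"),
        ("decision_pure", "number", "decision"),
        ("decision_mixed", "number", "decision"),
    ]
    rows = []
    for group, fx, fy in spec_pairs:
        sel = groups[group].to_numpy()
        if sel.sum() < 3:
            logger.info("effect_size_correlations: subgroup %s has <3 neurons; omitted", group)
            continue
        x = (num_peak if fx == "number" else peak[fx])[sel]
        y = (num_peak if fy == "number" else peak[fy])[sel]
        if np.std(x) == 0 or np.std(y) == 0:
            logger.info("effect_size_correlations: subgroup %s constant; omitted", group)
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((group, fx, fy, int(sel.sum()), float(rho), float(p)))
    return pd.DataFrame(
        rows, columns=["group", "factor_x", "factor_y", "n", "spearman_r", "p"]
    )
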