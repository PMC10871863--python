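import numpy as np
import pytest

from seqdecide import (
    PEV_GRID,
    SelectivityModel,
    WindowGrid,
    bin_counts,
    classify_selectivity,
    effect_size_correlations,
    permutation_null,
    population_summary,
    sliding_pev,
    split_half_tiling,
)
from seqdecide.selectivity import selectivity_groups


class TestPermutationNull:
    def test_percentile_100_equals_max(self, rng):
        data = rng.normal(size=(24, 3))
        codes = np.repeat([0, 1], 12)
        thr, null = permutation_null(
            data, codes, n_perm=200, percentile=100, n_subsamples=5, rng=rng, return_null=True
        )
        assert thr == pytest.approx(null.max(axis=0))

    def test_null_exceedance_near_nominal_rate(self, rng):
        # iid data: per-window exceedance of the 99th percentile ~ 1%
        hits = total = 0
        for _ in range(20):
            data = rng.normal(size=(40, 60))
            codes = np.repeat([0, 1], 20)
            pev = sliding_pev(data, codes, n_subsamples=10, rng=rng)
            thr = permutation_null(data, codes, 300, 99, n_subsamples=10, rng=rng)
            hits += (pev > thr).sum()
            total += pev.size
        assert 0.002 < hits / total < 0.025

    def test_seed_stability_of_thresholds(self, rng):
        from scipy.stats import ks_2samp

        data = rng.normal(size=(40, 20))
        codes = np.repeat([0, 1], 20)
        t1 = permutation_null(data, codes, 300, 99, 10, np.random.default_rng(1))
        t2 = permutation_null(data, codes, 300, 99, 10, np.random.default_rng(2))
        assert ks_2samp(t1, t2).pvalue > 0.01


class TestClassifySelectivity:
    grid = WindowGrid(0.2, 0.02, 0.0, 3.7)

    def fabricate(self, above_windows, n_trials=24):
        pev = np.zeros(self.grid.n_windows)
        pev[above_windows] = 10.0
        thr = np.full(self.grid.n_windows, 5.0)
        data = np.zeros((n_trials, self.grid.n_windows))
        data[:, above_windows] = np.repeat([1.0, 2.0], n_trials // 2)[:, None]
        codes = np.repeat([0, 1], n_trials // 2)
        return pev, thr, data, codes

    def test_never_above_threshold_not_selective(self):
        pev, thr, data, codes = self.fabricate([])
        call = classify_selectivity(pev, thr, self.grid.times, data, codes, np.array([1, 3]))
        assert not call.selective
        assert np.isnan(call.latency_s)
        assert call.preferred_level is None

    def test_run_of_nine_windows_insufficient(self):
        pev, thr, data, codes = self.fabricate(list(range(30, 39)))
        call = classify_selectivity(
            pev, thr, self.grid.times, data, codes, np.array([1, 3]), min_run=10
        )
        assert not call.selective
        assert call.longest_run == 9

    def test_run_of_ten_selective_with_latency_and_preference(self):
        pev, thr, data, codes = self.fabricate(list(range(30, 40)))
        call = classify_selectivity(
            pev, thr, self.grid.times, data, codes, np.array([1, 3]), min_run=10
        )
        assert call.selective
        # latency = right edge of first window of the qualifying run
        assert call.latency_s == pytest.approx(self.grid.times[30])
        assert call.preferred_level == 3  # level coded 1 has the higher rate

    def test_grid_mismatch_rejected(self):
        pev, thr, data, codes = self.fabricate(list(range(10)))
        with pytest.raises(ValueError):
            classify_selectivity(pev, thr[:-1], self.grid.times, data, codes, np.array([1, 3]))


class TestSelectivityModel:
    def test_planted_first_number_neuron_peaks_in_epoch(self, design, small_dataset):
        trials, spikes, truth = small_dataset
        planted = [i for i, g in enumerate(truth) if g.gain1_hz > 15][:3]
        if not planted:
            pytest.skip("no strongly planted neuron in fixture draw")
        rates = bin_counts(
            spikes.subset(planted), PEV_GRID, trial_ids=trials["trial_id"].to_numpy()
        )
        model = SelectivityModel(rates, trials, "first_num", n_subsamples=20)
        res = model.fit(n_perm=150, seed=0)
        for i, idx in enumerate(planted):
            g = truth[idx]
            peak_t = res.calls["peak_time_s"].iloc[i]
            assert g.latency1_s <= peak_t <= g.latency1_s + g.duration1_s + PEV_GRID.length
            assert res.calls["selective"].iloc[i]

    def test_preferred_level_recovery(self, design, small_dataset):
        trials, spikes, truth = small_dataset
        planted = [i for i, g in enumerate(truth) if g.gain1_hz > 15]
        rates = bin_counts(
            spikes.subset(planted), PEV_GRID, trial_ids=trials["trial_id"].to_numpy()
        )
        res = SelectivityModel(rates, trials, "first_num", n_subsamples=20).fit(
            n_perm=150, seed=1
        )
        hits = sum(
            res.calls["preferred_level"].iloc[i] == truth[idx].pref_num
            for i, idx in enumerate(planted)
            if res.calls["selective"].iloc[i]
        )
        n_sel = int(res.calls["selective"].sum())
        assert n_sel > 0 and hits >= 0.75 * n_sel

    def test_single_level_factor_rejected(self, design, small_dataset):
        trials, spikes, _ = small_dataset
        bad = trials.copy()
        bad["decision"] = "same"
        rates = bin_counts(spikes.subset([0]), PEV_GRID, trial_ids=trials["trial_id"].to_numpy())
        with pytest.raises(ValueError, match="single level"):
            SelectivityModel(rates, bad, "decision")


@pytest.fixture(scope="module")
def fitted(design, small_dataset):
    trials, spikes, truth = small_dataset
    rates = bin_counts(spikes, PEV_GRID, trial_ids=trials["trial_id"].to_numpy())
    out = {}
    for f in ("first_num", "second_num", "decision"):
        out[f] = SelectivityModel(rates, trials, f, n_subsamples=10).fit(n_perm=100, seed=3)
    return out


class TestPopulationSummary:

    def test_summary_shapes_and_cumulative_monotone(self, fitted):
        summ = population_summary(fitted)
        assert set(summ.pev_mean.columns) == set(fitted)
        for f in fitted:
            assert (np.diff(summ.cumulative[f]) >= 0).all()
            assert summ.cumulative[f].iloc[-1] == fitted[f].n_selective

    def test_identical_factor_distributions_not_significant(self, fitted):
        res = fitted["first_num"]
        summ = population_summary({"a": res, "b": res})
        assert (summ.ranksum_p[("a", "b")] > 0.01).all()

    def test_effect_size_correlation_table(self, fitted):
        table = effect_size_correlations(fitted)
        assert set(table.columns) == {"group", "factor_x", "factor_y", "n", "spearman_r", "p"}
        assert (table["n"] >= 3).all()
        assert table["spearman_r"].between(-1, 1).all()

    def test_groups_partition_population(self, fitted):
        g = selectivity_groups(fitted)
        parts = g[["first_only", "second_only", "both_numbers", "non_number"]].to_numpy()
        assert (parts.sum(axis=1) == 1).all()


class TestSplitHalfTiling:
    def test_noiseless_planted_latencies_recovered(self):
        # deterministic rate bumps at tiled windows, level-dependent amplitude
        rng = np.random.default_rng(0)
        grid = WindowGrid(0.2, 0.02, 0.0, 3.7)
        n_neurons, n_trials = 25, 48
        codes = np.tile([0, 1, 2], n_trials // 3)
        peaks = np.linspace(10, 160, n_neurons).astype(int)
        data = rng.normal(0, 0.01, size=(n_neurons, n_trials, grid.n_windows))
        for i, w in enumerate(peaks):
            data[i, :, w] += codes * 5.0
        from seqdecide.core import BinnedRates
        from seqdecide import enumerate_conditions, generate_trials, TaskDesign

        trials = generate_trials(enumerate_conditions(TaskDesign()), 1, p_correct=1.0, seed=0)
        rates = BinnedRates(data, grid, list(range(n_neurons)), trials["trial_id"].to_numpy())
        trials = trials.assign(first_num=np.array([1, 3, 9])[codes])
        trials["decision"] = np.where(trials.first_num == trials.second_num, "same", "different")
        order, train, test, rho, p = split_half_tiling(
            rates, trials, "first_num", n_subsamples=5, seed=1
        )
        assert rho > 0.99
        assert (np.argsort(train.argmax(axis=1))[: 5] == order[:5]).all()

    def test_single_neuron_rejected(self, design, small_dataset):
        trials, spikes, _ = small_dataset
        rates = bin_counts(spikes.subset([0]), PEV_GRID, trial_ids=trials["trial_id"].to_numpy())
        with pytest.raises(ValueError, match="2 neurons"):
            split_half_tiling(rates, trials, "first_num")
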