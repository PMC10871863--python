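import numpy as np
import pytest

from seqdecide import (
    DecoderSpec,
    NeuronGroundTruth,
    build_pseudopopulation,
    decode_cross_order,
    decode_decision_generalization,
    decode_sequence_vs_decision,
    decode_time_resolved,
    enumerate_conditions,
    generate_trials,
    simulate_spikes,
)

FAST = DecoderSpec(n_runs=8, n_perm=0, seed=0)


@pytest.fixture(scope="module")
def number_dataset(design):
    """Population with a strong first-number code in the number-1 epoch."""
    trials = generate_trials(enumerate_conditions(design), 5, seed=0)
    rng = np.random.default_rng(0)
    truth = [
        NeuronGroundTruth(
            baseline_hz=5.0, pref_num=int(rng.choice([1, 3, 9])),
            gain1_hz=25.0, latency1_s=0.6, duration1_s=0.45,
        )
        for _ in range(40)
    ]
    return trials, simulate_spikes(truth, trials, design, seed=1), truth


class TestPseudoPopulation:
    def test_min_trials_boundary(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        counts = trials.loc[trials.correct].first_num.value_counts()
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=int(counts.min()))
        assert pop.n_neurons == spikes.n_neurons  # all neurons share the session
        with pytest.raises(ValueError, match="no neuron"):
            build_pseudopopulation(trials, spikes, "first_num", min_trials=int(counts.min()) + 1)

    def test_sequence_pools_have_nine_classes(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "sequence", min_trials=5)
        assert len(pop.classes) == 9

    def test_infeasible_spec_rejected(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        big = DecoderSpec(n_train=100, n_test=100, n_perm=0)
        with pytest.raises(ValueError, match="trials per level"):
            decode_time_resolved(pop, big)


class TestTimeResolved:
    def test_planted_code_decodes_in_epoch_not_baseline(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        win = np.array([3, 16, 70])  # fixation, number-1 epoch, late delay 2
        res = decode_time_resolved(pop, FAST, win)
        assert res.mean_accuracy[1] >= 95.0
        assert abs(res.mean_accuracy[0] - res.chance) < 15
        assert abs(res.mean_accuracy[2] - res.chance) < 15

    def test_shuffled_labels_give_chance(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20).shuffled(3)
        res = decode_time_resolved(pop, DecoderSpec(n_runs=15, n_perm=0, seed=1), np.array([16]))
        assert abs(res.mean_accuracy[0] - 100 / 3) <= 3 * max(res.se_accuracy[0], 1.0)

    def test_permutation_threshold_separates_signal(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        spec = DecoderSpec(n_runs=8, n_perm=100, seed=2)
        res = decode_time_resolved(pop, spec, np.array([3, 16]))
        assert not res.significant[0]
        assert res.significant[1]

    def test_confusion_identity_for_perfect_decoder(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        res = decode_time_resolved(pop, FAST, np.array([16]))
        probs = res.confusion_probabilities(np.array([0]))
        assert np.diag(probs) == pytest.approx(np.ones(3), abs=0.1)

    def test_numerical_distance_effect_in_confusion(self, design):
        # wide log-Gaussian tuning: 3 and 9 are one octave-ish apart on log2
        # scale vs three for 1 and 9, so confusion(3,9) > confusion(1,9)
        trials = generate_trials(enumerate_conditions(design), 5, seed=2)
        rng = np.random.default_rng(5)
        truth = [
            NeuronGroundTruth(
                baseline_hz=5.0, pref_num=int(rng.choice([1, 3, 9])),
                tuning_width_oct=1.6, gain1_hz=8.0, latency1_s=0.6, duration1_s=0.45,
            )
            for _ in range(40)
        ]
        spikes = simulate_spikes(truth, trials, design, seed=6)
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        res = decode_time_resolved(pop, DecoderSpec(n_runs=25, n_perm=0, seed=3), np.array([16]))
        probs = res.confusion_probabilities(np.array([0]))
        i1, i3, i9 = (list(res.classes).index(n) for n in (1, 3, 9))
        near = probs[i3, i9] + probs[i9, i3]
        far = probs[i1, i9] + probs[i9, i1]
        assert near > far

    def test_chance_level_matches_class_count(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop2 = build_pseudopopulation(trials, spikes, "decision", min_trials=20)
        pop3 = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        r2 = decode_time_resolved(pop2, FAST, np.array([3]))
        r3 = decode_time_resolved(pop3, FAST, np.array([3]))
        assert r2.chance == pytest.approx(50.0)
        assert r3.chance == pytest.approx(100 / 3)


class TestCrossOrder:
    def make(self, design, consistent, n=35):
        trials = generate_trials(enumerate_conditions(design), 5, seed=1)
        rng = np.random.default_rng(4)
        truth = []
        for _ in range(n):
            p1 = int(rng.choice([1, 3, 9]))
            # inconsistent neurons re-tune arbitrarily in the second period
            t2map = None if consistent else {k: float(rng.random()) for k in (1, 3, 9)}
            truth.append(
                NeuronGroundTruth(
                    baseline_hz=5.0, pref_num=p1,
                    gain1_hz=20.0, latency1_s=0.6, duration1_s=0.5,
                    gain2_hz=20.0, latency2_s=2.1, duration2_s=0.5,
                    order_consistent=consistent, tuning2_map=t2map,
                )
            )
        return trials, simulate_spikes(truth, trials, design, seed=5)

    def test_order_consistent_code_generalizes(self, design):
        trials, spikes = self.make(design, consistent=True)
        out = decode_cross_order(trials, spikes, DecoderSpec(n_runs=8, n_perm=60, seed=6))
        assert out[(1, 2)].mean_accuracy[0] > 80
        assert out[(2, 1)].mean_accuracy[0] > 80
        assert out[(1, 2)].significant[0] and out[(2, 1)].significant[0]

    def test_order_specific_code_does_not_generalize(self, design):
        trials, spikes = self.make(design, consistent=False)
        out = decode_cross_order(trials, spikes, DecoderSpec(n_runs=8, n_perm=60, seed=7))
        assert out[(1, 1)].mean_accuracy[0] > 90
        assert out[(2, 2)].mean_accuracy[0] > 90
        for cell in ((1, 2), (2, 1)):
            assert abs(out[cell].mean_accuracy[0] - 100 / 3) < 15
            assert not out[cell].significant[0]


class TestSequenceVsDecision:
    def test_sequence_peaks_at_number2_decision_in_delay2(self, design):
        trials = generate_trials(enumerate_conditions(design), 5, seed=8)
        rng = np.random.default_rng(9)
        truth = []
        for _ in range(30):  # transient number codes for both orders
            truth.append(
                NeuronGroundTruth(
                    baseline_hz=5.0, pref_num=int(rng.choice([1, 3, 9])),
                    gain1_hz=20.0, latency1_s=0.6, duration1_s=0.5,
                    gain2_hz=20.0, latency2_s=2.1, duration2_s=0.5,
                )
            )
        for _ in range(15):  # decision signal in delay 2
            truth.append(
                NeuronGroundTruth(
                    baseline_hz=5.0,
                    decision_hz=float(10.0 * rng.choice([-1, 1])),
                    decision_onset_s=2.6,
                )
            )
        spikes = simulate_spikes(truth, trials, design, seed=10)
        win = np.array([9, 47, 67])  # fixation, number-2 epoch, late delay 2
        seq, dec = decode_sequence_vs_decision(
            trials, spikes,
            spec_seq=DecoderSpec(n_train=3, n_runs=8, n_perm=0, seed=11),
            spec_dec=DecoderSpec(n_train=10, n_runs=8, n_perm=0, seed=11),
            windows=win,
        )
        assert seq.chance == pytest.approx(100 / 9)
        assert np.argmax(seq.mean_accuracy) == 1
        assert np.argmax(dec.mean_accuracy) == 2
        assert dec.mean_accuracy[2] > 90

    def test_infeasible_training_pool_rejected(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        with pytest.raises(ValueError):
            decode_sequence_vs_decision(
                trials, spikes,
                spec_seq=DecoderSpec(n_train=100, n_test=100, n_perm=0),
                windows=np.array([10]),
            )


class TestDecisionGeneralization:
    def test_held_out_level_must_exist(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "decision", min_trials=20)
        with pytest.raises(ValueError, match="not in the task design"):
            decode_decision_generalization(pop, FAST, held_out_numbers=[5], windows=np.array([70]))

    def test_requires_decision_population(self, design, number_dataset):
        trials, spikes, _ = number_dataset
        pop = build_pseudopopulation(trials, spikes, "first_num", min_trials=20)
        with pytest.raises(ValueError, match="decision"):
            decode_decision_generalization(pop, FAST, windows=np.array([70]))
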