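"""Task-structured synthetic data: trials, ground-truth neurons, Poisson spikes.

The generator emulates the statistical structure the downstream analyses
assume: a 48-slot counterbalanced condition table, ~90% correct behavior,
and a population containing numerosity-tuned neurons (Gaussian tuning on a
log2 numerosity axis), order-consistent or order-specific second-period
tuning, decision signals ramping up in the second delay, selectivity
latencies tiled across the trial, and inhomogeneous Poisson spiking at 1 ms
resolution.  Generator parameters are calibration knobs for the analyses,
not claims about any recorded dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeData
from .design import TaskDesign, correct_action, enumerate_conditions

_DT = 0.001  # simulation resolution, seconds


@dataclass
class NeuronGroundTruth:
    """Rate-model parameters of one simulated neuron.

    The instantaneous rate is ``baseline`` plus, inside each number-response
    window ``[latency, latency + duration)``, an epoch gain times a Gaussian
    tuning curve in log2 numerosity, plus a decision term that ramps up from
    ``decision_onset_s`` and is sustained to the end of the trial.  Rates are
    clipped at zero before spike generation.
    """

    baseline_hz: float = 5.0
    pref_num: int = 3
    tuning_width_oct: float = 1.0
    gain1_hz: float = 0.0
    gain2_hz: float = 0.0
    latency1_s: float = 0.5
    duration1_s: float = 0.6
    latency2_s: float = 2.0
    duration2_s: float = 0.6
    order_consistent: bool = True
    pref_num2: int | None = None  # used when not order consistent
    #: optional map numerosity -> drive in [0, 1] for the second period,
    #: overriding the Gaussian tuning (fully order-specific re-tuning)
    tuning2_map: dict | None = None
    decision_hz: float = 0.0  # signed; + prefers "same"
    decision_onset_s: float = 2.5
    decision_ramp_s: float = 0.4
    #: optional map (first, second) -> sign multiplying the decision term;
    #: None means an abstract (pair-invariant) decision signal
    decision_pair_signs: dict | None = None

    def tuning(self, num: float, pref: float) -> float:
        d = np.log2(num) - np.log2(pref)
        return float(np.exp(-0.5 * (d / self.tuning_width_oct) ** 2))

    def rate_profile(self, n1: int, n2: int, design: TaskDesign) -> np.ndarray:
        """Instantaneous rate (Hz) on the 1 ms simulation grid for one condition."""
        t = np.arange(0.0, design.analysis_end, _DT)
        r = np.full(t.shape, self.baseline_hz)
        if self.gain1_hz:
            box = (t >= self.latency1_s) & (t < self.latency1_s + self.duration1_s)
            r += self.gain1_hz * self.tuning(n1, self.pref_num) * box
        if self.gain2_hz:
            box = (t >= self.latency2_s) & (t < self.latency2_s + self.duration2_s)
            if self.tuning2_map is not None:
                drive = self.tuning2_map[n2]
            else:
                pref2 = self.pref_num if self.order_consistent else (self.pref_num2 or self.pref_num)
                drive = self.tuning(n2, pref2)
            r += self.gain2_hz * drive * box
        if self.decision_hz:
            ramp = np.clip((t - self.decision_onset_s) / self.decision_ramp_s, 0.0, 1.0)
            if self.decision_pair_signs is not None:
                drive = self.decision_pair_signs.get((n1, n2), 0.0)
            else:
                drive = 1.0 if n1 == n2 else 0.0
            r += self.decision_hz * drive * ramp
        return np.clip(r, 0.0, None)


@dataclass
class PopulationSpec:
    """Composition and behavior of a simulated population.

    Fractions follow the mixed-selectivity composition reported for prefrontal
    populations in this task (pure first-number, pure second-number,
    both-number, pure decision, mixed number+decision); the remainder is
    untuned.  ``effect_scale`` multiplies every tuning/decision gain; 0 gives
    a statistically null population.
    """

    n_neurons: int = 100
    frac_pure_first: float = 0.056
    frac_pure_second: float = 0.041
    frac_both_numbers: float = 0.074
    frac_pure_decision: float = 0.098
    frac_mixed: float = 0.071
    order_consistent_frac: float = 0.61
    effect_scale: float = 1.0
    baseline_mean_hz: float = 5.0
    gain_mean_hz: float = 12.0
    decision_mean_hz: float = 9.0
    tuning_width_oct: float = 1.0
    duration_mean_s: float = 0.6
    decision_mode: str = "abstract"  # or "conjunctive"
    p_correct: float = 0.9
    rt_mu_log: float = -1.4  # lognormal parameters of release RT, seconds
    rt_sigma_log: float = 0.3
    seed: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "pure_first": self.frac_pure_first,
            "pure_second": self.frac_pure_second,
            "both_numbers": self.frac_both_numbers,
            "pure_decision": self.frac_pure_decision,
            "mixed": self.frac_mixed,
        }


def generate_trials(
    conditions: pd.DataFrame,
    n_per_slot: int = 10,
    p_correct: float = 0.9,
    seed: int | np.random.Generator = 0,
    rt_mu_log: float = -1.4,
    rt_sigma_log: float = 0.3,
) -> pd.DataFrame:
    """Expand condition slots into a randomized, behaviorally realized trial table."""
    if n_per_slot < 1:
        raise ValueError("n_per_slot must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    reps = conditions.loc[conditions.index.repeat(n_per_slot)].reset_index(drop=True)
    order = rng.permutation(len(reps))
    reps = reps.iloc[order].reset_index(drop=True)

    correct_act = [correct_action(d, r) for d, r in zip(reps["decision"], reps["rule"])]
    is_correct = rng.random(len(reps)) < p_correct
    other = {"hold": "release", "release": "hold"}
    performed = [
        ca if ok else other[ca] for ca, ok in zip(correct_act, is_correct)
    ]
    rt = np.full(len(reps), np.nan)
    released = np.asarray(performed) == "release"
    rt[released] = rng.lognormal(rt_mu_log, rt_sigma_log, released.sum())

    return pd.DataFrame(
        {
            "trial_id": np.arange(len(reps)),
            "first_num": reps["first_num"].astype(int),
            "second_num": reps["second_num"].astype(int),
            "protocol": reps["protocol"],
            "rule": reps["rule"],
            "decision": reps["decision"],
            "correct_action": correct_act,
            "performed_action": performed,
            "correct": is_correct,
            "rt_s": rt,
        }
    )


def _tiled(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Stratified latencies spanning [lo, hi): even spacing plus jitter."""
    if n == 0:
        return np.empty(0)
    edges = np.linspace(lo, hi, n + 1)
    return rng.permutation(edges[:-1] + rng.random(n) * np.diff(edges))


def sample_ground_truth(
    spec: PopulationSpec, design: TaskDesign | None = None
) -> list[NeuronGroundTruth]:
    """Draw a ground-truth population matching the spec composition.

    Deterministic for a given ``spec`` (the seed is part of the spec).
    Number-response latencies are tiled across the relevant span of the trial
    so that population selectivity covers the task timeline.
    """
    design = design or TaskDesign()
    if sum(spec.fractions.values()) > 1.0 + 1e-9:
        raise ValueError("population fractions sum to more than 1")
    rng = np.random.default_rng(spec.seed)
    counts = {k: int(round(f * spec.n_neurons)) for k, f in spec.fractions.items()}

    kinds: list[str] = []
    for k, c in counts.items():
        kinds += [k] * c
    kinds += ["untuned"] * (spec.n_neurons - len(kinds))
    kinds = kinds[: spec.n_neurons]

    first_kinds = [k for k in kinds if k in ("pure_first", "both_numbers", "mixed")]
    second_kinds = [k for k in kinds if k in ("pure_second", "both_numbers", "mixed")]
    lat1 = iter(_tiled(rng, len(first_kinds), design.number1_onset + 0.05, design.number2_onset - 0.1))
    lat2 = iter(_tiled(rng, len(second_kinds), design.number2_onset + 0.05, design.rule_onset - 0.5))

    numerosities = np.asarray(design.numerosities)
    pairs = [(int(a), int(b)) for a in numerosities for b in numerosities]
    out = []
    for k in kinds:
        gt = NeuronGroundTruth(
            baseline_hz=float(rng.gamma(2.0, spec.baseline_mean_hz / 2.0)),
            pref_num=int(rng.choice(numerosities)),
            tuning_width_oct=spec.tuning_width_oct,
        )
        scale = spec.effect_scale
        dur = float(np.clip(rng.gamma(4.0, spec.duration_mean_s / 4.0), 0.2, 1.2))
        if k in ("pure_first", "both_numbers", "mixed"):
            gt.gain1_hz = scale * float(rng.gamma(3.0, spec.gain_mean_hz / 3.0))
            gt.latency1_s = float(next(lat1))
            gt.duration1_s = dur
        if k in ("pure_second", "both_numbers", "mixed"):
            gt.gain2_hz = scale * float(rng.gamma(3.0, spec.gain_mean_hz / 3.0))
            gt.latency2_s = float(next(lat2))
            gt.duration2_s = dur
            gt.order_consistent = bool(rng.random() < spec.order_consistent_frac)
            if not gt.order_consistent:
                gt.pref_num2 = int(rng.choice(numerosities))
        if k in ("pure_decision", "mixed"):
            gt.decision_hz = (
                scale
                * float(rng.choice([-1.0, 1.0]))
                * float(rng.gamma(3.0, spec.decision_mean_hz / 3.0))
            )
            gt.decision_onset_s = float(rng.uniform(design.number2_onset + 0.4, design.delay2_onset + 0.4))
            if spec.decision_mode == "conjunctive":
                gt.decision_pair_signs = {p: float(rng.choice([-1.0, 1.0])) for p in pairs}
            elif spec.decision_mode != "abstract":
                raise ValueError(f"unknown decision_mode {spec.decision_mode!r}")
        out.append(gt)
    return out


def simulate_spikes(
    truth: list[NeuronGroundTruth],
    trials: pd.DataFrame,
    design: TaskDesign | None = None,
    seed: int | np.random.Generator = 0,
) -> SpikeData:
    """Inhomogeneous-Poisson spike trains for every neuron on every trial.

    The rate profile of a neuron depends only on the numerosity pair (and the
    derived decision), so profiles are evaluated once per condition; spike
    times are drawn by inverting the cumulative rate, at 1 ms resolution with
    sub-bin uniform placement.
    """
    design = design or TaskDesign()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n1 = trials["first_num"].to_numpy()
    n2 = trials["second_num"].to_numpy()
    tids = trials["trial_id"].to_numpy()
    pair_key = n1 * 1000 + n2
    trains: dict[int, dict[int, np.ndarray]] = {}
    for i, gt in enumerate(truth):
        d: dict[int, np.ndarray] = {}
        for key in np.unique(pair_key):
            a, b = int(key // 1000), int(key % 1000)
            rate = gt.rate_profile(a, b, design)
            cum = np.cumsum(rate) * _DT
            total = cum[-1] if cum.size else 0.0
            sel = np.flatnonzero(pair_key == key)
            counts = rng.poisson(total, sel.size) if total > 0 else np.zeros(sel.size, int)
            for j, c in zip(sel, counts):
                if c == 0:
                    d[int(tids[j])] = np.empty(0)
                    continue
                u = rng.random(c) * total
                idx = np.searchsorted(cum, u, side="left")
                times = (idx + rng.random(c)) * _DT
                d[int(tids[j])] = np.sort(np.minimum(times, design.analysis_end))
        trains[i] = d
    return SpikeData(trains)


def simulate_dataset(
    spec: PopulationSpec,
    design: TaskDesign | None = None,
    n_per_slot: int = 10,
):
    """Full synthetic dataset: (trials, spikes, ground truth).

    Seeding: trial realization, ground-truth sampling and spiking all derive
    from ``spec.seed`` via independent child streams.
    """
    design = design or TaskDesign()
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    trials = generate_trials(
        enumerate_conditions(design),
        n_per_slot=n_per_slot,
        p_correct=spec.p_correct,
        seed=np.random.default_rng(ss[0]),
        rt_mu_log=spec.rt_mu_log,
        rt_sigma_log=spec.rt_sigma_log,
    )
    truth = sample_ground_truth(spec, design)
    spikes = simulate_spikes(truth, trials, design, seed=np.random.default_rng(ss[2]))
    return trials, spikes, truth
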