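"""Pseudo-population decoding of task factors with linear SVMs.

Neurons recorded in separate sessions are combined into a pseudo-population:
per decoding run, trials are drawn independently per neuron within each factor
level and concatenated in a fixed neuron order into pseudo-trials (no
cross-neuron trial identity or noise correlation is assumed).  A linear SVM
(one-vs-one for more than two classes, as in the ECOC default of the toolbox
the analyses were introduced with) is trained on ``n_train`` trials per level
per window and scored on ``n_test`` held-out trials; accuracies are averaged
over runs and tested against the 99th percentile of decoders trained on
label-shuffled training trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from .core import DECODING_GRID, BinnedRates, SpikeData, WindowGrid, bin_counts, smooth_rates
from .design import FACTOR_COLUMNS, TaskDesign

logger = logging.getLogger("seqdecide")

#: tuning-period windows used for epoch-level (cross-order) decoding,
#: offset 100 ms from stimulus onset for visual latency
EPOCH_WINDOWS = {1: (0.6, 1.1), 2: (2.1, 2.6)}


@dataclass(frozen=True)
class DecoderSpec:
    """Classifier protocol parameters (linear SVM, one-vs-one multiclass)."""

    n_train: int = 10
    n_test: int = 10
    cv_folds: int = 5
    n_runs: int = 20
    n_perm: int = 1000
    percentile: float = 99.0
    seed: int | None = None
    standardize: bool = True
    record_cv: bool = False


class PseudoPopulation:
    """Trial-matched rate tensor plus per-neuron, per-level trial pools."""

    def __init__(
        self,
        rates: BinnedRates,
        trials: pd.DataFrame,
        factor: str,
        labels: np.ndarray,
        pools: list[dict],
        neuron_ids: list[int],
    ):
        self.rates = rates
        self.trials = trials
        self.factor = factor
        self.labels = labels
        self.pools = pools
        self.neuron_ids = neuron_ids
        self.classes = np.unique(labels)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def grid(self) -> WindowGrid:
        return self.rates.grid

    @property
    def min_pool(self) -> int:
        return min(min(len(v) for v in p.values()) for p in self.pools)

    def shuffled(self, seed=None) -> "PseudoPopulation":
        """Label-shuffled copy: per neuron, trials are reassigned to levels.

        Each neuron's recorded trials are randomly redistributed over the
        factor levels (pool sizes preserved).  Because pseudo-population
        neurons come from separate sessions, the session-local shuffle is the
        appropriate no-information null for the trial pools.
        """
        rng = np.random.default_rng(seed)
        pools = []
        for p in self.pools:
            allt = rng.permutation(np.concatenate([p[c] for c in self.classes]))
            out, at = {}, 0
            for c in self.classes:
                out[c] = allt[at : at + len(p[c])]
                at += len(p[c])
            pools.append(out)
        return PseudoPopulation(
            self.rates, self.trials, self.factor, self.labels, pools, self.neuron_ids
        )

    def relabel(self, factor: str, min_trials: int | None = None) -> "PseudoPopulation":
        """Same neurons and rate tensor, pools rebuilt for another factor."""
        labels = _trial_labels(self.trials, factor)
        pools, keep = _build_pools(self.pools, self.trials, labels, min_trials or 1)
        if not keep:
            raise ValueError(f"no neuron satisfies min_trials for factor {factor!r}")
        sub = [i for i, k in enumerate(keep) if k]
        rates = BinnedRates(
            self.rates.rates[sub],
            self.rates.grid,
            [self.neuron_ids[i] for i in sub],
            self.rates.trial_ids,
            self.rates.smoothing_sigma,
        )
        return PseudoPopulation(
            rates, self.trials, factor, labels, [pools[i] for i in sub],
            [self.neuron_ids[i] for i in sub],
        )


def _trial_labels(trials: pd.DataFrame, factor: str) -> np.ndarray:
    if factor == "sequence":
        return (
            trials["first_num"].astype(str) + "-" + trials["second_num"].astype(str)
        ).to_numpy()
    return trials[FACTOR_COLUMNS.get(factor, factor)].to_numpy()


def _build_pools(ref_pools_or_masks, trials, labels, min_trials):
    """Per-neuron pools dict(level -> trial positions), and a keep mask."""
    classes = np.unique(labels)
    pools, keep = [], []
    for entry in ref_pools_or_masks:
        if isinstance(entry, dict):  # existing pools: neuron's recorded trials
            avail = np.unique(np.concatenate(list(entry.values())))
        else:  # boolean mask over trial axis
            avail = np.flatnonzero(entry)
        p = {c: avail[labels[avail] == c] for c in classes}
        pools.append(p)
        keep.append(all(len(v) >= min_trials for v in p.values()))
    return pools, keep


def build_pseudopopulation(
    trials: pd.DataFrame,
    spikes: SpikeData,
    factor: str,
    min_trials: int = 20,
    grid: WindowGrid = DECODING_GRID,
    sigma: float = 1.0,
    include_errors: bool = False,
    design: TaskDesign | None = None,
) -> PseudoPopulation:
    """Bin, smooth, and pool trials per neuron and factor level.

    Neurons lacking ``min_trials`` usable trials for any level of the factor
    are excluded (default 20; the sequence factor over ordered numerosity
    pairs conventionally uses 5).
    """
    if not include_errors:
        trials = trials.loc[trials["correct"].astype(bool)].reset_index(drop=True)
    tids = trials["trial_id"].to_numpy()
    binned = bin_counts(spikes, grid, trial_ids=tids)
    rates = smooth_rates(binned, sigma) if sigma > 0 else binned
    labels = _trial_labels(trials, factor)

    pos = {int(t): i for i, t in enumerate(tids)}
    masks = []
    for n in spikes.neuron_ids:
        m = np.zeros(len(tids), dtype=bool)
        for t in spikes.trial_ids(n):
            if int(t) in pos:
                m[pos[int(t)]] = True
        masks.append(m)
    pools, keep = _build_pools(masks, trials, labels, min_trials)
    kept = [i for i, k in enumerate(keep) if k]
    if not kept:
        raise ValueError(f"no neuron has {min_trials} trials per level of {factor!r}")
    if len(kept) < len(keep):
        logger.info(
            "build_pseudopopulation: %d/%d neurons excluded (<%d trials per %s level)",
            len(keep) - len(kept), len(keep), min_trials, factor,
        )
    sub_rates = BinnedRates(
        rates.rates[kept], grid, [spikes.neuron_ids[i] for i in kept], tids,
        rates.smoothing_sigma,
    )
    return PseudoPopulation(
        sub_rates, trials, factor, labels,
        [pools[i] for i in kept], [spikes.neuron_ids[i] for i in kept],
    )


# ---------------------------------------------------------------------------
# decoding engine


def _draw_ids(pools_tr, pools_te, classes, n_train, n_test, rng):
    """Per-neuron disjoint train/test trial draws, per class."""
    n_neurons = len(pools_tr)
    tr = np.empty((n_neurons, len(classes), n_train), dtype=int)
    te = np.empty((n_neurons, len(classes), n_test), dtype=int)
    for i in range(n_neurons):
        used: set[int] = set()
        for c, cls in enumerate(classes):
            pool = pools_tr[i][cls]
            if len(pool) < n_train:
                raise ValueError(
                    f"neuron index {i}: train pool for level {cls!r} smaller than n_train"
                )
            pick = rng.permutation(pool)[:n_train]
            tr[i, c] = pick
            used.update(int(x) for x in pick)
        for c, cls in enumerate(classes):
            pool = np.array([t for t in pools_te[i][cls] if int(t) not in used])
            if len(pool) < n_test:
                raise ValueError(
                    f"neuron index {i}: test pool for level {cls!r} smaller than n_test"
                )
            te[i, c] = rng.permutation(pool)[:n_test]
    return tr, te


def _gather(rates: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """(neurons, k, m) trial ids -> pseudo-trial features (k*m, neurons, W)."""
    n, k, m = ids.shape
    feats = rates[np.arange(n)[:, None, None], ids, :]  # n, k, m, W
    return feats.transpose(1, 2, 0, 3).reshape(k * m, n, feats.shape[-1])


def _fit_score(Xtr, ytr, Xte, yte, standardize, cv_folds=0):
    """Train a linear SVM on one window; return (accuracy %, confusion, cv)."""
    if standardize:
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = 100.0 * np.mean(pred == yte)
    classes = clf.classes_
    lut = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)))
    for t, p in zip(yte, pred):
        conf[lut[t], lut[p]] += 1
    cv = np.nan
    if cv_folds:
        cv = 100.0 * cross_val_score(
            SVC(kernel="linear", C=1.0), Xtr, ytr, cv=cv_folds
        ).mean()
    return acc, conf, cv


@dataclass
class DecodingResult:
    """Accuracy time course of one decoder with its permutation threshold."""

    factor: str
    classes: np.ndarray
    times: np.ndarray
    accuracy: np.ndarray  # runs x windows, percent
    null_threshold: np.ndarray | None  # per window
    confusion: np.ndarray  # windows x k x k counts, summed over runs
    spec: DecoderSpec
    cv_accuracy: np.ndarray | None = None

    @property
    def chance(self) -> float:
        return 100.0 / len(self.classes)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def se_accuracy(self) -> np.ndarray:
        return self.accuracy.std(axis=0, ddof=1) / np.sqrt(self.accuracy.shape[0])

    @property
    def significant(self) -> np.ndarray:
        if self.null_threshold is None:
            raise ValueError("no permutation null was computed")
        return self.mean_accuracy > self.null_threshold

    def confusion_probabilities(self, windows: np.ndarray | None = None) -> np.ndarray:
        """Row-normalized classification-probability matrix.

        Averaged over runs and the selected windows (default: windows with
        significant decoding).
        """
        if windows is None:
            windows = np.flatnonzero(self.significant)
        windows = np.atleast_1d(windows)
        if windows.size == 0:
            raise ValueError("empty window selection for confusion probabilities")
        conf = self.confusion[windows].sum(axis=0)
        rows = conf.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return conf / rows

    def summary(self) -> str:
        peak = int(np.argmax(self.mean_accuracy))
        lines = [
            f"Decoding of {self.factor!r} ({len(self.classes)} classes, chance {self.chance:.1f}%)",
            f"  runs: {self.accuracy.shape[0]}; windows: {self.times.size}",
            f"  peak accuracy {self.mean_accuracy[peak]:.1f}% ± {self.se_accuracy[peak]:.1f}% "
            f"at {self.times[peak]:.2f} s",
        ]
        if self.null_threshold is not None:
            sig = self.significant
            lines.append(f"  significant windows: {int(sig.sum())}/{sig.size}")
        return "\n".join(lines)


def _decode_windows(rates, pools_tr, pools_te, classes, spec, windows, rng, n_reps,
                    shuffle=False, record_cv=False):
    k = len(classes)
    acc = np.empty((n_reps, len(windows)))
    conf = np.zeros((len(windows), k, k))
    cv = np.full((n_reps, len(windows)), np.nan) if record_cv else None
    ytr = np.repeat(classes, spec.n_train)
    yte = np.repeat(classes, spec.n_test)
    for r in range(n_reps):
        tr_ids, te_ids = _draw_ids(pools_tr, pools_te, classes, spec.n_train, spec.n_test, rng)
        ftr = _gather(rates, tr_ids)[:, :, windows]
        fte = _gather(rates, te_ids)[:, :, windows]
        y = rng.permutation(ytr) if shuffle else ytr
        for w in range(len(windows)):
            a, c, v = _fit_score(
                ftr[:, :, w], y, fte[:, :, w], yte, spec.standardize,
                spec.cv_folds if record_cv else 0,
            )
            acc[r, w] = a
            conf[w] += c
            if record_cv:
                cv[r, w] = v
    return acc, conf, cv


def decode_time_resolved(
    pop: PseudoPopulation,
    spec: DecoderSpec = DecoderSpec(),
    windows: np.ndarray | None = None,
    test_pop: PseudoPopulation | None = None,
) -> DecodingResult:
    """Per-window decoding accuracy with permutation significance.

    ``test_pop`` optionally supplies separate test pools over the same rate
    tensor (used by the generalization analyses); training draws are excluded
    from the test draws per neuron.
    """
    if spec.n_train + spec.n_test > pop.min_pool and test_pop is None:
        raise ValueError(
            f"spec needs {spec.n_train}+{spec.n_test} trials per level; "
            f"smallest pool has {pop.min_pool}"
        )
    rng = np.random.default_rng(spec.seed)
    windows = np.arange(pop.grid.n_windows) if windows is None else np.atleast_1d(windows)
    pools_te = test_pop.pools if test_pop is not None else pop.pools
    acc, conf, cv = _decode_windows(
        pop.rates.rates, pop.pools, pools_te, pop.classes, spec, windows, rng,
        spec.n_runs, shuffle=False, record_cv=spec.record_cv,
    )
    thr = None
    if spec.n_perm:
        null, _, _ = _decode_windows(
            pop.rates.rates, pop.pools, pools_te, pop.classes, spec, windows, rng,
            spec.n_perm, shuffle=True,
        )
        thr = np.percentile(null, spec.percentile, axis=0)
    return DecodingResult(
        pop.factor, pop.classes, pop.grid.times[windows], acc, thr, conf, spec, cv
    )


# ---------------------------------------------------------------------------
# cross-temporal decoding


@dataclass
class CrossTemporalResult:
    """Train-window x test-window accuracy matrix with significance outline."""

    factor: str
    classes: np.ndarray
    times: np.ndarray
    accuracy: np.ndarray  # runs x Wtrain x Wtest
    null_threshold: np.ndarray | None  # Wtrain x Wtest
    spec: DecoderSpec

    @property
    def chance(self) -> float:
        return 100.0 / len(self.classes)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def significant(self) -> np.ndarray:
        if self.null_threshold is None:
            raise ValueError("no permutation null was computed")
        return self.mean_accuracy > self.null_threshold

    def diagonal_test(self, alternative: str = "greater"):
        """Wilcoxon sign-rank of diagonal vs mean off-diagonal accuracy.

        Paired over train windows; ``greater`` asks whether decoding is
        better on the diagonal (a dynamic code) than off it.
        """
        m = self.mean_accuracy
        diag = np.diag(m)
        w = m.shape[0]
        off = (m.sum(axis=1) - diag) / (w - 1)
        res = stats.wilcoxon(diag, off, alternative=alternative)
        return float(res.statistic), float(res.pvalue)

    def summary(self) -> str:
        stat, p = self.diagonal_test()
        sig = self.significant if self.null_threshold is not None else None
        lines = [
            f"Cross-temporal decoding of {self.factor!r} "
            f"({self.times.size}x{self.times.size} windows, chance {self.chance:.1f}%)",
            f"  diagonal vs off-diagonal sign-rank: W={stat:.1f}, p={p:.2g}",
        ]
        if sig is not None:
            lines.append(
                f"  significant cells: {int(sig.sum())}/{sig.size} "
                f"(diagonal: {int(np.diag(sig).sum())}/{sig.shape[0]})"
            )
        return "\n".join(lines)


def decode_cross_temporal(
    pop: PseudoPopulation,
    spec: DecoderSpec = DecoderSpec(),
    windows: np.ndarray | None = None,
) -> CrossTemporalResult:
    """Train at one window, test at every window; permutation outline per cell."""
    if spec.n_train + spec.n_test > pop.min_pool:
        raise ValueError("spec infeasible for pool sizes")
    rng = np.random.default_rng(spec.seed)
    windows = np.arange(pop.grid.n_windows) if windows is None else np.atleast_1d(windows)
    classes = pop.classes
    ytr = np.repeat(classes, spec.n_train)
    yte = np.repeat(classes, spec.n_test)

    def one_rep(shuffle):
        tr_ids, te_ids = _draw_ids(pop.pools, pop.pools, classes, spec.n_train, spec.n_test, rng)
        ftr = _gather(pop.rates.rates, tr_ids)[:, :, windows]
        fte = _gather(pop.rates.rates, te_ids)[:, :, windows]
        y = rng.permutation(ytr) if shuffle else ytr
        out = np.empty((len(windows), len(windows)))
        for wt in range(len(windows)):
            Xtr = ftr[:, :, wt]
            if spec.standardize:
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                Xtr = (Xtr - mu) / sd
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(Xtr, y)
            for wv in range(len(windows)):
                Xte = fte[:, :, wv]
                if spec.standardize:
                    Xte = (Xte - mu) / sd
                out[wt, wv] = 100.0 * np.mean(clf.predict(Xte) == yte)
        return out

    acc = np.stack([one_rep(False) for _ in range(spec.n_runs)])
    thr = None
    if spec.n_perm:
        null = np.stack([one_rep(True) for _ in range(spec.n_perm)])
        thr = np.percentile(null, spec.percentile, axis=0)
    return CrossTemporalResult(pop.factor, classes, pop.grid.times[windows], acc, thr, spec)


# ---------------------------------------------------------------------------
# specialised decoders


def _epoch_features(trials, spikes, design, sigma=1.0, include_errors=False):
    """Smoothed-rate epoch means per neuron x trial for both number periods."""
    if not include_errors:
        trials = trials.loc[trials["correct"].astype(bool)].reset_index(drop=True)
    tids = trials["trial_id"].to_numpy()
    binned = bin_counts(spikes, DECODING_GRID, trial_ids=tids)
    rates = smooth_rates(binned, sigma)
    feats = {}
    for order, (t0, t1) in EPOCH_WINDOWS.items():
        m = rates.grid.window_mask(t0, t1)
        feats[order] = rates.rates[:, :, m].mean(axis=2)  # neurons x trials
    return trials, feats


def decode_cross_order(
    trials: pd.DataFrame,
    spikes: SpikeData,
    spec: DecoderSpec = DecoderSpec(),
    min_trials: int = 20,
    sigma: float = 1.0,
    design: TaskDesign | None = None,
) -> dict[tuple[int, int], DecodingResult]:
    """The 2x2 of training/testing numerosity decoders across orders.

    Cells are keyed ``(train_order, test_order)``; within-order cells decode
    at their own number epoch, cross-order cells train at one epoch and test
    at the other (features are epoch-averaged smoothed rates).
    """
    design = design or TaskDesign()
    if len(design.numerosities) < 2:
        raise ValueError("cross-order decoding needs at least 2 numerosity levels")
    trials, feats = _epoch_features(trials, spikes, design, sigma)
    labels = {1: trials["first_num"].to_numpy(), 2: trials["second_num"].to_numpy()}
    classes = np.unique(labels[1])
    n_neurons = feats[1].shape[0]
    masks = [np.ones(len(trials), dtype=bool)] * n_neurons
    pools = {}
    for order in (1, 2):
        p, keep = _build_pools(masks, trials, labels[order], min_trials)
        if not all(keep):
            raise ValueError("a neuron lacks trials for cross-order decoding")
        pools[order] = p

    out = {}
    for train_order in (1, 2):
        for test_order in (1, 2):
            rng = np.random.default_rng(spec.seed)
            Xsrc = feats[train_order][:, :, None]  # neurons x trials x 1 window
            Xdst = feats[test_order][:, :, None]
            k = len(classes)
            acc = np.empty((spec.n_runs, 1))
            conf = np.zeros((1, k, k))
            ytr = np.repeat(classes, spec.n_train)
            yte = np.repeat(classes, spec.n_test)

            def run_once(shuffle):
                tr_ids, te_ids = _draw_ids(
                    pools[train_order], pools[test_order], classes,
                    spec.n_train, spec.n_test, rng,
                )
                ftr = _gather(Xsrc, tr_ids)[:, :, 0]
                fte = _gather(Xdst, te_ids)[:, :, 0]
                y = rng.permutation(ytr) if shuffle else ytr
                return _fit_score(ftr, y, fte, yte, spec.standardize)

            for r in range(spec.n_runs):
                a, c, _ = run_once(False)
                acc[r, 0] = a
                conf[0] += c
            thr = None
            if spec.n_perm:
                null = np.array([run_once(True)[0] for _ in range(spec.n_perm)])
                thr = np.array([np.percentile(null, spec.percentile)])
            name = f"number(train={train_order},test={test_order})"
            times = np.array([EPOCH_WINDOWS[test_order][1]])
            out[(train_order, test_order)] = DecodingResult(
                name, classes, times, acc, thr, conf, spec
            )
    return out


def decode_sequence_vs_decision(
    trials: pd.DataFrame,
    spikes: SpikeData,
    spec_seq: DecoderSpec | None = None,
    spec_dec: DecoderSpec | None = None,
    windows: np.ndarray | None = None,
    min_trials_seq: int = 5,
    grid: WindowGrid = DECODING_GRID,
    sigma: float = 1.0,
) -> tuple[DecodingResult, DecodingResult]:
    """Decode the exact number sequence vs the same/different decision.

    Both decoders run on the sequence-qualified pseudo-population (at least
    ``min_trials_seq`` trials per ordered numerosity pair).  Sequence chance
    is 100/9 under the default design; decision chance is 50%.
    """
    spec_seq = spec_seq or DecoderSpec(n_train=3)
    spec_dec = spec_dec or DecoderSpec(n_train=10)
    pop_seq = build_pseudopopulation(
        trials, spikes, "sequence", min_trials=min_trials_seq, grid=grid, sigma=sigma
    )
    pop_dec = pop_seq.relabel("decision", min_trials=spec_dec.n_train + spec_dec.n_test)
    res_seq = decode_time_resolved(pop_seq, spec_seq, windows)
    res_dec = decode_time_resolved(pop_dec, spec_dec, windows)
    return res_seq, res_dec


def decode_decision_generalization(
    pop: PseudoPopulation,
    spec: DecoderSpec | None = None,
    held_out_numbers=None,
    windows: np.ndarray | None = None,
    design: TaskDesign | None = None,
) -> dict[int, DecodingResult]:
    """Leave-one-number-out generalization of the decision decoder.

    For each held-out numerosity, decision classifiers are trained on trials
    whose numbers exclude it in both positions (5 training trials per decision
    by default) and tested only on trials that contain it.
    """
    design = design or TaskDesign()
    spec = spec or DecoderSpec(n_train=5)
    if pop.factor != "decision":
        raise ValueError("generalization requires a decision pseudo-population")
    held_out_numbers = (
        list(design.numerosities) if held_out_numbers is None else list(np.atleast_1d(held_out_numbers))
    )
    n1 = pop.trials["first_num"].to_numpy()
    n2 = pop.trials["second_num"].to_numpy()
    out = {}
    for h in held_out_numbers:
        if h not in design.numerosities:
            raise ValueError(f"held-out numerosity {h} not in the task design")
        train_mask = (n1 != h) & (n2 != h)
        test_mask = (n1 == h) | (n2 == h)
        tr_pools, te_pools = [], []
        for p in pop.pools:
            tr = {c: v[train_mask[v]] for c, v in p.items()}
            te = {c: v[test_mask[v]] for c, v in p.items()}
            if any(len(v) < spec.n_train for v in tr.values()):
                raise ValueError(f"empty/insufficient training pool leaving out {h}")
            if any(len(v) < spec.n_test for v in te.values()):
                raise ValueError(f"empty/insufficient test pool for held-out {h}")
            tr_pools.append(tr)
            te_pools.append(te)
        rng = np.random.default_rng(spec.seed)
        win = np.arange(pop.grid.n_windows) if windows is None else np.atleast_1d(windows)
        acc, conf, _ = _decode_windows(
            pop.rates.rates, tr_pools, te_pools, pop.classes, spec, win, rng, spec.n_runs
        )
        thr = None
        if spec.n_perm:
            null, _, _ = _decode_windows(
                pop.rates.rates, tr_pools, te_pools, pop.classes, spec, win, rng,
                spec.n_perm, shuffle=True,
            )
            thr = np.percentile(null, spec.percentile, axis=0)
        out[h] = DecodingResult(
            f"decision(hold-out {h})", pop.classes, pop.grid.times[win], acc, thr, conf, spec
        )
    return out


class PopulationDecoder:
    """Model-style wrapper: a pseudo-population plus a decoding protocol.

    ``fit`` runs time-resolved decoding; ``fit_cross_temporal`` the
    train x test window generalization.  Both return results objects with
    ``summary()``.
    """

    def __init__(self, pop: PseudoPopulation, spec: DecoderSpec = DecoderSpec()):
        self.pop = pop
        self.spec = spec

    @classmethod
    def from_dataset(
        cls, trials, spikes, factor, spec: DecoderSpec = DecoderSpec(),
        min_trials: int = 20, **kwargs,
    ) -> "PopulationDecoder":
        return cls(build_pseudopopulation(trials, spikes, factor, min_trials, **kwargs), spec)

    def fit(self, windows=None) -> DecodingResult:
        return decode_time_resolved(self.pop, self.spec, windows)

    def fit_cross_temporal(self, windows=None) -> CrossTemporalResult:
        return decode_cross_temporal(self.pop, self.spec, windows)
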