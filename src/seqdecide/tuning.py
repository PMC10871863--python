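"""Numerosity tuning curves per presentation period and their consistency.

Tuning curves are mean firing rates per numerosity in 0.5 s windows offset by
100 ms from stimulus onset to accommodate visual response latency: the first
period is [0.6, 1.1) s and the second [2.1, 2.6) s.  Cross-period Pearson
correlations of a neuron's two curves quantify order consistency; a shuffle
predictor (mean + 3 SD of correlations under random rate-numerosity
reassignment) serves as the significance floor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import SpikeData, trial_mean_rates
from .design import TaskDesign

logger = logging.getLogger("seqdecide")

PERIODS = {"number1": (0.6, 1.1), "number2": (2.1, 2.6)}


def tuning_curves(
    trials: pd.DataFrame,
    spikes: SpikeData,
    design: TaskDesign | None = None,
    normalize: bool = False,
    include_errors: bool = False,
) -> pd.DataFrame:
    """Mean rate per numerosity per presentation period for every neuron.

    Returns a long DataFrame (neuron_id, period, numerosity, rate_hz).  With
    ``normalize`` each neuron x period curve is divided by its maximum (rate
    at the preferred numerosity).
    """
    design = design or TaskDesign()
    if not include_errors:
        trials = trials.loc[trials["correct"].astype(bool)]
    rows = []
    for period, (t0, t1) in PERIODS.items():
        col = "first_num" if period == "number1" else "second_num"
        rates = trial_mean_rates(spikes, t0, t1)
        trial_order = {int(t): i for i, t in enumerate(spikes.trial_ids(spikes.neuron_ids[0]))} if spikes.n_neurons else {}
        for n in spikes.neuron_ids:
            tids = np.asarray(spikes.trial_ids(n))
            sub = trials[trials["trial_id"].isin(tids)]
            pos = {int(t): i for i, t in enumerate(tids)}
            vals = {}
            for num in design.numerosities:
                sel = sub.loc[sub[col] == num, "trial_id"].to_numpy()
                if sel.size == 0:
                    raise ValueError(
                        f"neuron {n}, period {period}: no trials with numerosity {num}"
                    )
                vals[num] = rates[n][[pos[int(t)] for t in sel]].mean()
            if normalize:
                peak = max(vals.values())
                if peak > 0:
                    vals = {k: v / peak for k, v in vals.items()}
            for num, v in vals.items():
                rows.append((n, period, num, float(v)))
    return pd.DataFrame(rows, columns=["neuron_id", "period", "numerosity", "rate_hz"])


def _curve_matrix(curves: pd.DataFrame, period: str) -> tuple[np.ndarray, np.ndarray]:
    sub = curves[curves["period"] == period].pivot(
        index="neuron_id", columns="numerosity", values="rate_hz"
    )
    return sub.to_numpy(), sub.index.to_numpy()


def tuning_cross_correlation(
    curves: pd.DataFrame,
    groups: pd.DataFrame | None = None,
    n_shuffles: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-period correlation of tuning curves with a shuffle predictor.

    Parameters
    ----------
    curves
        Output of :func:`tuning_curves`.
    groups
        Optional per-neuron boolean group columns (e.g. from
        :func:`seqdecide.selectivity.selectivity_groups`); a column
        ``neuron_id`` is required.  Without it a single ``all`` group is used.

    Returns
    -------
    per_neuron : DataFrame
        neuron_id, r (Pearson between the neuron's two period curves).
        Neurons with a constant curve are excluded (logged).
    per_group : DataFrame
        group, n, mean_r, se_r, shuffle_mean, shuffle_predictor.  The
        predictor is mean + 3 SD of the *group-mean* correlation across
        shuffle repetitions: each repetition rebuilds the group mean from
        shuffled curves, so the observed group mean is compared against the
        spread of shuffled group means.
    """
    rng = np.random.default_rng(seed)
    c1, ids1 = _curve_matrix(curves, "number1")
    c2, ids2 = _curve_matrix(curves, "number2")
    assert np.array_equal(ids1, ids2)

    ok = (c1.std(axis=1) > 0) & (c2.std(axis=1) > 0)
    if (~ok).any():
        logger.info("tuning_cross_correlation: %d constant curves excluded", int((~ok).sum()))

    def rowwise_r(a, b):
        az = a - a.mean(axis=1, keepdims=True)
        bz = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((az**2).sum(axis=1) * (bz**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (az * bz).sum(axis=1) / denom

    r = rowwise_r(c1, c2)
    per_neuron = pd.DataFrame({"neuron_id": ids1[ok], "r": r[ok]})

    # shuffle predictor: break each neuron's rate-numerosity association
    # independently (neurons are independent recordings)
    k = c1.shape[1]
    null = np.empty((n_shuffles, int(ok.sum())))
    c1ok, c2ok = c1[ok], c2[ok]
    for s in range(n_shuffles):
        perm = np.argsort(rng.random((c2ok.shape[0], k)), axis=1)
        null[s] = rowwise_r(c1ok, np.take_along_axis(c2ok, perm, axis=1))

    if groups is None:
        groups = pd.DataFrame({"neuron_id": ids1, "all": True})
    rows = []
    gcols = [c for c in groups.columns if c != "neuron_id"]
    gidx = groups.set_index("neuron_id")
    for g in gcols:
        member = gidx.loc[ids1[ok], g].to_numpy(dtype=bool)
        n = int(member.sum())
        if n == 0:
            continue
        vals = r[ok][member]
        null_group_mean = null[:, member].mean(axis=1)  # one value per shuffle rep
        rows.append(
            (
                g,
                n,
                float(vals.mean()),
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                float(null_group_mean.mean()),
                float(null_group_mean.mean() + 3 * null_group_mean.std()),
            )
        )
    per_group = pd.DataFrame(
        rows, columns=["group", "n", "mean_r", "se_r", "shuffle_mean", "shuffle_predictor"]
    )
    return per_neuron, per_group
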