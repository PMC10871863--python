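"""Dataset persistence: trial-table CSV, NPZ spike container, JSON design sidecar."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpikeData
from .design import TRIAL_COLUMNS, TaskDesign, validate_trial_table

TRIALS_FILE = "trials.csv"
SPIKES_FILE = "spikes.npz"
DESIGN_FILE = "design.json"


def save_dataset(path, trials: pd.DataFrame, spikes: SpikeData, design: TaskDesign) -> Path:
    """Write a dataset directory (trials.csv, spikes.npz, design.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials[TRIAL_COLUMNS].to_csv(path / TRIALS_FILE, index=False)
    arrays = {}
    for n in spikes.neuron_ids:
        # ragged spikes flattened to (trial_id, spike_time) pair rows
        pairs = [
            np.column_stack(
                [np.full(len(spikes.train(n, t)), t, dtype=float), spikes.train(n, t)]
            )
            for t in spikes.trial_ids(n)
        ]
        arrays[f"neuron_{n}"] = (
            np.concatenate(pairs) if pairs else np.empty((0, 2))
        )
        arrays[f"trials_{n}"] = np.asarray(spikes.trial_ids(n), dtype=int)
    np.savez(path / SPIKES_FILE, **arrays)
    design.save_json(path / DESIGN_FILE)
    return path


def load_dataset(path) -> tuple[pd.DataFrame, SpikeData, TaskDesign]:
    """Load and validate a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    design = TaskDesign.load_json(path / DESIGN_FILE)
    trials = pd.read_csv(path / TRIALS_FILE)
    trials["correct"] = trials["correct"].astype(bool)
    validate_trial_table(trials, design)

    with np.load(path / SPIKES_FILE) as npz:
        neuron_ids = sorted(
            int(k.split("_", 1)[1]) for k in npz.files if k.startswith("neuron_")
        )
        trains: dict[int, dict[int, np.ndarray]] = {}
        for n in neuron_ids:
            pairs = npz[f"neuron_{n}"]
            d: dict[int, np.ndarray] = {
                int(t): np.empty(0) for t in npz[f"trials_{n}"]
            }
            if pairs.size:
                tids = pairs[:, 0].astype(int)
                for t in np.unique(tids):
                    d[int(t)] = pairs[tids == t, 1]
            trains[n] = d
    spikes = SpikeData(trains)
    spikes.validate(trials, design)
    return trials, spikes, design
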