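"""Config-driven end-to-end runs: simulate -> filter -> analyses -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import PEV_GRID, bin_counts, filter_neurons
from .decoding import (
    DecoderSpec,
    build_pseudopopulation,
    decode_time_resolved,
)
from .design import TaskDesign
from .io import save_dataset
from .selectivity import (
    SelectivityModel,
    effect_size_correlations,
    population_summary,
    selectivity_groups,
)
from .simulate import PopulationSpec, simulate_dataset
from .subspace import NumberDecisionSubspace
from .tuning import tuning_cross_correlation, tuning_curves

logger = logging.getLogger("seqdecide")


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run; every value has a demo-scale default."""

    master_seed: int = 0
    design: dict = field(default_factory=dict)  # TaskDesign overrides
    population: dict = field(default_factory=dict)  # PopulationSpec overrides
    n_per_slot: int = 6
    min_rate_hz: float = 0.5
    min_trials: int = 30
    stages: list = field(
        default_factory=lambda: ["simulate", "selectivity", "tuning", "decode", "subspace"]
    )
    selectivity_factors: list = field(default_factory=lambda: ["first_num", "second_num", "decision"])
    n_subsamples: int = 10
    n_perm: int = 100
    min_run: int = 10
    decode_factors: list = field(default_factory=lambda: ["decision"])
    decoder: dict = field(default_factory=lambda: {"n_runs": 10, "n_perm": 100})
    decode_window_step: int = 4  # decode every k-th 50 ms window
    min_trials_decoding: int = 20
    subspace_pairings: list = field(default_factory=lambda: ["num1"])
    n_boot: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(
            np.random.SeedSequence([self.master_seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
            % (2**31)
        )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order and write all outputs.

    Outputs are tidy CSVs per stage plus ``manifest.json`` (config, hash,
    derived seeds, versions) and ``summary.txt``.  A stage failure raises an
    error naming the stage; outputs of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = TaskDesign(**config.design)
    manifest = {
        "package": "seqdecide",
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
    }
    summary_lines = [f"seqdecide run (config {manifest['config_hash']})"]
    results: dict = {"manifest": manifest}

    def stage(name):
        return name in config.stages

    trials = spikes = truth = None
    try:
        if stage("simulate"):
            t0 = time.perf_counter()
            spec = PopulationSpec(**{**config.population, "seed": config.stage_seed("simulate")})
            trials, spikes, truth = simulate_dataset(spec, design, config.n_per_slot)
            spikes = filter_neurons(trials, spikes, config.min_rate_hz, config.min_trials, design)
            save_dataset(outdir / "dataset", trials, spikes, design)
            results.update(trials=trials, spikes=spikes, truth=truth)
            summary_lines.append(
                f"simulate: {len(trials)} trials, {spikes.n_neurons} neurons after filtering "
                f"({100 * trials['correct'].mean():.1f}% correct)"
            )
            logger.info("stage simulate done in %.1fs", time.perf_counter() - t0)

        if stage("selectivity"):
            t0 = time.perf_counter()
            if trials is None:
                raise RuntimeError("selectivity stage requires the simulate stage")
            rates = bin_counts(spikes, PEV_GRID, trial_ids=trials["trial_id"].to_numpy())
            sel_results = {}
            long_rows, call_rows = [], []
            for factor in config.selectivity_factors:
                model = SelectivityModel(rates, trials, factor, n_subsamples=config.n_subsamples)
                res = model.fit(
                    n_perm=config.n_perm,
                    min_run=config.min_run,
                    seed=config.stage_seed(f"selectivity:{factor}"),
                )
                sel_results[factor] = res
                call_rows.append(res.calls.assign(factor=factor))
                long_rows.append(res.to_frame())
                summary_lines.append("selectivity: " + res.summary().replace("\n", "; "))
            pd.concat(call_rows, ignore_index=True).to_csv(outdir / "selectivity_calls.csv", index=False)
            pd.concat(long_rows, ignore_index=True).to_csv(outdir / "selectivity_pev.csv", index=False)
            results["selectivity"] = sel_results
            if {"first_num", "second_num", "decision"} <= set(sel_results):
                corr = effect_size_correlations(sel_results)
                corr.to_csv(outdir / "effect_size_correlations.csv", index=False)
                summ = population_summary(sel_results)
                summ.pev_mean.to_csv(outdir / "population_pev_mean.csv")
                summary_lines.append(
                    "selectivity overlap: "
                    + ", ".join(f"{k}={v}" for k, v in summ.overlap_counts().items())
                )
            logger.info("stage selectivity done in %.1fs", time.perf_counter() - t0)

        if stage("tuning"):
            t0 = time.perf_counter()
            curves = tuning_curves(trials, spikes, design)
            curves.to_csv(outdir / "tuning_curves.csv", index=False)
            groups = None
            sel = results.get("selectivity")
            if sel and {"first_num", "second_num", "decision"} <= set(sel):
                groups = selectivity_groups(sel)[
                    ["neuron_id", "first_only", "second_only", "both_numbers", "non_number"]
                ]
            per_neuron, per_group = tuning_cross_correlation(
                curves, groups, seed=config.stage_seed("tuning")
            )
            per_group.to_csv(outdir / "tuning_cross_correlation.csv", index=False)
            results["tuning"] = (per_neuron, per_group)
            summary_lines.append(
                "tuning cross-correlation groups: "
                + ", ".join(f"{r.group}: r={r.mean_r:.2f}" for r in per_group.itertuples())
            )
            logger.info("stage tuning done in %.1fs", time.perf_counter() - t0)

        if stage("decode"):
            t0 = time.perf_counter()
            dec_results = {}
            rows = []
            for factor in config.decode_factors:
                spec = DecoderSpec(
                    **{**config.decoder, "seed": config.stage_seed(f"decode:{factor}")}
                )
                pop = build_pseudopopulation(
                    trials, spikes, factor, min_trials=config.min_trials_decoding
                )
                windows = np.arange(0, pop.grid.n_windows, config.decode_window_step)
                res = decode_time_resolved(pop, spec, windows)
                dec_results[factor] = res
                for r in range(res.accuracy.shape[0]):
                    rows.append(
                        pd.DataFrame(
                            {
                                "factor": factor,
                                "run": r,
                                "time_s": res.times,
                                "accuracy": res.accuracy[r],
                                "threshold": res.null_threshold,
                            }
                        )
                    )
                summary_lines.append("decode: " + res.summary().replace("\n", "; "))
            pd.concat(rows, ignore_index=True).to_csv(outdir / "decoding_accuracy.csv", index=False)
            results["decoding"] = dec_results
            logger.info("stage decode done in %.1fs", time.perf_counter() - t0)

        if stage("subspace"):
            t0 = time.perf_counter()
            sub_results = {}
            rows = []
            for pairing in config.subspace_pairings:
                model = NumberDecisionSubspace(trials, spikes, pairing, design=design)
                res = model.fit(n_boot=config.n_boot, seed=config.stage_seed(f"subspace:{pairing}"))
                sub_results[pairing] = res
                rows.append(
                    pd.DataFrame(
                        {
                            "pairing": pairing,
                            "time_s": res.times,
                            "area_same": res.area_mean("same"),
                            "area_different": res.area_mean("different"),
                            "cos_theta_mean": res.cos_mean,
                            "cos_theta_var": res.cos_var,
                            "variance_explained": np.nanmean(res.variance_explained, axis=0),
                        }
                    )
                )
                summary_lines.append("subspace: " + res.summary().replace("\n", "; "))
            pd.concat(rows, ignore_index=True).to_csv(outdir / "subspace_geometry.csv", index=False)
            results["subspace"] = sub_results
            logger.info("stage subspace done in %.1fs", time.perf_counter() - t0)
    except Exception as exc:  # annotate with the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write("\n".join(summary_lines) + "\n")
    return results
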