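"""Task design, condition enumeration, and trial-table validation.

The task is a sequential numerosity same/different comparison: after 0.5 s of
fixation a first dot numerosity is shown for 0.5 s, remembered over a 1 s
delay, followed by a second numerosity (0.5 s) and a second 1 s delay in which
the same/different decision can be formed.  A colored rule cue presented at
3.5 s maps the decision onto a motor act (red: release if different, hold if
same; blue: the reverse).  Analyses run on the trial clock from fixation onset
(0 s) to 0.2 s after rule onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROTOCOLS = ("standard", "control")
RULES = ("red", "blue")
DECISIONS = ("same", "different")
ACTIONS = ("hold", "release")

#: task factors analysable per trial, mapped to trial-table columns
FACTOR_COLUMNS = {
    "first_num": "first_num",
    "second_num": "second_num",
    "decision": "decision",
    "protocol": "protocol",
    "rule": "rule",
    "action": "performed_action",
}


class ValidationError(ValueError):
    """A dataset record violates a task-design invariant."""


@dataclass(frozen=True)
class TaskDesign:
    """Factor levels and epoch timing of the sequential comparison task.

    Epochs are contiguous half-open intervals on the trial clock (seconds):
    fixation [0, 0.5), number1 [0.5, 1.0), delay1 [1.0, 2.0), number2
    [2.0, 2.5), delay2 [2.5, 3.5); the rule cue appears at 3.5 s and the
    analysed span ends 0.2 s later.
    """

    numerosities: tuple[int, ...] = (1, 3, 9)
    protocols: tuple[str, ...] = PROTOCOLS
    rules: tuple[str, ...] = RULES
    fixation_s: float = 0.5
    number_s: float = 0.5
    delay_s: float = 1.0
    post_rule_s: float = 0.2

    def __post_init__(self):
        if len(self.numerosities) < 1 or len(set(self.numerosities)) != len(self.numerosities):
            raise ValueError("numerosities must be distinct")
        object.__setattr__(self, "numerosities", tuple(sorted(self.numerosities)))

    # -- epoch boundaries -------------------------------------------------
    @property
    def number1_onset(self) -> float:
        return self.fixation_s

    @property
    def delay1_onset(self) -> float:
        return self.fixation_s + self.number_s

    @property
    def number2_onset(self) -> float:
        return self.delay1_onset + self.delay_s

    @property
    def delay2_onset(self) -> float:
        return self.number2_onset + self.number_s

    @property
    def rule_onset(self) -> float:
        return self.delay2_onset + self.delay_s

    @property
    def analysis_end(self) -> float:
        return self.rule_onset + self.post_rule_s

    @property
    def epochs(self) -> dict[str, tuple[float, float]]:
        return {
            "fixation": (0.0, self.number1_onset),
            "number1": (self.number1_onset, self.delay1_onset),
            "delay1": (self.delay1_onset, self.number2_onset),
            "number2": (self.number2_onset, self.delay2_onset),
            "delay2": (self.delay2_onset, self.rule_onset),
        }

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "numerosities": list(self.numerosities),
            "protocols": list(self.protocols),
            "rules": list(self.rules),
            "fixation_s": self.fixation_s,
            "number_s": self.number_s,
            "delay_s": self.delay_s,
            "post_rule_s": self.post_rule_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            numerosities=tuple(d["numerosities"]),
            protocols=tuple(d["protocols"]),
            rules=tuple(d["rules"]),
            fixation_s=d["fixation_s"],
            number_s=d["number_s"],
            delay_s=d["delay_s"],
            post_rule_s=d["post_rule_s"],
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "TaskDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def correct_action(decision: str, rule: str) -> str:
    """Rule contingency: red -> release if different; blue -> release if same."""
    if rule == "red":
        return "release" if decision == "different" else "hold"
    if rule == "blue":
        return "release" if decision == "same" else "hold"
    raise ValueError(f"unknown rule {rule!r}")


def enumerate_conditions(design: TaskDesign | None = None) -> pd.DataFrame:
    """Enumerate the counterbalanced condition slots of the task.

    Ordered numerosity pairs are crossed with stimulus protocol and rule cue.
    Each same-pair (n, n) is duplicated so that, under the default three
    numerosities, same and different decisions contribute equally many slots:
    (3 same-pairs x 2) + 6 different pairs = 12 pair slots, times 2 protocols
    times 2 rules = 48 slots.

    Returns a DataFrame with one row per slot and columns ``slot_id``,
    ``first_num``, ``second_num``, ``protocol``, ``rule``, ``decision``,
    ``weight``.
    """
    design = design or TaskDesign()
    rows = []
    for n1 in design.numerosities:
        for n2 in design.numerosities:
            reps = 2 if n1 == n2 else 1
            decision = "same" if n1 == n2 else "different"
            for _ in range(reps):
                for proto in design.protocols:
                    for rule in design.rules:
                        rows.append((n1, n2, proto, rule, decision, 1))
    df = pd.DataFrame(
        rows,
        columns=["first_num", "second_num", "protocol", "rule", "decision", "weight"],
    )
    df.insert(0, "slot_id", np.arange(len(df)))
    return df


TRIAL_COLUMNS = [
    "trial_id",
    "first_num",
    "second_num",
    "protocol",
    "rule",
    "decision",
    "correct_action",
    "performed_action",
    "correct",
    "rt_s",
]


def validate_trial_table(trials: pd.DataFrame, design: TaskDesign | None = None) -> pd.DataFrame:
    """Validate a trial table against the task contingencies.

    Checks column presence, factor levels, the decision/number-pair identity,
    the rule-action contingency and the correctness flag.  Returns the table
    (with ``trial_id`` as plain column) on success.

    Raises
    ------
    ValidationError
        Naming the first offending record.
    """
    design = design or TaskDesign()
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    if trials["trial_id"].duplicated().any():
        dup = trials.loc[trials["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValidationError(f"duplicate trial_id {dup}")

    checks = [
        ("first_num", set(design.numerosities)),
        ("second_num", set(design.numerosities)),
        ("protocol", set(design.protocols)),
        ("rule", set(design.rules)),
        ("decision", set(DECISIONS)),
        ("correct_action", set(ACTIONS)),
        ("performed_action", set(ACTIONS)),
    ]
    for col, allowed in checks:
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = trials.loc[bad].iloc[0]
            raise ValidationError(
                f"trial {row['trial_id']}: unknown {col} level {row[col]!r}"
            )

    derived = np.where(trials["first_num"] == trials["second_num"], "same", "different")
    bad = trials["decision"].to_numpy() != derived
    if bad.any():
        row = trials.loc[bad].iloc[0]
        raise ValidationError(
            f"trial {row['trial_id']}: decision {row['decision']!r} inconsistent with "
            f"pair ({row['first_num']}, {row['second_num']})"
        )

    expect = [correct_action(d, r) for d, r in zip(trials["decision"], trials["rule"])]
    bad = trials["correct_action"].to_numpy() != np.asarray(expect)
    if bad.any():
        row = trials.loc[bad].iloc[0]
        raise ValidationError(f"trial {row['trial_id']}: correct_action violates rule contingency")

    bad = trials["correct"].astype(bool).to_numpy() != (
        trials["performed_action"].to_numpy() == trials["correct_action"].to_numpy()
    )
    if bad.any():
        row = trials.loc[bad].iloc[0]
        raise ValidationError(f"trial {row['trial_id']}: correct flag inconsistent with actions")
    return trials
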