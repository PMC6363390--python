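"""Trial-table container, CSV I/O and data-preparation filters.

The canonical in-memory container is a pandas DataFrame with one row
per choice trial; :class:`Dataset` wraps it together with an
append-only provenance log of the filters that have been applied.

Column dialect (comma-separated, UTF-8, header required, booleans 0/1):

    subjid, task, session, block, trial, sooner_mag, later_mag,
    later_delay, delay_unit, chose_later
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import TASK_UNITS

TASKS = tuple(TASK_UNITS)
DELAY_UNITS = ("second", "day", "week")

REQUIRED_COLUMNS = [
    "subjid", "task", "session", "block", "trial",
    "sooner_mag", "later_mag", "later_delay", "delay_unit", "chose_later",
]


class TrialFormatError(ValueError):
    """Raised when a trials table is structurally invalid."""


@dataclass(frozen=True)
class Offer:
    """One sooner-vs-later offer: a fixed immediate option against
    ``later_magnitude`` coins at ``later_delay`` (in ``delay_unit``)."""

    sooner_magnitude: float
    later_magnitude: float
    later_delay: float
    delay_unit: str
    sooner_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.later_delay <= 0:
            raise ValueError("later_delay must be > 0")
        if self.sooner_magnitude <= 0 or self.later_magnitude <= 0:
            raise ValueError("magnitudes must be > 0")
        if self.delay_unit not in DELAY_UNITS:
            raise ValueError(f"unknown delay unit: {self.delay_unit!r}")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    task: str
    session: int
    block: int
    trial_index: int
    offer: Offer
    chose_later: bool

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task: {self.task!r}")
        if self.session < 1:
            raise ValueError("session must be >= 1")


@dataclass
class Dataset:
    """Trial table plus an append-only record of applied filters."""

    trials: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_table(self.trials)

    @property
    def subjects(self) -> list:
        return sorted(self.trials["subjid"].unique())

    @property
    def tasks(self) -> list:
        return sorted(self.trials["task"].unique())

    def with_filter(self, trials: pd.DataFrame, note: dict) -> "Dataset":
        return Dataset(trials=trials.reset_index(drop=True),
                       provenance=[*self.provenance, note])

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2)

    def to_records(self) -> list:
        out = []
        for row in self.trials.itertuples(index=False):
            out.append(TrialRecord(
                subject_id=str(row.subjid), task=row.task, session=int(row.session),
                block=int(row.block), trial_index=int(row.trial),
                offer=Offer(sooner_magnitude=float(row.sooner_mag),
                            later_magnitude=float(row.later_mag),
                            later_delay=float(row.later_delay),
                            delay_unit=row.delay_unit),
                chose_later=bool(row.chose_later)))
        return out


def _validate_table(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"missing required column: {col!r}")
    bad_tasks = set(df["task"].unique()) - set(TASKS)
    if bad_tasks:
        raise TrialFormatError(f"unknown task token(s): {sorted(bad_tasks)}")
    bad_units = set(df["delay_unit"].unique()) - set(DELAY_UNITS)
    if bad_units:
        raise TrialFormatError(f"unknown delay unit(s): {sorted(bad_units)}")
    # each task's rows must carry that task's native unit
    unit_map = df.groupby("task")["delay_unit"].unique()
    for task, units in unit_map.items():
        expected = TASK_UNITS[task]
        if set(units) != {expected}:
            raise TrialFormatError(
                f"task {task} must use delay unit {expected!r}, found {sorted(units)}")
    if (df["later_delay"] <= 0).any():
        raise TrialFormatError("later_delay must be > 0")
    if (df[["sooner_mag", "later_mag"]] <= 0).any().any():
        raise TrialFormatError("magnitudes must be > 0")
    dup = df.duplicated(subset=["subjid", "task", "trial"])
    if dup.any():
        raise TrialFormatError("trial index must be unique within (subject, task)")


def read_trials(path) -> Dataset:
    """Read a trials CSV into a :class:`Dataset` (validating the dialect)."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"missing required column: {col!r}")
    df = df[REQUIRED_COLUMNS].copy()
    df["chose_later"] = df["chose_later"].astype(int).astype(bool)
    for col in ("session", "block", "trial"):
        df[col] = df[col].astype(int)
    for col in ("sooner_mag", "later_mag", "later_delay"):
        df[col] = df[col].astype(float)
    df["subjid"] = df["subjid"].astype(str)
    return Dataset(trials=df)


def write_trials(dataset: Dataset, path) -> None:
    """Write the trials table in the package CSV dialect (booleans 0/1)."""
    df = dataset.trials.copy()
    df["chose_later"] = df["chose_later"].astype(int)
    df.to_csv(path, index=False)


def count_first_order_violations(trials: pd.DataFrame, by=("subjid", "session")) -> pd.Series:
    """Count first-order (stochastic dominance) violations.

    A violation is choosing a 'smaller-later' offer: the later option is
    both smaller than the immediate option and delayed, so choosing it is
    dominated. Returns counts grouped by ``by`` (empty input -> empty).
    """
    if len(trials) == 0:
        return pd.Series(dtype=int)
    viol = (trials["later_mag"] < trials["sooner_mag"]) & trials["chose_later"].astype(bool)
    return viol.groupby([trials[c] for c in by]).sum().astype(int)


def flag_insensitive_subjects(trials: pd.DataFrame) -> list:
    """Subjects whose choices are insensitive to delay in some task.

    Operationalized as fraction-later in {0, 1} over all of a subject's
    trials in a task (always-later or always-sooner); such subjects
    carry no information about their discount rate.
    """
    frac = trials.groupby(["subjid", "task"])["chose_later"].mean()
    flagged = frac[(frac == 0.0) | (frac == 1.0)]
    return sorted({subj for subj, _task in flagged.index})


@dataclass(frozen=True)
class FilterPolicy:
    """Data-preparation policy: drop the first non-verbal session (high
    violation rates while perceptual learning completes) and optionally
    exclude delay-insensitive subjects."""

    drop_nv_session1: bool = True
    exclude_insensitive: bool = False

    @classmethod
    def from_json(cls, text: str) -> "FilterPolicy":
        return cls(**json.loads(text))


def prepare_dataset(raw: Dataset, policy: FilterPolicy = FilterPolicy()) -> Dataset:
    """Apply the preparation filters, recording each in provenance.

    Idempotent: applying the same policy twice changes nothing beyond a
    repeated provenance note.
    """
    df = raw.trials
    out = raw
    if policy.drop_nv_session1:
        nv1 = (df["task"] == "NV") & (df["session"] == 1)
        kept = df.loc[~nv1]
        out = out.with_filter(kept, {
            "filter": "drop_nv_session1", "n_dropped": int(nv1.sum())})
        df = out.trials
    flagged = flag_insensitive_subjects(df)
    if policy.exclude_insensitive and flagged:
        kept = df.loc[~df["subjid"].isin(flagged)]
        out = out.with_filter(kept, {
            "filter": "exclude_insensitive", "subjects": flagged})
    else:
        out = out.with_filter(df, {
            "filter": "flag_insensitive", "subjects": flagged})
    if len(out.trials) == 0:
        raise ValueError("no data left after filtering")
    return out
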