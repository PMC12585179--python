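"""Encoding of the fear-conditioning reinstatement paradigm.

The experiment is represented as a fixed schedule of 36 atomic trials spread
over seven phases (acquisition, test 1, two extinction blocks, test 2, an
unsignaled shock, and test 3).  Each trial carries an abstract time stamp
(24 h between experimental days maps to 20 model time units), a
two-dimensional stimulus vector (tone/CS salience and context salience), and
a binary shock (US) indicator.  Conditioned responses (CR; freezing
proportions in [0, 1]) are handled as per-animal traces that can be
max-normalized, and test phases are compared through a discrimination index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "TrialSchedule",
    "CRTrace",
    "build_reinstatement_schedule",
    "normalize_trace",
    "discrimination_index",
    "read_traces_csv",
    "write_traces_csv",
]

#: Phase labels in experimental order.
PHASES = (
    "acquisition",
    "test1",
    "extinction1",
    "extinction2",
    "test2",
    "unsignaled_shock",
    "test3",
)

# 1-based trial ranges of each phase (inclusive).
_PHASE_TRIALS = {
    "acquisition": (1, 3),
    "test1": (4, 4),
    "extinction1": (5, 23),
    "extinction2": (24, 33),
    "test2": (34, 34),
    "unsignaled_shock": (35, 35),
    "test3": (36, 36),
}

#: Trials after which a new experimental day begins (1-based).
_DAY_BOUNDARIES = (3, 4, 23, 33, 34, 35)

#: Trials on which the US (foot shock) is delivered (1-based).
US_TRIALS = (1, 2, 3, 35)

#: Test-phase trial indices (1-based): test 1, test 2, test 3.
TEST_TRIALS = (4, 34, 36)

N_TRIALS = 36


@dataclass(frozen=True)
class TrialSchedule:
    """Immutable trial-by-trial description of the paradigm.

    Attributes
    ----------
    times : (n,) float array
        Abstract time τ(t) of each trial, strictly increasing.
    stimuli : (n, 2) float array
        Per-trial stimulus vector x; column 0 is the CS (tone) salience,
        column 1 the context salience.  Non-negative.
    us : (n,) int array
        Binary shock indicator r ∈ {0, 1}.
    phase : (n,) object array
        Phase label of each trial; labels partition the trials contiguously.
    """

    times: np.ndarray
    stimuli: np.ndarray
    us: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        stimuli = np.asarray(self.stimuli, dtype=float)
        us = np.asarray(self.us, dtype=int)
        phase = np.asarray(self.phase, dtype=object)
        n = times.shape[0]
        if stimuli.shape != (n, 2):
            raise ValueError(f"stimuli must have shape ({n}, 2), got {stimuli.shape}")
        if us.shape != (n,) or phase.shape != (n,):
            raise ValueError("times, stimuli, us and phase must have matching length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("trial times must be strictly increasing")
        if np.any(stimuli < 0):
            raise ValueError("stimulus salience values must be non-negative")
        if not np.isin(us, (0, 1)).all():
            raise ValueError("us must be binary")
        # phase labels must partition trials contiguously
        changes = [i for i in range(1, n) if phase[i] != phase[i - 1]]
        if len(set(phase)) != len(changes) + 1:
            raise ValueError("phase labels must be contiguous blocks")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stimuli", stimuli)
        object.__setattr__(self, "us", us)
        object.__setattr__(self, "phase", phase)

    @property
    def n_trials(self) -> int:
        return int(self.times.shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Export as a table with columns trial, time, cs, context, us, phase."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "time": self.times,
                "cs": self.stimuli[:, 0],
                "context": self.stimuli[:, 1],
                "us": self.us,
                "phase": self.phase,
            }
        )


@dataclass(frozen=True)
class CRTrace:
    """A conditioned-response (freezing) trace, one value per trial in [0, 1]."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("CR trace must be one-dimensional")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("CR values must lie in [0, 1]")
        if self.normalized and values.max(initial=0.0) not in (0.0, 1.0):
            # a normalized non-all-zero trace has max exactly 1
            if not np.isclose(values.max(), 1.0):
                raise ValueError("normalized trace must have max 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.shape[0])


def build_reinstatement_schedule(
    phase_gap: float = 20.0,
    intra_gap: float = 1.0,
    context_salience: float = 0.2,
) -> TrialSchedule:
    """Construct the 36-trial reinstatement schedule.

    Parameters
    ----------
    phase_gap : float
        Time units between trials separated by a 24 h day boundary
        (default 20, the model-time equivalent of one day).
    intra_gap : float
        Time units between consecutive trials within the same day.
    context_salience : float
        Constant context salience presented on every trial.

    The CS is present (salience 1) on every trial except the unsignaled
    shock (trial 35); the US is delivered on trials 1-3 and 35.
    """
    if not (phase_gap > intra_gap > 0):
        raise ValueError("require phase_gap > intra_gap > 0")
    if context_salience < 0:
        raise ValueError("context_salience must be non-negative")

    times = np.empty(N_TRIALS)
    times[0] = 0.0
    for t in range(1, N_TRIALS):
        gap = phase_gap if t in _DAY_BOUNDARIES else intra_gap
        times[t] = times[t - 1] + gap

    stimuli = np.column_stack(
        [np.ones(N_TRIALS), np.full(N_TRIALS, float(context_salience))]
    )
    stimuli[34, 0] = 0.0  # trial 35: unsignaled shock, no tone

    us = np.zeros(N_TRIALS, dtype=int)
    us[[t - 1 for t in US_TRIALS]] = 1

    phase = np.empty(N_TRIALS, dtype=object)
    for name, (lo, hi) in _PHASE_TRIALS.items():
        phase[lo - 1 : hi] = name

    return TrialSchedule(times=times, stimuli=stimuli, us=us, phase=phase)


def normalize_trace(trace: CRTrace) -> CRTrace:
    """Divide a CR trace by its maximum over all trials.

    Raises
    ------
    ValueError
        If the trace is all zero (the normalization is undefined).
    """
    peak = trace.values.max(initial=0.0)
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero CR trace")
    return CRTrace(values=trace.values / peak, normalized=True)


def discrimination_index(cr_t: float, cr_tprime: float) -> float:
    """Discrimination index DI = CR(t) / [CR(t) + CR(t')].

    0.5 means identical responding in the two phases; values above 0.5 mean
    a stronger response in phase t.  Undefined (raises) when both responses
    are zero.
    """
    if cr_t < 0 or cr_tprime < 0:
        raise ValueError("conditioned responses must be non-negative")
    total = cr_t + cr_tprime
    if total == 0:
        raise ValueError("DI undefined when both responses are zero")
    return float(cr_t) / float(total)


def read_traces_csv(path) -> pd.DataFrame:
    """Read per-animal CR traces from CSV (long or wide format).

    Long format has columns ``animal_id, group, trial, cr``; wide format has
    ``animal_id, group, cr_001 .. cr_NNN``.  Returns a long-format frame
    sorted by animal and trial.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"animal_id", "group", "trial", "cr"} <= cols:
        long = df[["animal_id", "group", "trial", "cr"]].copy()
    elif {"animal_id", "group"} <= cols:
        cr_cols = sorted(c for c in df.columns if c.startswith("cr_"))
        if not cr_cols:
            raise ValueError("trace CSV has neither long nor wide trace columns")
        long = df.melt(
            id_vars=["animal_id", "group"],
            value_vars=cr_cols,
            var_name="trial",
            value_name="cr",
        )
        long["trial"] = long["trial"].str.removeprefix("cr_").astype(int)
    else:
        raise ValueError("trace CSV must contain animal_id and group columns")
    long["trial"] = long["trial"].astype(int)
    long["cr"] = long["cr"].astype(float)
    return long.sort_values(["animal_id", "trial"], kind="stable").reset_index(drop=True)


def write_traces_csv(df: pd.DataFrame, path) -> None:
    """Write a long-format trace table (animal_id, group, trial, cr) to CSV."""
    df[["animal_id", "group", "trial", "cr"]].to_csv(path, index=False)
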