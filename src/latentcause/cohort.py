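"""Synthetic cohorts of simulated animals with known ground truth.

Each group (genotype × age) is defined by a centre parameter set — defaults
are the group-level estimates of the four experimental groups (6- and
12-month-old control and App knock-in mice) — a multiplicative log-normal
jitter spreading animals around the centre, and additive truncated Gaussian
observation noise on the conditioned response.  Traces are max-normalized
exactly like observed freezing traces, and the true parameters are always
recorded alongside so parameter-recovery experiments lose no information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import DEFAULT_BOUNDS
from .lcm import INTEGER_PARAMS, PARAM_NAMES, ParamSet, simulate_paradigm
from .paradigm import CRTrace, TrialSchedule, normalize_trace

__all__ = [
    "GROUP_CENTERS",
    "GroupSpec",
    "CohortTable",
    "default_group_specs",
    "generate_trace",
    "generate_cohort",
]

#: Group-level parameter estimates of the four experimental groups.
GROUP_CENTERS: dict[str, ParamSet] = {
    "6mo_control": ParamSet(2.4, 0.05, 0.42, 2, 0.009, 2.90, 0.49, 0.008, 0.018, 10),
    "6mo_appnlgf": ParamSet(1.1, 0.61, 0.51, 2, 0.004, 1.51, 0.32, 0.015, 0.019, 30),
    "12mo_control": ParamSet(1.1, 0.92, 0.82, 5, 0.009, 1.88, 0.51, 0.010, 0.017, 4),
    "12mo_appnlgf": ParamSet(1.0, 1.10, 0.04, 2, 0.0025, 1.51, 0.18, 0.011, 0.011, 36),
}

#: Number of animals with accepted fits per experimental group.
GROUP_SIZES = {"6mo_control": 15, "6mo_appnlgf": 12, "12mo_control": 20, "12mo_appnlgf": 18}


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic group: centre parameters, spread, size and noise."""

    name: str
    center: ParamSet
    n_animals: int
    jitter: float = 0.1  # multiplicative log-normal spread per parameter
    noise_sd: float = 0.05  # additive CR observation noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValueError("n_animals must be non-negative")
        if self.jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise_sd must be non-negative")


def default_group_specs(
    n_animals: dict | int | None = None, jitter: float = 0.1, noise_sd: float = 0.05
) -> list[GroupSpec]:
    """The four experimental groups at their reported centres and sizes."""
    specs = []
    for i, (name, center) in enumerate(GROUP_CENTERS.items()):
        if n_animals is None:
            n = GROUP_SIZES[name]
        elif isinstance(n_animals, dict):
            n = n_animals[name]
        else:
            n = int(n_animals)
        specs.append(
            GroupSpec(name=name, center=center, n_animals=n, jitter=jitter,
                      noise_sd=noise_sd, seed=i)
        )
    return specs


@dataclass
class CohortTable:
    """Animals × {labels, ground truth, traces} (fitted columns added later).

    ``animals`` has one row per animal with ``true_<param>`` columns;
    ``traces`` is the long-format trace table (animal_id, group, trial, cr).
    """

    animals: pd.DataFrame
    traces: pd.DataFrame

    def trace_of(self, animal_id: str) -> CRTrace:
        sub = self.traces[self.traces.animal_id == animal_id].sort_values("trial")
        if sub.empty:
            raise KeyError(animal_id)
        return CRTrace(values=sub.cr.to_numpy(), normalized=True)

    def true_params_of(self, animal_id: str) -> ParamSet:
        row = self.animals.set_index("animal_id").loc[animal_id]
        return ParamSet(**{n: row[f"true_{n}"] for n in PARAM_NAMES})


def generate_trace(
    params: ParamSet, schedule: TrialSchedule, noise_sd: float, seed: int
) -> CRTrace:
    """Simulate a CR trace, add observation noise, clip to [0,1], max-normalize."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sim = simulate_paradigm(params, schedule)
    rng = np.random.default_rng(seed)
    noisy = sim.cr.values + rng.normal(0.0, noise_sd, size=schedule.n_trials)
    return normalize_trace(CRTrace(values=np.clip(noisy, 0.0, 1.0)))


def _jitter_params(center: ParamSet, jitter: float, rng: np.random.Generator) -> ParamSet:
    vec = center.to_vector()
    if jitter > 0:
        vec = vec * rng.lognormal(mean=0.0, sigma=jitter, size=vec.shape)
    values = {}
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = DEFAULT_BOUNDS[name]
        v = float(np.clip(vec[i], lo, hi))
        if name in INTEGER_PARAMS:
            v = max(1, int(np.ceil(v - 1e-12)))
        values[name] = v
    return ParamSet(**values)


def generate_cohort(
    specs: list[GroupSpec], schedule: TrialSchedule, seed: int = 0
) -> CohortTable:
    """Draw per-animal parameter sets and traces for every group.

    Per-animal parameters are the group centre times a multiplicative
    log-normal jitter, clipped to the estimation bounds (integer parameters
    re-rounded).  Fully reproducible from (specs, seed).
    """
    if not specs:
        raise ValueError("need at least one group spec")
    animal_rows = []
    trace_rows = []
    for spec in specs:
        rng = np.random.default_rng(np.random.SeedSequence([seed, spec.seed]))
        for i in range(spec.n_animals):
            animal_id = f"{spec.name}_{i + 1:03d}"
            params = _jitter_params(spec.center, spec.jitter, rng)
            trace_seed = int(rng.integers(0, 2**31 - 1))
            trace = generate_trace(params, schedule, spec.noise_sd, trace_seed)
            row = {"animal_id": animal_id, "group": spec.name}
            row.update({f"true_{n}": getattr(params, n) for n in PARAM_NAMES})
            animal_rows.append(row)
            for t, cr in enumerate(trace.values, start=1):
                trace_rows.append(
                    {"animal_id": animal_id, "group": spec.name, "trial": t, "cr": cr}
                )
    return CohortTable(
        animals=pd.DataFrame(animal_rows),
        traces=pd.DataFrame(trace_rows),
    )
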