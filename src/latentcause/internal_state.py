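"""Post-fit characterization of an agent's internal state.

Latent causes are categorized by the phase in which they were first
inferred — during acquisition (trials 1–3), during the extinction block
(test 1 through test 2, trials 4–34), or after extinction (the unsignaled
shock and test 3, trials 35–36) — and each category is summarized by its
cause count, the summed posterior probability at a test trial, and the
summed associative weights at test 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lcm import SimulationResult

__all__ = ["CATEGORIES", "InternalStateSummary", "categorize_causes", "summarize_internal_state"]

CATEGORIES = ("acquisition", "extinction_block", "post_extinction")

_CATEGORY_RANGES = {
    "acquisition": (1, 3),
    "extinction_block": (4, 34),
    "post_extinction": (35, 36),
}


def _category_of_trial(trial: int) -> str:
    for name, (lo, hi) in _CATEGORY_RANGES.items():
        if lo <= trial <= hi:
            return name
    raise ValueError(f"trial {trial} outside the 36-trial paradigm")


@dataclass(frozen=True)
class InternalStateSummary:
    """Per-category internal-state statistics plus the total cause count.

    ``posterior_sum`` holds, per category, the summed posterior probability
    of its causes at the evaluation trial; the three values sum to 1.
    ``w_cs_sum`` / ``w_context_sum`` are summed associative weights at
    test 3 over the category's causes.
    """

    n_causes: dict
    posterior_sum: dict
    w_cs_sum: dict
    w_context_sum: dict
    k_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "n_causes": [self.n_causes[c] for c in CATEGORIES],
                "posterior_sum": [self.posterior_sum[c] for c in CATEGORIES],
                "w_cs_sum": [self.w_cs_sum[c] for c in CATEGORIES],
                "w_context_sum": [self.w_context_sum[c] for c in CATEGORIES],
                "k_total": self.k_total,
            }
        )


def categorize_causes(result: SimulationResult) -> np.ndarray:
    """Category of each instantiated cause, from its first-inference trial."""
    if result.schedule.n_trials != 36:
        raise ValueError("internal-state categorization expects the 36-trial paradigm")
    cats = []
    for k, trial in enumerate(result.first_inferred_trial):
        if trial < 1:
            warnings.warn(f"cause {k + 1} was never MAP-assigned; excluded")
            cats.append(None)
        else:
            cats.append(_category_of_trial(int(trial)))
    return np.array(cats, dtype=object)


def summarize_internal_state(
    result: SimulationResult, eval_trial: int = 36, stimulus_only: bool = True
) -> InternalStateSummary:
    """Summarize counts, posterior mass and weight mass per cause category.

    The posterior is evaluated at ``eval_trial`` (default test 3, trial 36)
    using the stimulus-only posterior — the response-relevant belief before
    the trial's outcome is observed.  Probability mass sitting on a
    prospective new cause that was not instantiated on that trial is counted
    toward the category containing that trial, so the three categories
    always partition the full probability mass.  Weight sums are taken at
    test 3 (post-trial weights); causes not yet instantiated contribute 0.
    """
    cats = categorize_causes(result)
    post = result.posterior_stim if stimulus_only else result.posterior
    row = post[eval_trial - 1]
    w36 = np.nan_to_num(result.weights[35], nan=0.0)

    n_causes = {c: 0 for c in CATEGORIES}
    posterior_sum = {c: 0.0 for c in CATEGORIES}
    w_cs = {c: 0.0 for c in CATEGORIES}
    w_ctx = {c: 0.0 for c in CATEGORIES}
    for k, cat in enumerate(cats):
        if cat is None:
            continue
        n_causes[cat] += 1
        posterior_sum[cat] += float(row[k])
        w_cs[cat] += float(w36[k, 0])
        w_ctx[cat] += float(w36[k, 1])
    # residual mass on the uninstantiated new-cause slot at the evaluation trial
    posterior_sum[_category_of_trial(eval_trial)] += float(row[-1])
    return InternalStateSummary(
        n_causes=n_causes,
        posterior_sum=posterior_sum,
        w_cs_sum=w_cs,
        w_context_sum=w_ctx,
        k_total=int(sum(n_causes.values())),
    )
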