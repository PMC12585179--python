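import numpy as np
import pytest

from latentcause import ParamSet, build_reinstatement_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_reinstatement_schedule()


@pytest.fixture(scope="session")
def fig_params():
    """Example per-group parameter sets used across tests (reported estimates)."""
    return {
        "wildtype_2mo": ParamSet(2.4, 0.316, 0.64, 9, -0.006, 4.50, 4.39, 0.03, 0.02, 6),
        "6mo_control": ParamSet(2.4, 0.05, 0.42, 2, 0.009, 2.90, 0.49, 0.008, 0.018, 10),
        "6mo_appnlgf": ParamSet(1.1, 0.61, 0.51, 2, 0.004, 1.51, 0.32, 0.015, 0.019, 30),
        "12mo_control": ParamSet(1.1, 0.92, 0.82, 5, 0.009, 1.88, 0.51, 0.010, 0.017, 4),
        "12mo_appnlgf": ParamSet(1.0, 1.10, 0.04, 2, 0.0025, 1.51, 0.18, 0.011, 0.011, 36),
    }


def random_paramsets(n, seed=0):
    """Random valid parameter sets spanning the estimation box."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            ParamSet(
                alpha=rng.uniform(1e-3, 5),
                g=rng.uniform(0, 2),
                eta=rng.uniform(0.01, 1),
                max_em_iter=int(rng.integers(1, 11)),
                w0=rng.uniform(-0.05, 0.05),
                sigma_r2=rng.uniform(0.01, 5),
                sigma_x2=rng.uniform(0.01, 5),
                theta=rng.uniform(0, 0.1),
                lam=rng.uniform(1e-3, 0.05),
                K=int(rng.integers(1, 41)),
            )
        )
    return out
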