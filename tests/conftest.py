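"""Shared fixtures: small simulated cohorts and summary-level instrument sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import phewas_mr as pm


def make_instruments(
    rng: np.random.Generator,
    m: int = 80,
    true_beta: float = 0.1,
    se_exp: float = 0.01,
    se_out: float = 0.008,
    n_exp: int = 50_000,
    n_out: int = 300_000,
    pleiotropy: np.ndarray | None = None,
    positive_gamma: bool = False,
) -> pm.InstrumentSet:
    """Summary-level instrument set with known causal effect.

    True variant-exposure effects are drawn so F-statistics land in the
    tens; optional per-instrument pleiotropic effects are added directly to
    the true variant-outcome effects. ``positive_gamma`` fixes the effect
    orientation (useful when planting a directional pleiotropy intercept).
    """
    signs = 1.0 if positive_gamma else rng.choice([-1.0, 1.0], size=m)
    gamma = rng.uniform(0.045, 0.075, size=m) * signs
    Gamma = true_beta * gamma
    if pleiotropy is not None:
        Gamma = Gamma + pleiotropy
    ge = rng.normal(gamma, se_exp)
    go = rng.normal(Gamma, se_out)
    eaf = rng.uniform(0.1, 0.4, size=m)
    data = pd.DataFrame(
        {
            "variant_id": [f"iv{j:03d}" for j in range(m)],
            "ea": "A",
            "oa": "G",
            "beta_exp": ge,
            "se_exp": se_exp,
            "beta_out": go,
            "se_out": se_out,
            "eaf_exp": eaf,
            "eaf_out": eaf,
            "palindromic": False,
            "f_stat": (ge / se_exp) ** 2,
            "n_exp": n_exp,
            "n_out": n_out,
        }
    )
    return pm.InstrumentSet(data)


@pytest.fixture(scope="session")
def small_cohort() -> pm.CohortDataset:
    """5,000-participant cohort with one causal and one null outcome."""
    cfg = pm.SimulationConfig(
        n_participants=5000,
        n_snps=100,
        n_causal_snps=20,
        outcome_specs=[
            pm.OutcomeSpec("K57", 0.12, causal_beta=0.5),
            pm.OutcomeSpec("E11", 0.10, causal_beta=0.0),
        ],
        seed=11,
    )
    return pm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort20k() -> pm.CohortDataset:
    """20,000-participant cohort used for the sampling-bound checks."""
    cfg = pm.SimulationConfig(
        n_participants=20_000,
        n_snps=120,
        n_causal_snps=25,
        seed=23,
    )
    return pm.simulate_cohort(cfg)
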