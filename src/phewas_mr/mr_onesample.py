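"""One-sample Mendelian randomization by two-stage predictor substitution.

Stage 1 regresses the binary exposure on the standardised polygenic score
plus covariates (logistic); the fitted linear predictor — the log-odds of
exposure — substitutes for the exposure in stage 2, a logistic regression
of the outcome on that predictor plus the same covariates. The stage-2
coefficient is the causal log-odds of outcome per unit log-odds of
exposure and is reported per doubling of exposure odds (x 0.693).

Stage-2 Wald standard errors are reported as-is (no generated-regressor
correction); a seeded bootstrap over participants is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import add_intercept, fit_logistic
from .assoc_scan import design_matrix
from .mr import MREstimate


def _two_stage_beta(
    s: np.ndarray, x: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[float, float]:
    """Return (stage-2 beta, se) for score s, exposure x, outcome y."""
    n = len(y)
    Xc = add_intercept(C, n)
    X1 = np.hstack([Xc, s[:, None]])
    fit1 = fit_logistic(X1, x)
    if not fit1.converged:
        raise ValueError("stage-1 exposure model did not converge")
    eta = X1 @ fit1.beta  # fitted exposure log-odds
    if eta.std() < 1e-12:
        raise ValueError("zero-variance fitted values from stage 1")
    X2 = np.hstack([Xc, eta[:, None]])
    fit2 = fit_logistic(X2, y)
    if not fit2.converged:
        raise ValueError("stage-2 outcome model did not converge")
    return float(fit2.beta[-1]), float(fit2.se[-1])


def two_stage_mr(
    profiles: pd.DataFrame,
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> MREstimate:
    """Two-stage individual-level MR estimate.

    ``profiles`` must carry a scaled_score column aligned with exposure,
    outcome and covariates. With n_boot > 0 the SE is replaced by a seeded
    nonparametric bootstrap over participants.
    """
    ids = profiles.index
    s = profiles["scaled_score"].to_numpy(dtype=float)
    x = exposure.loc[ids].to_numpy(dtype=float)
    y = outcome.loc[ids].to_numpy(dtype=float)
    if outcome.name is not None and covariate_names and outcome.name in covariate_names:
        raise ValueError("outcome may not appear among the covariates")
    C = (
        design_matrix(covariates.loc[ids], covariate_names)
        if covariates is not None
        else np.empty((len(ids), 0))
    )
    beta, se = _two_stage_beta(s, x, y, C)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(ids)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boots[i], _ = _two_stage_beta(s[idx], x[idx], y[idx], C[idx])
            except ValueError:
                boots[i] = np.nan
        se = float(np.nanstd(boots, ddof=1))
    z = beta / se
    return MREstimate(
        "two_stage", beta, se, float(2 * stats.norm.sf(abs(z))), n_instruments=0
    )
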