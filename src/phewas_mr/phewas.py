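"""Phenome-wide scan of the standardised polygenic score.

Each phecode is regressed on the scaled score with covariate adjustment
(age, sex, assessment center, principal components by default); the
family-wise error rate is controlled by Bonferroni over the number of
phecodes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import add_intercept, fit_logistic
from .assoc_scan import design_matrix

Z95 = 1.959963984540054


@dataclass
class PhewasResult:
    phecode: str
    n_case: int
    n_control: int
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


def run_phewas(
    profiles: pd.DataFrame,
    phecode_indicator: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    alpha: float = 0.05,
    exclude_phecodes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Scan every phecode against the scaled score.

    The Bonferroni threshold is alpha / K with K the number of phecodes
    actually tested (zero-case phecodes are skipped with a warning;
    phecodes named in ``exclude_phecodes`` — by default the exposure's own
    code, supplied by the caller — are not tested).
    """
    ids = profiles.index.intersection(phecode_indicator.index)
    s = profiles.loc[ids, "scaled_score"].to_numpy(dtype=float)
    C = (
        design_matrix(covariates.loc[ids], covariate_names)
        if covariates is not None
        else np.empty((len(ids), 0))
    )
    Xc = add_intercept(C, len(ids))
    X = np.hstack([Xc, s[:, None]])

    testable = [c for c in phecode_indicator.columns if c not in exclude_phecodes]
    rows = []
    skipped = []
    for phe in testable:
        y = phecode_indicator.loc[ids, phe].to_numpy(dtype=float)
        n_case = int(y.sum())
        if n_case == 0 or n_case == len(y):
            skipped.append(phe)
            continue
        fit = fit_logistic(X, y)
        if not fit.converged:
            skipped.append(phe)
            continue
        beta, se = fit.beta[-1], fit.se[-1]
        z = beta / se
        rows.append(
            dict(
                phecode=phe,
                n_case=n_case,
                n_control=len(y) - n_case,
                or_per_sd=float(np.exp(beta)),
                ci_low=float(np.exp(beta - Z95 * se)),
                ci_high=float(np.exp(beta + Z95 * se)),
                p=float(2 * stats.norm.sf(abs(z))),
            )
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {len(skipped)} phecode(s) with no usable fit: {skipped[:5]}")
    res = pd.DataFrame(
        rows,
        columns=["phecode", "n_case", "n_control", "or_per_sd", "ci_low", "ci_high", "p"],
    )
    k = len(res)
    threshold = bonferroni_threshold(alpha, k) if k else np.nan
    res["significant"] = res["p"] < threshold
    res.attrs["bonferroni_threshold"] = threshold
    res.attrs["n_tested"] = k
    return res


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise threshold alpha / K."""
    if k <= 0:
        raise ValueError("K must be positive")
    return alpha / k


def confounder_independence(
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    confounders: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of the scaled score with each putative confounder.

    Continuous confounders: OLS slope of confounder on score; binary or
    two-level categorical ones are coded 0/1 first. Flags any confounder
    with p below alpha / n_confounders.
    """
    ids = profiles.index.intersection(covariates.index)
    s = profiles.loc[ids, "scaled_score"].to_numpy(dtype=float)
    rows = []
    for name in confounders:
        if name not in covariates.columns:
            raise KeyError(f"confounder {name!r} not in covariate table")
        v = covariates.loc[ids, name]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(v.unique())
            if len(levels) < 2:
                rows.append(dict(confounder=name, estimate=np.nan, p=np.nan, note="constant"))
                continue
            v = (v == levels[-1]).astype(float)
        v = v.to_numpy(dtype=float)
        if v.std() == 0:
            rows.append(dict(confounder=name, estimate=np.nan, p=np.nan, note="constant"))
            continue
        res = stats.linregress(s, v)
        rows.append(dict(confounder=name, estimate=float(res.slope), p=float(res.pvalue), note=""))
    out = pd.DataFrame(rows, columns=["confounder", "estimate", "p", "note"])
    if len(out):
        thr = alpha / max((out["note"] == "").sum(), 1)
        out["flagged"] = (out["p"] < thr) & (out["note"] == "")
    else:
        out["flagged"] = pd.Series(dtype=bool)
    return out
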