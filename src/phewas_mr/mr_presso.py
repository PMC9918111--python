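"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

The observed global statistic is the weighted residual sum of squares
RSS = sum_j w_j (Gamma_j - beta_{-j} gamma_j)^2 with beta_{-j} the
leave-one-out IVW estimate and w_j = 1/sy_j^2. Its null distribution is
built from parametric draws Gamma*_j ~ N(beta_{-j} gamma_j, sy_j); the
global p-value is the (+1-corrected) exceedance fraction. Per-instrument
outliers are instruments whose observed weighted residual is extreme
against their own simulated residual distribution (two-sided, Bonferroni
over instruments). When outliers are found the IVW estimate is recomputed
without them and a distortion coefficient with a resampling p-value is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import InstrumentSet, ivw


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_instrument_p: np.ndarray  # Bonferroni-adjusted, capped at 1
    outlier_ids: list[str]
    beta_all: float
    beta_outlier_corrected: float = np.nan
    distortion_coefficient: float = np.nan  # percent
    distortion_p: float = np.nan
    n_sim: int = 0
    seed: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def _loo_ivw_beta(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates from ratio estimates b with weights w."""
    sw, swb = w.sum(), (w * b).sum()
    return (swb - w * b) / (sw - w)


def presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global heterogeneity test, outlier detection, distortion assessment."""
    m = len(instruments)
    if m < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    d = instruments.data
    ge = d["beta_exp"].to_numpy()
    go = d["beta_out"].to_numpy()
    sy = d["se_out"].to_numpy()
    w_y = 1.0 / sy**2

    ratios = go / ge
    w_ratio = (ge / sy) ** 2
    beta_loo = _loo_ivw_beta(ratios, w_ratio)
    resid_obs = go - beta_loo * ge
    rss_obs = float(np.sum(w_y * resid_obs**2))

    rng = np.random.default_rng(seed)
    go_sim = rng.normal(beta_loo[None, :] * ge[None, :], sy[None, :], size=(n_sim, m))
    ratios_s = go_sim / ge[None, :]
    sw = w_ratio.sum()
    swb = ratios_s @ w_ratio
    beta_loo_s = (swb[:, None] - w_ratio[None, :] * ratios_s) / (sw - w_ratio[None, :])
    resid_s = go_sim - beta_loo_s * ge[None, :]
    rss_s = np.sum(w_y[None, :] * resid_s**2, axis=1)
    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))

    # per-instrument two-sided empirical p against own simulated residuals
    exceed = np.sum(np.abs(resid_s) >= np.abs(resid_obs)[None, :], axis=0)
    p_raw = (1 + exceed) / (n_sim + 1)
    p_adj = np.minimum(p_raw * m, 1.0)
    out_mask = p_adj < outlier_alpha
    outlier_ids = d["variant_id"].to_numpy()[out_mask].tolist()
    if out_mask.all():
        raise ValueError("no instruments remain: every instrument flagged as outlier")

    beta_all = ivw(instruments, "fixed").beta
    res = PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        per_instrument_p=p_adj,
        outlier_ids=outlier_ids,
        beta_all=beta_all,
        n_sim=n_sim,
        seed=seed,
        residuals=resid_obs,
    )
    if out_mask.any():
        kept = instruments.subset(~out_mask)
        beta_corr = ivw(kept, "fixed").beta
        res.beta_outlier_corrected = beta_corr
        if beta_corr != 0:
            dist = 100.0 * (beta_corr - beta_all) / abs(beta_corr)
        else:
            dist = np.nan
        res.distortion_coefficient = float(dist)
        # resampling p: distortion from random same-size subsets
        k = int(m - out_mask.sum())
        dist_null = np.empty(1000)
        for i in range(1000):
            sub = rng.choice(m, size=k, replace=False)
            b_sub = float(np.sum(w_ratio[sub] * ratios[sub]) / np.sum(w_ratio[sub]))
            dist_null[i] = 100.0 * (b_sub - beta_all) / abs(b_sub) if b_sub != 0 else np.nan
        finite = dist_null[np.isfinite(dist_null)]
        if np.isfinite(dist) and finite.size:
            res.distortion_p = float(
                (1 + np.sum(np.abs(finite) >= abs(dist))) / (finite.size + 1)
            )
    return res
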