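"""LD clumping, polygenic scoring, standardisation and tertile analysis.

Clumping is greedy by ascending p-value: the best remaining variant is
retained and every variant within the window whose squared correlation with
it reaches the threshold is removed. Two presets mirror the two uses of
clumping in the analysis: a permissive one for polygenic-score construction
and a stringent one for instrument selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_scan import design_matrix
from ._glm import add_intercept, fit_logistic

# clumping-and-thresholding presets: (r2 threshold, window kb, p threshold)
PRS_PRESET = {"r2_threshold": 0.1, "window_kb": 250.0, "p_threshold": 0.05}
IV_PRESET = {"r2_threshold": 0.001, "window_kb": 10_000.0, "p_threshold": 1e-5}


class InSampleLD:
    """Pairwise variant r^2 computed from an in-sample dosage matrix."""

    def __init__(self, dosages: pd.DataFrame):
        self._cols = {v: i for i, v in enumerate(dosages.columns)}
        G = dosages.to_numpy(dtype=float)
        self._G = (G - G.mean(axis=0)) / np.where(G.std(axis=0) == 0, 1, G.std(axis=0))
        self._n = G.shape[0]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._cols

    def r2(self, a: str, others: list[str]) -> np.ndarray:
        ia = self._cols[a]
        idx = [self._cols[o] for o in others]
        r = self._G[:, idx].T @ self._G[:, ia] / self._n
        return r**2


def clump(
    summary_stats: pd.DataFrame,
    ld_source: InSampleLD,
    r2_threshold: float = PRS_PRESET["r2_threshold"],
    window_kb: float = PRS_PRESET["window_kb"],
    p_threshold: float = PRS_PRESET["p_threshold"],
) -> list[str]:
    """Greedy p-value clumping; returns the retained variant ids.

    Ties on p are broken by smaller SE then lexicographic id, making the
    output invariant to input row order.
    """
    df = summary_stats.dropna(subset=["p"]).copy()
    df = df[df["p"] < p_threshold]
    absent = [v for v in df["variant_id"] if v not in ld_source]
    if absent:
        import warnings

        warnings.warn(
            f"{len(absent)} variant(s) absent from LD source were excluded "
            f"from clumping (e.g. {absent[0]})"
        )
        df = df[~df["variant_id"].isin(absent)]
    df = df.sort_values(["p", "se", "variant_id"], kind="stable")

    window_bp = window_kb * 1000.0
    retained: list[str] = []
    alive = df[["variant_id", "chrom", "pos"]].reset_index(drop=True)
    alive_mask = np.ones(len(alive), dtype=bool)
    for i in range(len(alive)):
        if not alive_mask[i]:
            continue
        lead = alive.iloc[i]
        retained.append(lead["variant_id"])
        near = (
            alive_mask
            & (alive["chrom"].to_numpy() == lead["chrom"])
            & (np.abs(alive["pos"].to_numpy() - lead["pos"]) <= window_bp)
        )
        near[i] = False
        idx = np.where(near)[0]
        if idx.size:
            r2 = ld_source.r2(lead["variant_id"], alive["variant_id"].iloc[idx].tolist())
            alive_mask[idx[r2 >= r2_threshold]] = False
        alive_mask[i] = False
    return retained


@dataclass
class ScalingConstants:
    mean: float
    sd: float


def score(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    scaling: ScalingConstants | None = None,
) -> tuple[pd.DataFrame, ScalingConstants]:
    """Polygenic score = sum of dosage x beta over the usable weights.

    ``weights`` needs columns (variant_id, beta); variants absent from the
    dosage matrix are skipped with a warning. When ``scaling`` is given
    (e.g. base-sample constants), it is applied to the raw scores instead of
    re-standardising, preserving between-sample mean differences. Returns
    (profiles, scaling) where profiles has raw_score, scaled_score and
    tertile columns.
    """
    w = weights.set_index("variant_id")["beta"]
    usable = [v for v in w.index if v in dosages.columns]
    if not usable:
        raise ValueError("no usable variants: none of the weight variants are present")
    if len(usable) < len(w):
        import warnings

        warnings.warn(f"{len(w) - len(usable)} weight variant(s) missing from dosages; skipped")
    G = dosages[usable].to_numpy(dtype=float)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    raw = G @ w.loc[usable].to_numpy()
    if scaling is None:
        sd = raw.std()
        if sd == 0:
            raise ValueError("zero-variance polygenic score (all weights zero?)")
        scaling = ScalingConstants(mean=float(raw.mean()), sd=float(sd))
    scaled = (raw - scaling.mean) / scaling.sd
    ranks = pd.Series(raw, index=dosages.index).rank(method="first")
    tertile = pd.cut(ranks, bins=3, labels=["low", "middle", "high"])
    profiles = pd.DataFrame(
        {"raw_score": raw, "scaled_score": scaled, "tertile": tertile},
        index=dosages.index,
    )
    return profiles, scaling


def tertile_association(
    profiles: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
) -> dict:
    """Logistic OR of the top vs bottom score tertile, covariate adjusted."""
    for t in ("low", "high"):
        if (profiles["tertile"] == t).sum() == 0:
            raise ValueError(f"empty tertile {t!r}")
    sel = profiles["tertile"].isin(["low", "high"])
    ids = profiles.index[sel]
    x = (profiles.loc[ids, "tertile"] == "high").to_numpy(dtype=float)
    y = outcome.loc[ids].to_numpy(dtype=float)
    C = (
        design_matrix(covariates.loc[ids], covariate_names)
        if covariates is not None
        else np.empty((len(ids), 0))
    )
    X = np.hstack([add_intercept(C, len(ids)), x[:, None]])
    fit = fit_logistic(X, y)
    if not fit.converged:
        raise ValueError("tertile association model did not converge")
    beta, se = fit.beta[-1], fit.se[-1]
    z = beta / se
    return {
        "or_high_vs_low": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "beta": float(beta),
        "se": float(se),
        "p": float(2 * stats.norm.sf(abs(z))),
        "n_high": int((profiles["tertile"] == "high").sum()),
        "n_low": int((profiles["tertile"] == "low").sum()),
    }


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", float_format="%.10g")


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "variant" in df.columns:
        df = df.rename(columns={"variant": "variant_id"})
    return df
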