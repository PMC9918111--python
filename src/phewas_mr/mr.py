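"""Two-sample Mendelian randomization: harmonization, estimators, sensitivity.

Operates purely on summary statistics. Per instrument j the harmonized set
carries the variant-exposure effect gamma_j (se sx_j) and variant-outcome
effect Gamma_j (se sy_j), both expressed per copy of the same effect
allele. Estimators:

* Wald ratio          beta_j = Gamma_j / gamma_j, se_j = sy_j / |gamma_j|
* IVW                 inverse-variance weighted mean of the Wald ratios;
                      fixed-effect or multiplicative random effects (SE
                      inflated by max(1, sqrt(Q/(m-1))))
* MR-Egger            WLS of Gamma on gamma with free intercept, weights
                      1/sy^2, instruments oriented so gamma >= 0; a nonzero
                      intercept indicates directional pleiotropy
* weighted median     consistent when <50% of weight is invalid
* weighted mode       mode of the weighted kernel density of ratios
* Cochran's Q         heterogeneity of the per-instrument ratios
* Steiger             directionality from variance explained in each trait
* leave-one-out       influence of single instruments
* pleiotropy pruning  drop instruments associated with secondary traits

Causal estimates are log-odds of outcome per unit log-odds of exposure and
are additionally reported per doubling of exposure odds (beta x 0.693).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prs import IV_PRESET, InSampleLD, clump

Z95 = 1.959963984540054
# literal per-doubling scaling constant (set to np.log(2) for the exact value)
DOUBLING_CONSTANT = 0.693

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
INTERMEDIATE_BAND = (0.42, 0.58)


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(str(ea).upper()) == str(oa).upper()


@dataclass
class InstrumentSet:
    """Harmonized per-instrument effects, all on the exposure effect allele."""

    data: pd.DataFrame  # variant_id, beta_exp, se_exp, beta_out, se_out,
    #                     eaf_exp, eaf_out, palindromic, f_stat, n_exp, n_out
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "InstrumentSet":
        return InstrumentSet(self.data.loc[mask].reset_index(drop=True), self.exclusions)

    @property
    def ratios(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy() / self.data["beta_exp"].to_numpy()

    @property
    def ratio_se(self) -> np.ndarray:
        return self.data["se_out"].to_numpy() / np.abs(self.data["beta_exp"].to_numpy())


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_instruments: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    or_per_doubling: float = np.nan
    or_ci_low: float = np.nan
    or_ci_high: float = np.nan
    q: float = np.nan
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
            self.ci_high = self.beta + Z95 * self.se
        self.or_per_doubling = float(np.exp(DOUBLING_CONSTANT * self.beta))
        self.or_ci_low = float(np.exp(DOUBLING_CONSTANT * self.ci_low))
        self.or_ci_high = float(np.exp(DOUBLING_CONSTANT * self.ci_high))

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_instruments,
            "beta": self.beta,
            "se": self.se,
            "or_per_doubling": self.or_per_doubling,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "p": self.p,
            "q": self.q,
            "q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    intermediate_band: tuple[float, float] = INTERMEDIATE_BAND,
    strict_eaf_exclusion: bool = False,
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele per variant.

    Rules per shared variant: identical allele pair -> keep as is; swapped
    alleles -> flip the outcome beta sign and complement its EAF; a strand
    flip (A<->T, C<->G relabelling) is tolerated, possibly combined with a
    swap; anything else is dropped with reason "incompatible alleles".
    Palindromic variants (A/T or C/G) whose exposure EAF falls inside
    ``intermediate_band`` (inclusive) are excluded as unresolvable; with
    ``strict_eaf_exclusion`` the band applies to every variant. Palindromic
    variants outside the band are aligned by allele frequency.
    """
    lo, hi = intermediate_band
    exp = exposure_stats.set_index("variant_id")
    out = outcome_stats.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    rows, dropped = [], []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        e_ea, e_oa = str(e["ea"]).upper(), str(e["oa"]).upper()
        o_ea, o_oa = str(o["ea"]).upper(), str(o["oa"]).upper()
        pal = is_palindromic(e_ea, e_oa)
        eaf_exp = float(e["eaf"]) if "eaf" in e else np.nan
        eaf_out = float(o["eaf"]) if "eaf" in o else np.nan

        if strict_eaf_exclusion and np.isfinite(eaf_exp) and lo <= eaf_exp <= hi:
            dropped.append((vid, "intermediate allele frequency"))
            continue
        if pal:
            if np.isfinite(eaf_exp) and lo <= eaf_exp <= hi:
                dropped.append((vid, "palindromic with intermediate allele frequency"))
                continue
            # strand is ambiguous: align by frequency side
            flip = (
                np.isfinite(eaf_exp)
                and np.isfinite(eaf_out)
                and (eaf_exp - 0.5) * (eaf_out - 0.5) < 0
            )
        else:
            c_ea, c_oa = COMPLEMENT.get(o_ea, "?"), COMPLEMENT.get(o_oa, "?")
            if (o_ea, o_oa) == (e_ea, e_oa) or (c_ea, c_oa) == (e_ea, e_oa):
                flip = False
            elif (o_oa, o_ea) == (e_ea, e_oa) or (c_oa, c_ea) == (e_ea, e_oa):
                flip = True
            else:
                dropped.append((vid, "incompatible alleles"))
                continue
        beta_out = -float(o["beta"]) if flip else float(o["beta"])
        eaf_o = 1 - eaf_out if flip else eaf_out
        be, se_e = float(e["beta"]), float(e["se"])
        f = (be / se_e) ** 2 if se_e > 0 else np.nan
        rows.append(
            dict(
                variant_id=vid, ea=e_ea, oa=e_oa,
                beta_exp=be, se_exp=se_e,
                beta_out=beta_out, se_out=float(o["se"]),
                eaf_exp=eaf_exp, eaf_out=eaf_o,
                palindromic=pal, f_stat=f,
                n_exp=int(e["n"]) if "n" in e and np.isfinite(e["n"]) else -1,
                n_out=int(o["n"]) if "n" in o and np.isfinite(o["n"]) else -1,
            )
        )
    data = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "ea", "oa", "beta_exp", "se_exp", "beta_out",
            "se_out", "eaf_exp", "eaf_out", "palindromic", "f_stat",
            "n_exp", "n_out",
        ],
    )
    excl = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return InstrumentSet(data, excl)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for zero variant-exposure effect")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    z = beta / se
    return MREstimate("wald", float(beta), float(se),
                      float(2 * stats.norm.sf(abs(z))), 1)


def cochran_q(instruments: InstrumentSet, beta_ref: float) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios about beta_ref; df = m - 1."""
    if len(instruments) < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    b = instruments.ratios
    w = 1.0 / instruments.ratio_se**2
    q = float(np.sum(w * (b - beta_ref) ** 2))
    df = len(b) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(instruments: InstrumentSet, mode: str = "fixed") -> MREstimate:
    """Inverse-variance weighted meta-analysis of the Wald ratios."""
    m = len(instruments)
    if m == 0:
        raise ValueError("no instruments")
    b = instruments.ratios
    w = 1.0 / instruments.ratio_se**2
    if not np.any(np.isfinite(w)):
        raise ValueError("all IVW weights are non-finite")
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = q_p = np.nan
    if m >= 2:
        q, df, q_p = cochran_q(instruments, beta)
        if mode == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / df))
        elif mode != "fixed":
            raise ValueError(f"unknown IVW mode {mode!r}")
    z = beta / se
    est = MREstimate(f"ivw_{'fe' if mode == 'fixed' else 'mre'}", beta, se,
                     float(2 * stats.norm.sf(abs(z))), m)
    est.q, est.q_p = q, q_p
    return est


def ivw_auto(instruments: InstrumentSet, het_alpha: float = 0.05) -> MREstimate:
    """IVW defaulting to multiplicative random effects under heterogeneity."""
    fe = ivw(instruments, "fixed")
    if len(instruments) >= 2 and np.isfinite(fe.q_p) and fe.q_p < het_alpha:
        return ivw(instruments, "multiplicative_random")
    return fe


def egger(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger: WLS of Gamma on gamma with intercept, weights 1/sy^2.

    Instruments are re-oriented so every variant-exposure effect is
    non-negative (the estimate is not invariant to allele orientation;
    this is the standard convention).
    """
    m = len(instruments)
    if m < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    sign = np.sign(instruments.data["beta_exp"].to_numpy())
    sign[sign == 0] = 1.0
    x = instruments.data["beta_exp"].to_numpy() * sign
    y = instruments.data["beta_out"].to_numpy() * sign
    w = 1.0 / instruments.data["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones(m), x])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ coef
    dof = m - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else np.nan
    cov = np.linalg.inv(XtWX) * max(sigma2, 1.0)  # MRE: never deflate below 1
    se_int, se_slope = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    est = MREstimate(
        "egger", float(coef[1]), float(se_slope),
        float(2 * stats.t.sf(abs(t_slope), dof)), m,
    )
    est.egger_intercept = float(coef[0])
    est.egger_intercept_p = float(2 * stats.t.sf(abs(t_int), dof))
    q, df, q_p = cochran_q(instruments, float(coef[1]))
    est.q, est.q_p = q, q_p
    return est


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b, w = b[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, b))


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the Wald ratios (weights 1/se^2), bootstrap SE."""
    m = len(instruments)
    if m < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable bootstrap standard errors")
    b = instruments.ratios
    w = 1.0 / instruments.ratio_se**2
    beta = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    ge = instruments.data["beta_exp"].to_numpy()
    se_e = instruments.data["se_exp"].to_numpy()
    go = instruments.data["beta_out"].to_numpy()
    se_o = instruments.data["se_out"].to_numpy()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ge_s = rng.normal(ge, se_e)
        go_s = rng.normal(go, se_o)
        ge_s[ge_s == 0] = 1e-12
        bs = go_s / ge_s
        ws = (np.abs(ge_s) / se_o) ** 2
        boots[i] = _weighted_median_point(bs, ws)
    se = float(boots.std(ddof=1))
    z = beta / se
    return MREstimate("weighted_median", beta, se,
                      float(2 * stats.norm.sf(abs(z))), m)


def _weighted_mode_point(b: np.ndarray, w: np.ndarray, bandwidth: float) -> float:
    grid = np.linspace(b.min() - 3 * bandwidth, b.max() + 3 * bandwidth, 2048)
    dens = np.zeros_like(grid)
    wn = w / w.sum()
    for bi, wi in zip(b, wn):
        dens += wi * np.exp(-0.5 * ((grid - bi) / bandwidth) ** 2)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    instruments: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the weighted kernel density of Wald ratios, bootstrap SE.

    Bandwidth = bandwidth_factor x weighted analogue of Silverman's rule
    (0.9 min(sd, iqr/1.34) m^-1/5 on the ratio distribution).
    """
    m = len(instruments)
    if m < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    b = instruments.ratios
    w = 1.0 / instruments.ratio_se**2

    def bw(bv: np.ndarray) -> float:
        s = np.std(bv, ddof=1)
        iqr = np.subtract(*np.percentile(bv, [75, 25]))
        spread = min(s, iqr / 1.34) if iqr > 0 else s
        h = bandwidth_factor * 0.9 * spread * len(bv) ** (-1 / 5)
        if h <= 0:
            if np.allclose(bv, bv[0]):
                return np.nan  # point mass: mode is the common value
            raise ValueError("zero kernel bandwidth")
        return h

    h = bw(b)
    beta = float(b[0]) if np.isnan(h) else _weighted_mode_point(b, w, h)
    rng = np.random.default_rng(seed)
    ge = instruments.data["beta_exp"].to_numpy()
    se_e = instruments.data["se_exp"].to_numpy()
    go = instruments.data["beta_out"].to_numpy()
    se_o = instruments.data["se_out"].to_numpy()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ge_s = rng.normal(ge, se_e)
        go_s = rng.normal(go, se_o)
        ge_s[ge_s == 0] = 1e-12
        bs = go_s / ge_s
        ws = (np.abs(ge_s) / se_o) ** 2
        hs = bw(bs)
        boots[i] = bs[0] if np.isnan(hs) else _weighted_mode_point(bs, ws, hs)
    se = float(boots.std(ddof=1))
    if se == 0:
        se = 1e-12
    z = beta / se
    return MREstimate("weighted_mode", beta, se,
                      float(2 * stats.norm.sf(abs(z))), m)


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------


def steiger(instruments: InstrumentSet) -> tuple[bool, float]:
    """Directionality test: does the instrument set explain more variance in
    the exposure than in the outcome?

    For binary traits the per-instrument variance explained is approximated
    from the association Z statistic and sample size as r^2 = Z^2/(Z^2+n).
    The p-value is a two-sided z-test on the difference of the Fisher-
    transformed aggregate correlations.
    """
    d = instruments.data
    if (d["n_exp"] < 0).any() or (d["n_out"] < 0).any():
        raise ValueError("Steiger test needs sample sizes for both traits")
    zx = d["beta_exp"] / d["se_exp"]
    zy = d["beta_out"] / d["se_out"]
    r2x = (zx**2 / (zx**2 + d["n_exp"])).sum()
    r2y = (zy**2 / (zy**2 + d["n_out"])).sum()
    r2x, r2y = float(min(r2x, 0.999)), float(min(r2y, 0.999))
    nx = int(d["n_exp"].min())
    ny = int(d["n_out"].min())
    zdiff = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / np.sqrt(
        1 / (nx - 3) + 1 / (ny - 3)
    )
    p = float(2 * stats.norm.sf(abs(zdiff)))
    return bool(r2x > r2y), p


def leave_one_out(instruments: InstrumentSet, estimator=ivw_auto) -> pd.DataFrame:
    """Re-estimate leaving each instrument out in turn.

    Flags rows whose CI excludes the sign of the full-set point estimate.
    """
    m = len(instruments)
    if m < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full = estimator(instruments)
    rows = []
    for i in range(m):
        mask = np.ones(m, dtype=bool)
        mask[i] = False
        est = estimator(instruments.subset(mask))
        sign_flip = (full.beta > 0 and est.ci_high < 0) or (full.beta < 0 and est.ci_low > 0)
        rows.append(
            dict(
                left_out=instruments.data["variant_id"].iloc[i],
                beta=est.beta, se=est.se,
                ci_low=est.ci_low, ci_high=est.ci_high, p=est.p,
                sign_conflict=sign_flip,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["full_beta"] = full.beta
    return out


def prune_pleiotropic(
    instruments: InstrumentSet,
    secondary_stats: pd.DataFrame,
    p_threshold: float = 0.05 / 665,
) -> tuple[InstrumentSet, pd.DataFrame]:
    """Drop instruments associated with secondary traits below p_threshold.

    ``secondary_stats`` needs columns (variant_id, p); the removal log
    records each removed variant's secondary p-value.
    """
    sec = secondary_stats.set_index("variant_id")["p"]
    d = instruments.data
    sec_p = d["variant_id"].map(sec)
    remove = sec_p.notna() & (sec_p < p_threshold)
    log = pd.DataFrame(
        {"variant_id": d.loc[remove, "variant_id"], "secondary_p": sec_p[remove]}
    ).reset_index(drop=True)
    kept = instruments.subset(~remove.to_numpy())
    return kept, log


def select_instruments(
    exposure_stats: pd.DataFrame,
    ld_source: InSampleLD,
    p_threshold: float = IV_PRESET["p_threshold"],
    r2_threshold: float = IV_PRESET["r2_threshold"],
    window_kb: float = IV_PRESET["window_kb"],
) -> pd.DataFrame:
    """Instrument selection: p-value cut plus stringent LD clumping.

    Returns the selected rows of ``exposure_stats`` with an ``f_stat``
    column (gamma^2 / se^2); warns when any instrument has F < 10.
    """
    keep = clump(exposure_stats, ld_source, r2_threshold, window_kb, p_threshold)
    if not keep:
        raise ValueError("no instruments pass the selection thresholds")
    sel = exposure_stats[exposure_stats["variant_id"].isin(keep)].copy()
    sel["f_stat"] = (sel["beta"] / sel["se"]) ** 2
    if (sel["f_stat"] < 10).any():
        import warnings

        weak = int((sel["f_stat"] < 10).sum())
        warnings.warn(f"{weak} instrument(s) have F < 10 (weak-instrument risk)")
    return sel.reset_index(drop=True)


def mr_suite(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every applicable estimator; one row per method."""
    m = len(instruments)
    rows = []
    if m == 1:
        d = instruments.data.iloc[0]
        rows.append(wald_ratio(d["beta_exp"], d["se_exp"], d["beta_out"], d["se_out"]).to_row())
    if m >= 2:
        rows.append(ivw(instruments, "fixed").to_row())
        rows.append(ivw(instruments, "multiplicative_random").to_row())
    if m >= 3:
        rows.append(egger(instruments).to_row())
        rows.append(weighted_median(instruments, n_boot, seed).to_row())
        rows.append(weighted_mode(instruments, 1.0, n_boot, seed + 1).to_row())
    return pd.DataFrame(rows)
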