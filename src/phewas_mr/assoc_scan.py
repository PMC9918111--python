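"""Per-variant association testing and descriptive contingency tests.

The genome-wide scan fits one covariate-adjusted logistic regression per
variant (Wald tests; IRLS with a warm start from the covariate-only fit).
Synthetic cohorts are unrelated by construction, so no mixed-model
relatedness correction is applied. ``split_sample`` produces the disjoint
base/target halves used to avoid base-target sample overlap between the
variant-effect estimation and the scoring/scanning stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import add_intercept, fit_logistic

DEFAULT_GWAS_COVARIATES = ("age", "sex") + tuple(f"pc{i}" for i in range(1, 11))


@dataclass
class SummaryStatRecord:
    """One variant's association result (effect-allele dosage coding)."""

    variant_id: str
    chrom: int
    pos: int
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    n_cases: int
    status: str = "ok"  # ok | monomorphic | non_converged


SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "ea", "oa", "eaf",
    "beta", "se", "p", "n", "n_cases", "status",
]


def design_matrix(covariates: pd.DataFrame, names: list[str] | None = None) -> np.ndarray:
    """Numeric design block from a covariate table.

    sex is coded female=0/male=1; categorical columns (e.g. assessment
    center) are expanded to treatment-coded dummies.
    """
    if names is None:
        names = list(covariates.columns)
    cols = []
    for name in names:
        s = covariates[name]
        if name == "sex" or s.dtype == bool:
            cols.append(s.map({"female": 0.0, "male": 1.0}).to_numpy()
                        if s.dtype == object else s.astype(float).to_numpy())
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            cols.append(s.astype(float).to_numpy())
    if not cols:
        return np.empty((len(covariates), 0))
    return np.column_stack(cols)


def gwas_scan(
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted logistic scan of a binary trait over all variants.

    Returns a summary-statistics DataFrame (one row per variant). Wald
    p-values; monomorphic variants are emitted with status "monomorphic"
    and NA effect fields, separation/non-convergence with status
    "non_converged".
    """
    y = trait.loc[dosages.index].to_numpy(dtype=float)
    n = len(y)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == n:
        raise ValueError("trait needs at least one case and one control")

    if covariates is not None:
        C = design_matrix(covariates.loc[dosages.index], covariate_names)
    else:
        C = np.empty((n, 0))
    Xc = add_intercept(C, n)
    base = fit_logistic(Xc, y)
    if not base.converged:
        raise ValueError("covariate-only model did not converge (collinear covariates?)")

    vmeta = variants.set_index("id")
    G = dosages.to_numpy(dtype=float)
    rows = []
    p_cov = Xc.shape[1]
    X = np.hstack([Xc, np.zeros((n, 1))])
    warm = np.append(base.beta, 0.0)
    for j, vid in enumerate(dosages.columns):
        g = G[:, j]
        meta = vmeta.loc[vid]
        eaf = float(g.mean() / 2.0)
        rec = dict(
            variant_id=vid, chrom=int(meta["chrom"]), pos=int(meta["pos"]),
            ea=meta["ea"], oa=meta["oa"], eaf=eaf,
            beta=np.nan, se=np.nan, p=np.nan, n=n, n_cases=n_cases, status="ok",
        )
        if g.std() == 0.0:
            rec["status"] = "monomorphic"
            rows.append(rec)
            continue
        X[:, p_cov] = g
        fit = fit_logistic(X, y, start=warm)
        if not fit.converged:
            rec["status"] = "non_converged"
            rows.append(rec)
            continue
        beta, se = fit.beta[p_cov], fit.se[p_cov]
        z = beta / se
        rec.update(beta=float(beta), se=float(se),
                   p=float(2 * stats.norm.sf(abs(z))))
        rows.append(rec)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def split_sample(
    participant_ids: pd.Index,
    ratio: float,
    seed: int,
    trait: pd.Series | None = None,
) -> tuple[pd.Index, pd.Index, dict]:
    """Random disjoint, exhaustive base/target partition.

    Returns (base_ids, target_ids, counts) where counts reports the
    case/control split of each half when a trait is supplied.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0,1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(participant_ids))
    n_base = int(round(len(participant_ids) * ratio))
    base = participant_ids[np.sort(perm[:n_base])]
    target = participant_ids[np.sort(perm[n_base:])]
    counts: dict = {"n_base": len(base), "n_target": len(target)}
    if trait is not None:
        counts["base_cases"] = int(trait.loc[base].sum())
        counts["base_controls"] = len(base) - counts["base_cases"]
        counts["target_cases"] = int(trait.loc[target].sum())
        counts["target_controls"] = len(target) - counts["target_cases"]
    return base, target, counts


def contingency_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row/column")
    res = stats.chi2_contingency(table, correction=False)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(res.statistic), df, float(res.pvalue)


def load_baseline_counts() -> pd.DataFrame:
    """Bundled baseline characteristics of the 346,352-participant reference
    cohort (counts of exposed/unexposed participants per level), used by the
    worked example and the descriptive chi-square tests."""
    from importlib import resources

    with resources.files("phewas_mr.data").joinpath("cohort_baseline.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_summary_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV; tolerates extra columns and common
    alternative column spellings (SNP/CHR/BP/EA/OA/EAF/BETA/SE/P/N)."""
    df = pd.read_csv(path, sep="\t")
    aliases = {
        "snp": "variant_id", "chr": "chrom", "bp": "pos",
        "effect_allele": "ea", "other_allele": "oa",
        "pval": "p", "p_value": "p",
    }
    df.columns = [aliases.get(c.lower(), c.lower()) for c in df.columns]
    required = {"variant_id", "ea", "oa", "beta", "se", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    return df
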