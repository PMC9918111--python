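"""Synthetic cohort generation under a liability-threshold model.

The simulator produces cohorts with the statistical structure the downstream
analysis assumes: a binary exposure arising from a normal liability
(polygenic component + shared confounder + residual, thresholded at the
quantile matching the target prevalence), binary disease outcomes whose
log-odds couple to the exposure liability, block-structured linkage
disequilibrium, palindromic variants with intermediate allele frequency,
questionnaire/self-report exposure flags, and dated ICD-9/ICD-10 diagnosis
records.

The liability L of participant i is

    L_i = G_i + c * U_i + eps_i,      G_i = sum_k b_k g_ik (standardised)

with Var(G)=h2 (enforced on the realised sample), U a standard-normal
confounder shared with the outcomes, and eps ~ N(0, 1 - h2 - c^2); the
exposure indicator is 1{L_i > tau} with tau = Phi^-1(1 - prevalence).

Each outcome couples to the liability on the exposure's observed log-odds
scale: the liability is multiplied by k = phi(tau) / (K (1-K)) — the usual
liability-to-log-odds conversion at prevalence K — so that an outcome's
``causal_beta`` reads directly as "outcome log-odds per unit exposure
log-odds", the scale on which Wald ratios and the per-doubling transform
operate.  The planted parameters are retained in a truth record so tests
can verify parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

# diagnosis dates are drawn uniformly over this window unless configured
DEFAULT_DATE_WINDOW = ("2000-01-01", "2020-12-31")

# toy ICD-9 -> ICD-10 equivalence mapping used for the small fraction of
# legacy-coded records the simulator emits (a user mapping can replace it)
TOY_ICD9_MAP = {
    "5750": "K810",
    "5640": "K590",
    "5641": "K580",
    "30000": "F410",
    "311": "F329",
    "53081": "K219",
    "5533": "K449",
    "5621": "K573",
    "5301": "K20",
}

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


@dataclass
class OutcomeSpec:
    """One binary disease outcome.

    name is used as the outcome's 3-character ICD-10 stem when diagnosis
    records are emitted, so it should match ``[A-Z][0-9]{2}``.
    causal_beta is the outcome log-odds change per unit exposure log-odds
    (liability scaled by the prevalence-dependent conversion factor);
    pleiotropic_snp_effects maps variant id -> direct effect on the outcome
    log-odds per standardised dosage (horizontal pleiotropy).
    """

    name: str
    baseline_prevalence: float
    causal_beta: float = 0.0
    confounder_beta: float = 0.0
    pleiotropic_snp_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_participants: int = 20_000
    n_snps: int = 200
    ld_block_size: int = 5
    ld_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.1
    frac_palindromic_intermediate: float = 0.5
    n_causal_snps: int = 30
    h2_liability: float = 0.25
    exposure_prevalence: float = 0.115
    confounder_beta_exposure: float = 0.0
    outcome_specs: list[OutcomeSpec] = field(default_factory=list)
    # covariate model
    age_mean: float = 57.0
    age_sd: float = 8.0
    female_fraction: float = 0.5334
    n_centers: int = 5
    n_pcs: int = 10
    # exposure ascertainment flags (probabilities given true exposure)
    p_rome3: float = 0.30
    p_dhq: float = 0.50
    p_self_report: float = 0.40
    p_icd10: float = 0.50
    flag_false_positive: float = 0.0
    exposure_icd10_stem: str = "K58"
    # diagnosis-record plumbing
    n_noise_phecodes: int = 8
    noise_prevalence_range: tuple[float, float] = (0.01, 0.05)
    icd9_fraction: float = 0.05
    exclusion_fraction: float = 0.002
    exclusion_codes: tuple[str, ...] = ("K50", "K51")
    date_window: tuple[str, str] = DEFAULT_DATE_WINDOW
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.exposure_prevalence < 1):
            raise ValueError("exposure_prevalence must lie in (0,1)")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must lie in [0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0,1)")
        if self.h2_liability + self.confounder_beta_exposure**2 >= 1:
            raise ValueError(
                "h2_liability + confounder_beta_exposure^2 must be < 1 "
                "(residual liability variance would be non-positive)"
            )
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps cannot exceed n_snps")
        for spec in self.outcome_specs:
            if not (0 < spec.baseline_prevalence < 1):
                raise ValueError(
                    f"outcome {spec.name!r}: baseline_prevalence must lie in (0,1)"
                )


@dataclass
class CohortDataset:
    """In-memory cohort: genotypes, covariates, flags, diagnoses, phenotypes.

    dosages: participants x variants integer dosage matrix (DataFrame,
    index participant_id). variants: metadata table (id, chrom, pos, ea,
    oa, eaf). phenotypes: derived exposure/outcome indicator table.
    truth: planted-parameter record for test oracles.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    covariates: pd.DataFrame
    flags: pd.DataFrame
    diagnoses: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict

    @property
    def participant_ids(self) -> pd.Index:
        return self.dosages.index

    def check_invariants(self) -> None:
        d = self.dosages.to_numpy()
        if d.min() < 0 or d.max() > 2:
            raise AssertionError("dosages outside [0,2]")
        n = len(self.dosages)
        eaf = self.variants.set_index("id").loc[self.dosages.columns, "eaf"].to_numpy()
        col_eaf = d.mean(axis=0) / 2.0
        se = np.sqrt(np.maximum(eaf * (1 - eaf), 1e-12) / (2 * n))
        if np.any(np.abs(col_eaf - eaf) > 6 * se + 1e-9):
            raise AssertionError("realised EAF inconsistent with metadata")


def liability_to_logodds_factor(prevalence: float) -> float:
    """Conversion factor k = phi(tau)/(K(1-K)) from liability units to the
    observed log-odds scale of a threshold trait with prevalence K."""
    tau = stats.norm.ppf(1 - prevalence)
    return stats.norm.pdf(tau) / (prevalence * (1 - prevalence))


def _simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator):
    """Block-LD dosages from a haplotype-sharing copula.

    Variants in an LD block share one allele frequency; on each haplotype a
    variant's allele is copied from the block's shared latent uniform with
    probability sqrt(ld_rho), giving pairwise dosage correlation ~ ld_rho
    within a block and independence across blocks.
    """
    n, m = cfg.n_participants, cfg.n_snps
    bs = max(1, cfg.ld_block_size)
    n_blocks = (m + bs - 1) // bs
    n_pal = int(round(cfg.frac_palindromic * m))
    pal_mask = np.zeros(m, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(m, size=n_pal, replace=False)] = True

    block_maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_blocks)
    maf = np.repeat(block_maf, bs)[:m]
    # a configurable share of palindromic variants gets intermediate EAF to
    # exercise the harmonisation filter
    inter = pal_mask & (rng.uniform(size=m) < cfg.frac_palindromic_intermediate)
    maf[inter] = rng.uniform(0.42, 0.5, size=inter.sum())

    dosage = np.zeros((n, m), dtype=np.int8)
    share_p = np.sqrt(cfg.ld_rho)
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        width = stop - start
        for _hap in range(2):
            u_shared = rng.uniform(size=n)[:, None]
            u_ind = rng.uniform(size=(n, width))
            use_shared = rng.uniform(size=(n, width)) < share_p
            u = np.where(use_shared, u_shared, u_ind)
            dosage[:, start:stop] += (u < maf[start:stop][None, :]).astype(np.int8)

    alleles = np.empty((m, 2), dtype=object)
    pal_choices = rng.integers(0, len(PALINDROMIC_PAIRS), size=m)
    non_choices = rng.integers(0, len(NON_PALINDROMIC_PAIRS), size=m)
    for j in range(m):
        ea, oa = (
            PALINDROMIC_PAIRS[pal_choices[j]]
            if pal_mask[j]
            else NON_PALINDROMIC_PAIRS[non_choices[j]]
        )
        alleles[j] = (ea, oa)

    n_blocks = (m + bs - 1) // bs
    block_of = np.repeat(np.arange(n_blocks), bs)[:m]
    chrom = (block_of % 22) + 1
    pos = np.zeros(m, dtype=int)
    for c in range(1, 23):
        idx = np.where(chrom == c)[0]
        pos[idx] = 100_000 + 10_000 * np.arange(len(idx))

    variants = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ea": alleles[:, 0],
            "oa": alleles[:, 1],
            "eaf": maf,
            "palindromic": pal_mask,
        }
    )
    return dosage, variants


def _solve_intercept(shift: np.ndarray, target: float, name: str) -> float:
    """Intercept alpha with mean(sigmoid(alpha + shift)) = target."""

    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + shift)))) - target

    lo, hi = -29.0, 29.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"outcome {name!r}: requested prevalence {target} infeasible "
            "(effects saturate the probabilities)"
        )
    alpha = optimize.brentq(f, lo, hi, xtol=1e-12)
    if abs(alpha) > 28:
        raise ValueError(f"outcome {name!r}: intercept at bound; effects saturate")
    return float(alpha)


def _random_dates(rng: np.random.Generator, n: int, window: tuple[str, str]):
    lo = np.datetime64(window[0])
    hi = np.datetime64(window[1])
    span = int((hi - lo) / np.timedelta64(1, "D"))
    offs = rng.integers(0, span + 1, size=n)
    return (lo + offs.astype("timedelta64[D]")).astype(str)


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a cohort according to the liability-threshold model."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    keys = (
        "genotypes", "covariates", "liability", "outcomes",
        "flags", "diagnoses", "exclusions",
    )
    child = {k: np.random.default_rng(s)
             for k, s in zip(keys, master.spawn(len(keys)))}

    dosage, variants = _simulate_genotypes(config, child["genotypes"])
    n, m = dosage.shape
    pids = pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id")

    # --- covariates -------------------------------------------------------
    rngc = child["covariates"]
    age = np.clip(rngc.normal(config.age_mean, config.age_sd, size=n), 40, 70)
    sex = np.where(rngc.uniform(size=n) < config.female_fraction, "female", "male")
    center = rngc.integers(0, config.n_centers, size=n)
    pcs = rngc.standard_normal((n, config.n_pcs))
    covariates = pd.DataFrame(
        {"age": np.round(age, 2), "sex": sex,
         "center": [f"C{c}" for c in center]},
        index=pids,
    )
    for k in range(config.n_pcs):
        covariates[f"pc{k + 1}"] = np.round(pcs[:, k], 6)

    # --- exposure liability ----------------------------------------------
    rngl = child["liability"]
    dstd = (dosage - dosage.mean(axis=0)) / np.maximum(dosage.std(axis=0), 1e-9)
    causal_idx = np.sort(
        rngl.choice(m, size=config.n_causal_snps, replace=False)
    )
    b_raw = rngl.standard_normal(config.n_causal_snps)
    G = dstd[:, causal_idx] @ b_raw
    g_sd = G.std()
    h2 = config.h2_liability
    if h2 > 0 and g_sd > 0:
        scale = np.sqrt(h2) / g_sd
    else:
        scale = 0.0
    G = G * scale
    b_std = b_raw * scale  # liability per standardised dosage
    c = config.confounder_beta_exposure
    U = rngl.standard_normal(n)
    eps_sd = np.sqrt(max(1.0 - h2 - c * c, 0.0))
    L = G + c * U + eps_sd * rngl.standard_normal(n)
    tau = float(stats.norm.ppf(1 - config.exposure_prevalence))
    exposure = (L > tau).astype(np.int8)
    k_factor = liability_to_logodds_factor(config.exposure_prevalence)

    # --- outcomes ---------------------------------------------------------
    rngo = child["outcomes"]
    phen = pd.DataFrame({"exposure": exposure}, index=pids)
    intercepts = {}
    for spec in config.outcome_specs:
        shift = spec.causal_beta * k_factor * L + spec.confounder_beta * U
        for vid, eff in spec.pleiotropic_snp_effects.items():
            j = int(variants.index[variants["id"] == vid][0])
            shift = shift + eff * dstd[:, j]
        alpha = _solve_intercept(shift, spec.baseline_prevalence, spec.name)
        p = 1.0 / (1.0 + np.exp(-(alpha + shift)))
        phen[spec.name] = (rngo.uniform(size=n) < p).astype(np.int8)
        intercepts[spec.name] = alpha

    # --- questionnaire flags ---------------------------------------------
    rngf = child["flags"]
    is_case = exposure.astype(bool)
    fp = config.flag_false_positive

    def flag(p_true):
        pr = np.where(is_case, p_true, fp)
        return rngf.uniform(size=n) < pr

    flags = pd.DataFrame(
        {
            "rome3": flag(config.p_rome3),
            "dhq_yes": flag(config.p_dhq),
            "self_report": flag(config.p_self_report),
        },
        index=pids,
    )

    # --- diagnosis records ------------------------------------------------
    rngd = child["diagnoses"]
    rows: list[tuple[str, str, str, str]] = []

    def add_records(mask: np.ndarray, stem: str):
        idx = np.where(mask)[0]
        if idx.size == 0:
            return
        sub = rngd.integers(0, 10, size=idx.size)
        dates = _random_dates(rngd, idx.size, config.date_window)
        use_icd9 = rngd.uniform(size=idx.size) < config.icd9_fraction
        rev = {v[:3]: k for k, v in TOY_ICD9_MAP.items()}
        for i, s, dt, old in zip(idx, sub, dates, use_icd9):
            code10 = f"{stem}{s}"
            if old and stem in rev:
                rows.append((pids[i], rev[stem], "ICD9", dt))
            else:
                rows.append((pids[i], code10, "ICD10", dt))

    # exposure ICD-10 records among true cases
    icd_mask = is_case & (rngd.uniform(size=n) < config.p_icd10)
    add_records(icd_mask, config.exposure_icd10_stem)
    # outcome records
    for spec in config.outcome_specs:
        add_records(phen[spec.name].to_numpy().astype(bool), spec.name)
    # background noise phecodes spread over permitted chapters
    noise_stems = []
    letters = ["A", "B", "C", "E", "G", "I", "J", "L", "M", "N"]
    for q in range(config.n_noise_phecodes):
        noise_stems.append(f"{letters[q % len(letters)]}{20 + q:02d}")
    lo_p, hi_p = config.noise_prevalence_range
    for stem in noise_stems:
        prev = rngd.uniform(lo_p, hi_p)
        add_records(rngd.uniform(size=n) < prev, stem)
    # planted exclusion conditions
    rnge = child["exclusions"]
    excl_mask = rnge.uniform(size=n) < config.exclusion_fraction
    for code in config.exclusion_codes:
        add_records(excl_mask & (rnge.uniform(size=n) < 0.7), code)

    diagnoses = pd.DataFrame(
        rows, columns=["participant_id", "code", "system", "date"]
    ).sort_values(["participant_id", "date", "code"], kind="stable").reset_index(drop=True)

    truth = {
        "causal_snp_ids": [variants["id"].iloc[j] for j in causal_idx],
        "liability_beta_per_std_dosage": [float(b) for b in b_std],
        "h2_liability": h2,
        "tau": tau,
        "liability_to_logodds": float(k_factor),
        "confounder_beta_exposure": c,
        "outcome_intercepts": intercepts,
        "outcome_specs": [
            {
                "name": s.name,
                "baseline_prevalence": s.baseline_prevalence,
                "causal_beta": s.causal_beta,
                "confounder_beta": s.confounder_beta,
                "pleiotropic_snp_effects": dict(s.pleiotropic_snp_effects),
            }
            for s in config.outcome_specs
        ],
        "realized_exposure_prevalence": float(exposure.mean()),
        "seed": config.seed,
        "noise_phecodes": noise_stems,
        "n_excluded_planted": int(excl_mask.sum()),
    }

    dosages = pd.DataFrame(dosage, index=pids, columns=variants["id"].tolist())
    variants = variants.drop(columns=["palindromic"]).assign(
        palindromic=variants["palindromic"]
    )
    ds = CohortDataset(dosages, variants, covariates, flags, diagnoses, phen, truth)
    realized = exposure.mean()
    se3 = 3 * np.sqrt(config.exposure_prevalence * (1 - config.exposure_prevalence) / n)
    if abs(realized - config.exposure_prevalence) > se3:
        raise RuntimeError(
            f"realised exposure prevalence {realized:.4f} departs from target "
            f"{config.exposure_prevalence} by more than 3 SE"
        )
    return ds


# ---------------------------------------------------------------------------
# on-disk round trip (plain TSV + JSON truth record)
# ---------------------------------------------------------------------------

_FILES = {
    "dosages": "dosages.tsv",
    "variants": "variants.tsv",
    "covariates": "covariates.tsv",
    "flags": "flags.tsv",
    "diagnoses": "diagnoses.tsv",
    "phenotypes": "phenotypes.tsv",
    "truth": "truth.json",
}


def write_cohort(dataset: CohortDataset, directory: str | Path) -> list[Path]:
    """Write a dataset as a set of TSV files plus a JSON truth record.

    Floats are written with 17 significant digits so the read/write round
    trip is exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def dump(df: pd.DataFrame, name: str, index: bool):
        path = directory / _FILES[name]
        df.to_csv(path, sep="\t", index=index, float_format="%.17g")
        written.append(path)

    dump(dataset.dosages, "dosages", True)
    dump(dataset.variants, "variants", False)
    dump(dataset.covariates, "covariates", True)
    dump(dataset.flags, "flags", True)
    dump(dataset.diagnoses, "diagnoses", False)
    dump(dataset.phenotypes, "phenotypes", True)
    tpath = directory / _FILES["truth"]
    tpath.write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    written.append(tpath)
    return written


def read_cohort(directory: str | Path) -> CohortDataset:
    """Read a dataset previously produced by :func:`write_cohort`."""
    directory = Path(directory)
    missing = [f for f in _FILES.values() if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"cohort directory {directory} is missing files: {', '.join(missing)}"
        )

    def load(name: str, index_col=None, dtype=None):
        path = directory / _FILES[name]
        try:
            return pd.read_csv(path, sep="\t", index_col=index_col, dtype=dtype)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed file {path}: {exc}") from exc

    dosages = load("dosages", index_col=0)
    ncol = dosages.shape[1]
    bad = dosages.isna().any(axis=1)
    if bad.any():
        line = int(np.where(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
        raise ValueError(
            f"truncated dosage file {directory / _FILES['dosages']} at line {line}"
        )
    dosages = dosages.astype(np.int8)
    variants = load("variants")
    covariates = load("covariates", index_col=0)
    flags = load("flags", index_col=0).astype(bool)
    diagnoses = load("diagnoses", dtype={"code": str})
    phenotypes = load("phenotypes", index_col=0).astype(np.int8)
    truth = json.loads((directory / _FILES["truth"]).read_text())
    if diagnoses.empty:
        diagnoses = pd.DataFrame(
            columns=["participant_id", "code", "system", "date"]
        )
    return CohortDataset(
        dosages, variants, covariates, flags, diagnoses, phenotypes, truth
    )
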