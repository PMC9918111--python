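"""End-to-end orchestration of the split-sample PheWAS-MR design.

The flow mirrors the study design: ascertain the exposure with exclusions,
split the cohort into disjoint base/target halves, run the exposure GWAS in
the base half, clump and score a polygenic risk score in the target half,
scan all phecodes against the standardised score, and take every
Bonferroni-significant phecode through one-sample MR and the two-sample MR
estimator/sensitivity suite. All randomness derives from one master seed
recorded, with every threshold and filter count, in the run manifest;
identical manifests give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc_scan, mr, mr_presso, phenome, prs
from .mr_onesample import two_stage_mr
from .synthetic_cohort import TOY_ICD9_MAP, CohortDataset, SimulationConfig, simulate_cohort

GWAS_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
PHEWAS_COVARIATES = ["age", "sex", "center"] + [f"pc{i}" for i in range(1, 11)]


@dataclass
class PipelineConfig:
    """Thresholds of the full analysis; defaults follow the study design."""

    split_ratio: float = 0.5
    alpha: float = 0.05
    min_cases: int = 250
    prs_preset: dict = field(default_factory=lambda: dict(prs.PRS_PRESET))
    iv_preset: dict = field(default_factory=lambda: dict(prs.IV_PRESET))
    intermediate_band: tuple[float, float] = mr.INTERMEDIATE_BAND
    pleiotropy_p_threshold: float = 0.05 / 665
    outcome_scan: str = "full"  # variant-outcome effects from full cohort or target
    n_boot: int = 200
    presso_n_sim: int = 1000
    seed: int = 0


def _exposure_indicator(dataset: CohortDataset, cfg: PipelineConfig):
    """Ascertain exposure (union of four criteria) and apply exclusions."""
    mapping = TOY_ICD9_MAP
    dx10, n_unmapped = phenome.convert_diagnoses(dataset.diagnoses, mapping)
    stem = dataset.truth.get("exposure_icd10_stem", "K58") if dataset.truth else "K58"
    excl_codes = list(dataset.truth.get("exclusion_codes", ["K50", "K51"])) if dataset.truth else ["K50", "K51"]
    status = phenome.ascertain_exposure(dataset.flags, dx10, excl_codes, [stem])
    keep = phenome.analysis_set(status)
    exposure = status.loc[keep, "is_case"].astype(np.int8)
    return exposure, dx10, status, n_unmapped, stem


def run_pipeline(
    source: SimulationConfig | CohortDataset,
    config: PipelineConfig | None = None,
    covariate_names: list[str] | None = None,
) -> dict:
    """Run the full design; returns a report bundle of tables + manifest."""
    cfg = config or PipelineConfig()
    dataset = simulate_cohort(source) if isinstance(source, SimulationConfig) else source
    stage = "phenotype construction"
    try:
        exposure, dx10, status, n_unmapped, stem = _exposure_indicator(dataset, cfg)
        ids = exposure.index

        stage = "split_sample"
        base, target, split_counts = assoc_scan.split_sample(
            ids, cfg.split_ratio, cfg.seed, exposure
        )

        stage = "base GWAS"
        gw_cov = covariate_names or GWAS_COVARIATES
        exp_stats_base = assoc_scan.gwas_scan(
            dataset.dosages.loc[base], dataset.variants, exposure.loc[base],
            dataset.covariates.loc[base], gw_cov,
        )

        stage = "PRS construction"
        ld_base = prs.InSampleLD(dataset.dosages.loc[base])
        prs_variants = prs.clump(exp_stats_base, ld_base, **cfg.prs_preset)
        weights = (
            exp_stats_base[exp_stats_base["variant_id"].isin(prs_variants)]
            [["variant_id", "beta"]]
        )
        profiles, scaling = prs.score(dataset.dosages.loc[target], weights)

        stage = "phecode construction"
        tables, indicator = phenome.build_phecodes(
            dx10, target, min_cases=cfg.min_cases
        )

        stage = "PheWAS"
        from .phewas import run_phewas

        phewas_res = run_phewas(
            profiles, indicator, dataset.covariates.loc[target],
            [c for c in PHEWAS_COVARIATES if c in dataset.covariates.columns],
            cfg.alpha, exclude_phecodes=(stem,),
        )
        significant = phewas_res.loc[phewas_res["significant"], "phecode"].tolist()

        stage = "instrument selection"
        iv_stats = mr.select_instruments(
            exp_stats_base, ld_base,
            p_threshold=cfg.iv_preset["p_threshold"],
            r2_threshold=cfg.iv_preset["r2_threshold"],
            window_kb=cfg.iv_preset["window_kb"],
        ) if significant else None

        stage = "MR"
        outcome_ids = ids if cfg.outcome_scan == "full" else target
        mr_tables, onesample_rows, sensitivity = {}, [], {}
        _, indicator_out = phenome.build_phecodes(dx10, outcome_ids, min_cases=0)
        out_stats_all = {
            phe: assoc_scan.gwas_scan(
                dataset.dosages.loc[outcome_ids], dataset.variants,
                indicator_out[phe].astype(np.int8),
                dataset.covariates.loc[outcome_ids], gw_cov,
            )
            for phe in significant
        }
        for phe in significant:
            out_stats = out_stats_all[phe]
            inst = mr.harmonize(iv_stats, out_stats, cfg.intermediate_band)
            suite = mr.mr_suite(inst, cfg.n_boot, cfg.seed)
            suite.insert(0, "phecode", phe)
            mr_tables[phe] = suite
            sens: dict = {"n_instruments": len(inst)}
            if len(inst) >= 4:
                pres = mr_presso.presso(inst, cfg.presso_n_sim, cfg.seed)
                sens["presso_global_p"] = pres.global_p
                sens["presso_outliers"] = pres.outlier_ids
            if len(inst) >= 3:
                direction_ok, steiger_p = mr.steiger(inst)
                sens["steiger_direction_correct"] = direction_ok
                sens["steiger_p"] = steiger_p
                sens["leave_one_out"] = mr.leave_one_out(inst)
            others = [p for p in significant if p != phe]
            if others:
                sec = pd.concat(
                    [out_stats_all[p][["variant_id", "p"]] for p in others]
                ).groupby("variant_id", as_index=False)["p"].min()
                pruned, prune_log = mr.prune_pleiotropic(
                    inst, sec, cfg.pleiotropy_p_threshold
                )
                sens["pruned_variants"] = prune_log["variant_id"].tolist()
                if len(prune_log) and len(pruned) >= 2:
                    rerun = mr.ivw_auto(pruned)
                    sens["ivw_after_pruning"] = rerun.to_row()
            sensitivity[phe] = sens

            est = two_stage_mr(
                profiles, exposure.loc[target], indicator[phe].astype(np.int8),
                dataset.covariates.loc[target], gw_cov,
            )
            row = est.to_row()
            row["phecode"] = phe
            onesample_rows.append(row)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "thresholds": {
            "split_ratio": cfg.split_ratio,
            "alpha": cfg.alpha,
            "bonferroni_threshold": phewas_res.attrs.get("bonferroni_threshold"),
            "min_cases": cfg.min_cases,
            "prs_preset": cfg.prs_preset,
            "iv_preset": cfg.iv_preset,
            "intermediate_band": list(cfg.intermediate_band),
            "pleiotropy_p_threshold": cfg.pleiotropy_p_threshold,
            "doubling_constant": mr.DOUBLING_CONSTANT,
            "outcome_scan": cfg.outcome_scan,
        },
        "counts": {
            **split_counts,
            "n_input": int(len(dataset.dosages)),
            "n_excluded": int(status["excluded"].sum()),
            "n_unmapped_icd9": int(n_unmapped),
            "n_phecodes_tested": int(phewas_res.attrs.get("n_tested", 0)),
            "n_significant_phecodes": len(significant),
            "n_prs_variants": len(weights),
            "n_instruments": 0 if iv_stats is None else len(iv_stats),
        },
    }
    return {
        "manifest": manifest,
        "exposure_status": status,
        "gwas_base": exp_stats_base,
        "prs_profiles": profiles,
        "phewas": phewas_res,
        "significant_phecodes": significant,
        "mr": mr_tables,
        "onesample_mr": pd.DataFrame(onesample_rows),
        "sensitivity": sensitivity,
    }


def run_stratified(
    source: SimulationConfig | CohortDataset,
    config: PipelineConfig | None = None,
    strata_variable: str = "sex",
    min_stratum_n: int = 500,
) -> dict:
    """Run the full pipeline separately within each stratum.

    The strata variable is removed from the within-stratum covariates;
    strata smaller than ``min_stratum_n`` are skipped with a warning.
    """
    cfg = config or PipelineConfig()
    dataset = simulate_cohort(source) if isinstance(source, SimulationConfig) else source
    strata = dataset.covariates[strata_variable]
    reports = {}
    for level in sorted(strata.unique()):
        ids = strata.index[strata == level]
        if len(ids) < min_stratum_n:
            import warnings

            warnings.warn(f"stratum {level!r} below minimum n ({len(ids)}); skipped")
            continue
        sub = CohortDataset(
            dataset.dosages.loc[ids], dataset.variants,
            dataset.covariates.loc[ids].drop(columns=[strata_variable]),
            dataset.flags.loc[ids],
            dataset.diagnoses[dataset.diagnoses["participant_id"].isin(ids)],
            dataset.phenotypes.loc[ids], dataset.truth,
        )
        cov = [c for c in GWAS_COVARIATES if c != strata_variable]
        reports[level] = run_pipeline(sub, cfg, covariate_names=cov)
        reports[level]["manifest"]["stratum"] = {
            "variable": strata_variable, "level": str(level), "n": int(len(ids)),
        }
    return reports


def run_reverse_mr(
    dataset: CohortDataset,
    outcome_as_exposure: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Role-swapped two-sample MR: a phecode drives, the exposure responds.

    Instruments are selected for the phecode from the base-half GWAS with
    the same IV preset, and the original exposure is scanned as the
    outcome in the full analysis set.
    """
    cfg = config or PipelineConfig()
    exposure, dx10, status, _, _stem = _exposure_indicator(dataset, cfg)
    ids = exposure.index
    base, _target, _ = assoc_scan.split_sample(ids, cfg.split_ratio, cfg.seed, exposure)
    _, indicator = phenome.build_phecodes(dx10, ids, min_cases=0)
    if outcome_as_exposure not in indicator.columns:
        raise ValueError(f"no diagnoses observed for phecode {outcome_as_exposure!r}")

    phe_stats = assoc_scan.gwas_scan(
        dataset.dosages.loc[base], dataset.variants,
        indicator.loc[base, outcome_as_exposure].astype(np.int8),
        dataset.covariates.loc[base], GWAS_COVARIATES,
    )
    ld_base = prs.InSampleLD(dataset.dosages.loc[base])
    iv_stats = mr.select_instruments(
        phe_stats, ld_base,
        p_threshold=cfg.iv_preset["p_threshold"],
        r2_threshold=cfg.iv_preset["r2_threshold"],
        window_kb=cfg.iv_preset["window_kb"],
    )
    exp_as_outcome = assoc_scan.gwas_scan(
        dataset.dosages.loc[ids], dataset.variants, exposure,
        dataset.covariates.loc[ids], GWAS_COVARIATES,
    )
    inst = mr.harmonize(iv_stats, exp_as_outcome, cfg.intermediate_band)
    report = {
        "exposure_trait": outcome_as_exposure,
        "outcome_trait": "exposure",
        "mr": mr.mr_suite(inst, cfg.n_boot, cfg.seed),
        "n_instruments": len(inst),
    }
    if len(inst) >= 3:
        ok, p = mr.steiger(inst)
        report["steiger_direction_correct"] = ok
        report["steiger_p"] = p
    return report


def report_hash(bundle: dict) -> str:
    """Deterministic SHA-256 over the report bundle's tabular content."""

    h = hashlib.sha256()

    def feed(obj):
        if isinstance(obj, pd.DataFrame):
            h.update(obj.to_csv(float_format="%.12g").encode())
        elif isinstance(obj, dict):
            for k in sorted(obj, key=str):
                h.update(str(k).encode())
                feed(obj[k])
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                feed(v)
        else:
            h.update(json.dumps(obj, default=str, sort_keys=True).encode())

    feed(bundle)
    return h.hexdigest()
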