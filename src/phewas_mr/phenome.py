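"""Phenotype construction: exposure ascertainment and phecode building.

Diagnoses arrive as long-format records in either ICD-9 or ICD-10. ICD-9
codes are first converted with a user-supplied two-column equivalence
mapping; all codes are then truncated to their first three characters to
form phecodes, restricted to the permitted ICD-10 chapters, and filtered to
phecodes with more than ``min_cases`` cases.

Exposure cases are ascertained by the union of four alternative criteria
(symptom questionnaire, digestive-health questionnaire, self report, ICD-10
diagnosis); participants carrying a confounding condition diagnosed on or
before their first exposure diagnosis are excluded from both the case and
the control set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Chapters I-XV and XVII of ICD-10 by leading letter: excludes perinatal (P),
# symptoms/signs (R), injury/poisoning (S, T) and the U-Z supplementary
# chapters.
DEFAULT_CHAPTER_WHITELIST = frozenset("ABCDEFGHIJKLMNOQ")

DEFAULT_MIN_CASES = 250

_PHECODE_RE = re.compile(r"^[A-Z][0-9]{2}$")


def normalize_code(code: str) -> str:
    """Strip dots and whitespace and upper-case an ICD code."""
    return str(code).replace(".", "").strip().upper()


def load_mapping(path: str | Path) -> dict[str, str]:
    """Load a two-column (icd9 TAB icd10) equivalence mapping file."""
    mapping = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"malformed mapping file {path}: line {lineno} has "
                f"{len(parts)} columns (expected 2)"
            )
        mapping[normalize_code(parts[0])] = normalize_code(parts[1])
    return mapping


def map_icd9_to_icd10(code: str, mapping: dict[str, str]) -> str | None:
    """Map one ICD-9 code to ICD-10; returns None when unmapped.

    Codes already in ICD-10 form (leading letter) pass through unchanged.
    """
    if not str(code).strip():
        raise ValueError("empty diagnosis code")
    code = normalize_code(code)
    if code[0].isalpha():  # already ICD-10
        return code
    return mapping.get(code)


def convert_diagnoses(
    diagnoses: pd.DataFrame, mapping: dict[str, str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Convert a long diagnosis table to ICD-10; returns (table, n_unmapped).

    Records whose ICD-9 code has no equivalence entry are dropped (their
    count is reported).
    """
    mapping = mapping or {}
    df = diagnoses.copy()
    df["code"] = df["code"].map(normalize_code)
    is9 = df["system"].str.upper().eq("ICD9")
    mapped = df.loc[is9, "code"].map(lambda c: mapping.get(c))
    n_unmapped = int(mapped.isna().sum())
    df.loc[is9, "code"] = mapped
    df = df.dropna(subset=["code"]).copy()
    df["system"] = "ICD10"
    return df, n_unmapped


@dataclass
class PhecodeTable:
    """One retained phecode with its membership."""

    phecode: str
    description: str
    case_count: int
    control_count: int
    member_codes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not _PHECODE_RE.match(self.phecode):
            raise ValueError(f"invalid phecode {self.phecode!r}")


def build_phecodes(
    diagnoses: pd.DataFrame,
    participant_ids: pd.Index,
    chapter_whitelist: frozenset[str] = DEFAULT_CHAPTER_WHITELIST,
    min_cases: int = DEFAULT_MIN_CASES,
) -> tuple[list[PhecodeTable], pd.DataFrame]:
    """Build 3-character phecodes from an ICD-10 diagnosis table.

    Returns the retained phecode summaries and a participants x phecodes
    boolean indicator matrix. A phecode is retained when its leading letter
    is whitelisted and its case count strictly exceeds ``min_cases``.
    """
    n = len(participant_ids)
    if diagnoses.empty:
        return [], pd.DataFrame(index=participant_ids)
    df = diagnoses.copy()
    df["code"] = df["code"].map(normalize_code)
    df["phecode"] = df["code"].str[:3]
    df = df[df["phecode"].str.match(_PHECODE_RE)]
    df = df[df["phecode"].str[0].isin(chapter_whitelist)]
    df = df[df["participant_id"].isin(participant_ids)]

    tables: list[PhecodeTable] = []
    cols = {}
    for phe, grp in sorted(df.groupby("phecode")):
        members = set(grp["code"])
        cases = grp["participant_id"].unique()
        if len(cases) <= min_cases:
            continue
        ind = pd.Series(False, index=participant_ids)
        ind.loc[cases] = True
        cols[phe] = ind
        tables.append(
            PhecodeTable(
                phecode=phe,
                description=phe,
                case_count=len(cases),
                control_count=n - len(cases),
                member_codes=members,
            )
        )
    indicator = pd.DataFrame(cols, index=participant_ids)
    return tables, indicator


@dataclass
class ExposureStatus:
    participant: str
    is_case: bool
    criteria_met: frozenset[str]
    excluded: bool
    exclusion_reason: str | None = None


def ascertain_exposure(
    flags: pd.DataFrame,
    diagnoses: pd.DataFrame,
    exclusion_codes: list[str],
    exposure_codes: list[str],
) -> pd.DataFrame:
    """Ascertain exposure per participant from flags and ICD-10 records.

    A participant is a case when any of the four criteria holds: the
    symptom-questionnaire flag (rome3), the digestive-health-questionnaire
    flag (dhq_yes), the self-report flag, or an ICD-10 diagnosis whose code
    starts with one of ``exposure_codes``. Participants with an exclusion
    diagnosis dated on or before their first exposure diagnosis — or with
    an exclusion diagnosis and no dated exposure diagnosis — are excluded.

    Returns a DataFrame indexed by participant with columns is_case,
    criteria_met (comma-joined), excluded, exclusion_reason.
    """
    if not exposure_codes:
        raise ValueError("exposure ICD code list is empty")
    exposure_codes = [normalize_code(c) for c in exposure_codes]
    exclusion_codes = [normalize_code(c) for c in exclusion_codes]

    pids = flags.index
    out = pd.DataFrame(
        {
            "is_case": False,
            "criteria_met": "",
            "excluded": False,
            "exclusion_reason": "",
        },
        index=pids,
    )

    dx = diagnoses.copy()
    if not dx.empty:
        dx["code"] = dx["code"].map(normalize_code)
        dx["date"] = pd.to_datetime(dx["date"], errors="coerce")

    def starts_with_any(series: pd.Series, prefixes: list[str]) -> pd.Series:
        m = pd.Series(False, index=series.index)
        for p in prefixes:
            m |= series.str.startswith(p)
        return m

    exp_dates = pd.Series(pd.NaT, index=pids)
    excl_dates = pd.Series(pd.NaT, index=pids)
    has_exp_dx = pd.Series(False, index=pids)
    has_excl_dx = pd.Series(False, index=pids)
    if not dx.empty:
        em = starts_with_any(dx["code"], exposure_codes)
        xm = starts_with_any(dx["code"], exclusion_codes)
        first_exp = dx[em].groupby("participant_id")["date"].min()
        first_excl = dx[xm].groupby("participant_id")["date"].min()
        common = first_exp.index.intersection(pids)
        exp_dates.loc[common] = first_exp.loc[common]
        has_exp_dx.loc[common] = True
        common = first_excl.index.intersection(pids)
        excl_dates.loc[common] = first_excl.loc[common]
        has_excl_dx.loc[common] = True

    crit = {
        "rome3": flags["rome3"].astype(bool),
        "dhq": flags["dhq_yes"].astype(bool),
        "self_report": flags["self_report"].astype(bool),
        "icd10": has_exp_dx,
    }
    any_case = pd.Series(False, index=pids)
    met = pd.Series([[] for _ in pids], index=pids)
    for name, mask in crit.items():
        any_case |= mask
        for pid in pids[mask]:
            met.loc[pid].append(name)
    out["is_case"] = any_case
    out["criteria_met"] = met.map(",".join)

    # exclusion: dated on/before first exposure dx, or exclusion present
    # with no dated exposure dx (conservative)
    undated_exp = has_exp_dx & exp_dates.isna()
    before = has_excl_dx & exp_dates.notna() & (excl_dates <= exp_dates)
    undated_excl = has_excl_dx & excl_dates.isna()
    no_exp = has_excl_dx & ~has_exp_dx
    excl = before | undated_excl | no_exp | (has_excl_dx & undated_exp)
    out.loc[excl, "excluded"] = True
    out.loc[excl & before, "exclusion_reason"] = "exclusion condition before exposure diagnosis"
    out.loc[excl & ~before, "exclusion_reason"] = "exclusion condition without prior exposure diagnosis"
    return out


def analysis_set(status: pd.DataFrame) -> pd.Index:
    """Participants retained after exclusions."""
    return status.index[~status["excluded"]]
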