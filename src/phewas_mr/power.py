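"""Analytic power for Mendelian randomization with a binary outcome.

For a two-sided Wald test at level alpha of a causal odds ratio ``or_target``
per unit genetically determined exposure, with an instrument (or score)
explaining a fraction r2 of exposure variance, n participants and a case
fraction f, the non-centrality of the test is approximately

    ncp = |ln OR| * sqrt(n * r2 * f * (1 - f))

and power = Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}).  The
second (wrong-tail) term matters only near the null, where it restores the
two-sided size. The form is validated against a Monte-Carlo oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerParams:
    alpha: float = 0.05
    n: int = 173_176
    r2: float = 0.0012
    or_target: float = 1.5
    case_fraction: float = 0.1

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0,1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0,1)")
        if self.n <= 0 or self.or_target <= 0:
            raise ValueError("n and or_target must be positive")


def mr_power(params: PowerParams) -> float:
    """Two-sided power to detect ``or_target`` at level ``alpha``."""
    params.validate()
    z = stats.norm.ppf(1 - params.alpha / 2)
    ncp = abs(np.log(params.or_target)) * np.sqrt(
        params.n * params.r2 * params.case_fraction * (1 - params.case_fraction)
    )
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def phenome_power_screen(
    phecode_params: pd.DataFrame,
    or_levels: tuple[float, ...] = (1.5, 1.8),
    power_threshold: float = 0.8,
    alpha: float = 0.05,
    r2: float = 0.0012,
) -> tuple[dict[float, int], pd.DataFrame]:
    """Per-phecode power at each OR level and the count powered above
    ``power_threshold``.

    ``phecode_params`` needs columns (phecode, n, case_fraction). Returns
    ({or_level: count}, per-phecode power table).
    """
    rows = []
    for _, r in phecode_params.iterrows():
        row = {"phecode": r["phecode"], "n": int(r["n"]),
               "case_fraction": float(r["case_fraction"])}
        for or_l in or_levels:
            row[f"power_or_{or_l:g}"] = mr_power(
                PowerParams(alpha=alpha, n=int(r["n"]), r2=r2,
                            or_target=or_l, case_fraction=float(r["case_fraction"]))
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = {
        or_l: int((table[f"power_or_{or_l:g}"] >= power_threshold).sum())
        for or_l in or_levels
    }
    return counts, table
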