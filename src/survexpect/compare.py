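"""Observed-versus-predicted survival comparison, the analysis headline.

For each (race/ethnicity, treatment) stratum the observed Kaplan–Meier curve
is paired with the predicted life-expectancy curve simulated from the life
table on the stratum's exact age multiset, and the yearly difference
``delta(k) = OS(k) - LE(k)`` is computed on the percent scale.  A positive
delta means the cohort outlives its general-population life-table prediction;
a negative delta means an excess-mortality pattern the life table does not
capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientRecord, RACE_GROUPS, TREATMENTS
from .lifetable import LifeTable
from .simulate import LEPrediction, le_from_closed_form, simulate_cohort_le
from .survival import SurvivalCurve, kaplan_meier

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "AnalysisConfig",
    "compare_curves",
    "run_stratified_analysis",
    "fit_excess_multiplier",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Paired annual curves and their difference for one stratum.

    All three arrays cover years 0..horizon on the percent scale;
    ``delta_annual = os_annual - le_annual`` exactly (unrounded; use
    :meth:`rounded` for one-decimal reporting).
    """

    stratum: tuple[str, str]
    os_annual: np.ndarray
    le_annual: np.ndarray
    delta_annual: np.ndarray
    n: int

    def rounded(self) -> pd.DataFrame:
        """One-decimal (half-up) report table: year, os, le, delta."""
        from .cohort import _round_half_up

        return pd.DataFrame(
            {
                "year": np.arange(self.os_annual.size),
                "os": [_round_half_up(v) for v in self.os_annual],
                "le": [_round_half_up(v) for v in self.le_annual],
                "delta": [_round_half_up(v) for v in self.delta_annual],
            }
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Run parameters for the stratified observed-vs-predicted analysis."""

    horizon: int = 10
    n_replicates: int = 1000
    seed: int | None = None
    min_stratum_size: int = 30
    analytic_le: bool = False
    overflow: str = "clamp"


def compare_curves(os_curve: SurvivalCurve, le: LEPrediction, stratum=("", "")) -> ComparisonResult:
    """Elementwise OS − LE on the shared annual grid, percent scale.

    Raises
    ------
    ValueError
        If the observed and predicted grids disagree.
    """
    horizon = le.horizon
    os_annual = os_curve.annual_values(horizon) * 100.0
    le_annual = le.le_curve * 100.0
    if os_annual.shape != le_annual.shape:
        raise ValueError(
            f"annual grid mismatch: OS has {os_annual.size} points, LE has {le_annual.size}"
        )
    return ComparisonResult(
        stratum=tuple(stratum),
        os_annual=os_annual,
        le_annual=le_annual,
        delta_annual=os_annual - le_annual,
        n=os_curve.n,
    )


def run_stratified_analysis(
    records: list[PatientRecord],
    table: LifeTable,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Per-stratum KM vs life-table LE for all race × treatment strata.

    For each stratum: Kaplan–Meier on the stratum's follow-up data; a
    predicted-LE curve for the stratum's exact age multiset (Monte-Carlo by
    default, analytic product-limit if ``config.analytic_le``); the yearly
    difference curve.  Strata below ``config.min_stratum_size`` are skipped
    with a warning.  Also returns the long difference table
    (race, treatment, year, os, le, delta) across all analyzed strata.
    """
    results: list[ComparisonResult] = []
    rows = []
    seed_seq = np.random.SeedSequence(config.seed)
    strata = [(race, trt) for race in RACE_GROUPS for trt in TREATMENTS]
    stratum_seeds = seed_seq.generate_state(len(strata)) % (2**31)
    for (race, trt), sub_seed in zip(strata, stratum_seeds):
        members = [r for r in records if r.race_ethnicity == race and r.treatment == trt]
        if len(members) == 0:
            logger.warning("stratum (%s, %s) is empty; skipped", race, trt)
            continue
        if len(members) < config.min_stratum_size:
            logger.warning(
                "stratum (%s, %s) has %d < %d records; skipped",
                race,
                trt,
                len(members),
                config.min_stratum_size,
            )
            continue
        km = kaplan_meier(
            [r.followup_years for r in members], [r.event for r in members]
        )
        ages = [r.age_dx for r in members]
        if config.analytic_le:
            le = le_from_closed_form(table, ages, config.horizon, overflow=config.overflow)
        else:
            le = simulate_cohort_le(
                table,
                ages,
                horizon=config.horizon,
                n_replicates=config.n_replicates,
                seed=int(sub_seed),
                overflow=config.overflow,
            )
        result = compare_curves(km, le, stratum=(race, trt))
        results.append(result)
        for k in range(config.horizon + 1):
            rows.append(
                {
                    "race_ethnicity": race,
                    "treatment": trt,
                    "year": k,
                    "os": result.os_annual[k],
                    "le": result.le_annual[k],
                    "delta": result.delta_annual[k],
                }
            )
    long_table = pd.DataFrame(
        rows, columns=["race_ethnicity", "treatment", "year", "os", "le", "delta"]
    )
    return results, long_table


def fit_excess_multiplier(
    records: list[PatientRecord],
    table: LifeTable,
    horizon: int = 10,
    bracket: tuple[float, float] = (0.05, 5.0),
) -> float:
    """Estimate the one-parameter excess-hazard multiplier for a cohort.

    Solves for the scalar ``m`` such that the closed-form predicted survival
    under per-year death probabilities ``min(1, m * q_x)`` matches the
    observed Kaplan–Meier survival at the horizon.  ``m = 1`` means observed
    mortality equals the life-table law; ``m > 1`` means excess mortality.
    """
    from scipy.optimize import brentq

    km = kaplan_meier([r.followup_years for r in records], [r.event for r in records])
    target = km.value_at(float(horizon))
    q_rows = np.stack(
        [table.q_path(r.age_dx, horizon, overflow="clamp") for r in records]
    )

    def predicted(m: float) -> float:
        return float(np.prod(1.0 - np.minimum(1.0, m * q_rows), axis=1).mean())

    lo, hi = bracket
    f_lo, f_hi = predicted(lo) - target, predicted(hi) - target
    if f_lo * f_hi > 0:
        # observed survival outside the achievable range: return nearest bound
        return lo if abs(f_lo) < abs(f_hi) else hi
    return float(brentq(lambda m: predicted(m) - target, lo, hi, xtol=1e-6))
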