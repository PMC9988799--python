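"""Patient-level cohort model for a registry-style prostate-cancer dataset.

Covers the record schema, D'Amico risk classification from PSA / clinical T
stage / Gleason Grade Group, the eligibility filter (intermediate- and
high-risk, known metastatic status M0, four analyzable race/ethnicity groups),
and descriptive "Table 1" style summaries with medians, IQRs, category
percentages and chi-square tests across strata.

D'Amico tiers as used here:

* intermediate — cT2b, and/or PSA in [10, 20] ng/ml, and/or GGG 3;
* high — cT2c or higher, and/or PSA > 20 ng/ml, and/or GGG >= 4;
* low — none of the above (all three inputs known).

High dominates intermediate when criteria from both tiers hold.  PSA exactly
10 or 20 defaults to intermediate (low risk is conventionally PSA < 10); both
boundaries are configurable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import chisquare_proportions

logger = logging.getLogger(__name__)

__all__ = [
    "RACE_GROUPS",
    "TREATMENTS",
    "CT_STAGES",
    "PatientRecord",
    "UnclassifiableError",
    "classify_damico",
    "apply_eligibility",
    "describe_cohort",
    "read_cohort",
    "write_cohort",
]

RACE_GROUPS = ("NHW", "NHB", "HISP", "ASIAN")
RACE_TOKENS = RACE_GROUPS + ("NATIVE", "UNKNOWN")
TREATMENTS = ("RP", "EBRT")
CT_STAGES = ("cT1", "cT2a", "cT2b", "cT2c", "cT3", "cT4", "cTx")
CN_STAGES = ("cN0", "cN1", "cNX")
_CT_RANK = {s: i for i, s in enumerate(("cT1", "cT2a", "cT2b", "cT2c", "cT3", "cT4"))}

COHORT_COLUMNS = [
    "id",
    "age_dx",
    "race_ethnicity",
    "treatment",
    "psa",
    "ct_stage",
    "ggg",
    "cn_stage",
    "m_status",
    "followup_years",
    "event",
]


class UnclassifiableError(ValueError):
    """Risk classification impossible: no criterion fires and inputs are missing."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row.

    ``followup_years`` is the death time when ``event`` is True, otherwise the
    censoring time; administrative censoring caps it at the study horizon
    (10 years by default).  ``psa`` and ``ggg`` may be None (unknown).
    """

    id: str
    age_dx: int
    race_ethnicity: str
    treatment: str
    psa: float | None
    ct_stage: str
    ggg: int | None
    cn_stage: str
    m_status: str
    followup_years: float
    event: bool

    def __post_init__(self) -> None:
        if self.race_ethnicity not in RACE_TOKENS:
            raise ValueError(f"unknown race/ethnicity token {self.race_ethnicity!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.ct_stage not in CT_STAGES:
            raise ValueError(f"unknown clinical T stage {self.ct_stage!r}")
        if self.cn_stage not in CN_STAGES:
            raise ValueError(f"unknown clinical N stage {self.cn_stage!r}")
        if self.m_status not in ("M0", "UNKNOWN"):
            raise ValueError(f"unknown metastatic status {self.m_status!r}")
        if self.psa is not None and self.psa < 0:
            raise ValueError("PSA must be non-negative")
        if self.ggg is not None and not 1 <= self.ggg <= 5:
            raise ValueError("GGG must be in 1..5")
        if self.followup_years < 0:
            raise ValueError("followup_years must be non-negative")


def classify_damico(
    psa: float | None,
    ct_stage: str | None,
    ggg: int | None,
    psa_low_cut: float = 10.0,
    psa_high_cut: float = 20.0,
    intermediate_includes_low_cut: bool = True,
    intermediate_includes_high_cut: bool = True,
    ct2_nos_as: str = "cT2a",
) -> str:
    """D'Amico risk group ("LOW" / "INTERMEDIATE" / "HIGH") from tumor fields.

    Missing inputs are skipped when another criterion fires; if nothing fires
    and any input is missing (or all are missing) the record is
    unclassifiable.  ``ct2_nos_as`` maps an unsubstaged "cT2" token; the
    default cT2a is conservative (never inflates risk).
    """
    if psa is None and ct_stage is None and ggg is None:
        raise UnclassifiableError("PSA, cT stage and GGG all missing")
    if ct_stage == "cT2":
        logger.warning("cT2 without substage treated as %s", ct2_nos_as)
        ct_stage = ct2_nos_as
    ct_rank = None
    if ct_stage is not None and ct_stage != "cTx":
        if ct_stage not in _CT_RANK:
            raise ValueError(f"unknown clinical T stage {ct_stage!r}")
        ct_rank = _CT_RANK[ct_stage]

    high = False
    if psa is not None:
        # the two PSA tiers partition at the high cut: excluding 20 from
        # intermediate moves it into high, not into low
        if psa > psa_high_cut or (not intermediate_includes_high_cut and psa == psa_high_cut):
            high = True
    if ggg is not None and ggg >= 4:
        high = True
    if ct_rank is not None and ct_rank >= _CT_RANK["cT2c"]:
        high = True
    if high:
        return "HIGH"

    inter = False
    if psa is not None:
        lo_ok = psa >= psa_low_cut if intermediate_includes_low_cut else psa > psa_low_cut
        hi_ok = psa <= psa_high_cut if intermediate_includes_high_cut else psa < psa_high_cut
        if lo_ok and hi_ok:
            inter = True
    if ggg is not None and ggg == 3:
        inter = True
    if ct_rank is not None and ct_rank == _CT_RANK["cT2b"]:
        inter = True
    if inter:
        return "INTERMEDIATE"

    if psa is None or ggg is None or ct_stage is None or ct_stage == "cTx":
        raise UnclassifiableError("no criterion fires and at least one input is unknown")
    return "LOW"


# Fixed exclusion precedence: first matching reason wins.
EXCLUSION_REASONS = (
    "unknown_metastatic",
    "unknown_race",
    "native_american",
    "low_risk",
    "unclassifiable_risk",
)


def apply_eligibility(
    records: list[PatientRecord], **classify_kwargs
) -> tuple[list[PatientRecord], Counter]:
    """Filter to the analyzable cohort; count exclusions per reason.

    Keeps records with known M0 status, one of the four analyzable
    race/ethnicity groups, and intermediate or high D'Amico risk.  Node-positive
    (cN1) and cNX records are retained.  Each dropped record is tallied under
    the first matching reason in :data:`EXCLUSION_REASONS`; kept + excluded
    always equals the input count.
    """
    kept: list[PatientRecord] = []
    log: Counter = Counter()
    for rec in records:
        if rec.m_status == "UNKNOWN":
            log["unknown_metastatic"] += 1
            continue
        if rec.race_ethnicity == "UNKNOWN":
            log["unknown_race"] += 1
            continue
        if rec.race_ethnicity == "NATIVE":
            log["native_american"] += 1
            continue
        try:
            risk = classify_damico(rec.psa, rec.ct_stage, rec.ggg, **classify_kwargs)
        except UnclassifiableError:
            log["unclassifiable_risk"] += 1
            continue
        if risk == "LOW":
            log["low_risk"] += 1
            continue
        kept.append(rec)
    return kept, log


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _records_frame(records: list[PatientRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])

    def _risk(r: PatientRecord) -> str:
        try:
            return classify_damico(r.psa, r.ct_stage, r.ggg)
        except UnclassifiableError:
            return "UNCLASSIFIABLE"

    frame["risk_group"] = [_risk(r) for r in records]
    return frame


def describe_cohort(records: list[PatientRecord], by: str = "race_ethnicity") -> pd.DataFrame:
    """Descriptive summary table stratified by ``by`` plus an Overall column.

    Continuous variables (age, PSA) get median and IQR (25th/75th percentile,
    linear interpolation); categorical variables (cT, GGG, cN, risk group,
    treatment) get counts with half-up one-decimal percentages, and a
    chi-square p-value for homogeneity across strata.  Empty strata appear
    with n=0 and blank statistics.
    """
    if not records:
        raise ValueError("cannot describe an empty cohort")
    frame = _records_frame(records)
    strata = list(dict.fromkeys(frame[by]))
    columns = ["Overall"] + strata

    def _subframes():
        yield "Overall", frame
        for s in strata:
            yield s, frame[frame[by] == s]

    rows: dict[str, dict[str, object]] = {}

    def _set(row: str, col: str, value: object) -> None:
        rows.setdefault(row, {})[col] = value

    for col, sub in _subframes():
        _set("n", col, len(sub))
        for var, label in (("age_dx", "age"), ("psa", "psa")):
            vals = sub[var].dropna().astype(float)
            if len(vals):
                med = float(np.percentile(vals, 50))
                lo = float(np.percentile(vals, 25))
                hi = float(np.percentile(vals, 75))
                _set(f"{label}_median_iqr", col, f"{med:g} ({lo:g}-{hi:g})")
            else:
                _set(f"{label}_median_iqr", col, "")

    categorical = {
        "ct_stage": list(CT_STAGES),
        "ggg": [1, 2, 3, 4, 5, None],
        "cn_stage": list(CN_STAGES),
        "risk_group": ["INTERMEDIATE", "HIGH"],
        "treatment": list(TREATMENTS),
    }
    for var, levels in categorical.items():
        for col, sub in _subframes():
            n = len(sub)
            series = sub[var]
            for level in levels:
                if level is None:
                    count = int(series.isna().sum())
                    name = f"{var}=Unknown"
                else:
                    count = int((series == level).sum())
                    name = f"{var}={level}"
                pct = _round_half_up(100.0 * count / n) if n else ""
                _set(name, col, f"{count} ({pct})" if n else "")
        # chi-square across strata, dropping all-zero levels
        counts = []
        for s in strata:
            sub = frame[frame[by] == s]
            row = [
                int(sub[var].isna().sum()) if lv is None else int((sub[var] == lv).sum())
                for lv in levels
            ]
            counts.append(row)
        tab = np.array(counts).T
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            _, p = chisquare_proportions(tab)
            _set(f"{var}=chi2_p", "Overall", f"{p:.4g}")

    out = pd.DataFrame(rows).T
    return out.reindex(columns=columns)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read the cohort CSV schema into validated records.

    Raises ``ValueError`` naming the 1-based file line of a malformed row.
    """
    frame = pd.read_csv(Path(path), dtype=str, skipinitialspace=True)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                PatientRecord(
                    id=str(row.id),
                    age_dx=int(float(row.age_dx)),
                    race_ethnicity=str(row.race_ethnicity),
                    treatment=str(row.treatment),
                    psa=None if pd.isna(row.psa) or row.psa == "" else float(row.psa),
                    ct_stage=str(row.ct_stage),
                    ggg=None if pd.isna(row.ggg) or row.ggg == "" else int(float(row.ggg)),
                    cn_stage=str(row.cn_stage),
                    m_status=str(row.m_status),
                    followup_years=float(row.followup_years),
                    event=bool(int(row.event)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row on line {i + 2}: {exc}") from None
    return records


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    """Write records in the canonical cohort CSV schema (deterministic order)."""
    frame = pd.DataFrame([vars(r) for r in records], columns=COHORT_COLUMNS)
    frame["event"] = frame["event"].astype(int)
    frame.to_csv(path, index=False, float_format="%.17g")
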