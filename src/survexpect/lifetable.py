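"""Period life tables: parsing, validation, and closed-form survival.

A period life table tabulates ``q_x``, the conditional probability that a
person alive at exact integer age ``x`` dies before age ``x + 1``.  The table
is the mortality law behind every life-expectancy prediction in this package:
the Monte-Carlo engine draws annual survive/die transitions from it, and the
closed-form product-limit survival computed here is the engine's exact limit,
used as an internal oracle and as a fast analytic path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "LifeTableError",
    "AgeRangeError",
    "read_life_table",
    "write_life_table",
    "closed_form_survival",
]


class LifeTableError(ValueError):
    """A life table file or object violates the table invariants."""


class AgeRangeError(LifeTableError):
    """An age lookup falls outside the tabulated range."""


@dataclass(frozen=True)
class LifeTable:
    """Annual conditional death probabilities ``q_x`` on a contiguous age grid.

    Parameters
    ----------
    ages
        Contiguous ascending integer ages, ``a_min .. a_max``.
    qx
        ``q_x`` for each age, each in ``[0, 1]``.  The terminal age is treated
        as absorbing: ``q`` at ``a_max`` is forced to 1 on construction (with a
        warning if the input differed).
    label
        Free-text provenance (source, calendar period, sex).
    """

    ages: np.ndarray
    qx: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=np.int64)
        qx = np.asarray(self.qx, dtype=np.float64)
        if ages.ndim != 1 or qx.ndim != 1 or ages.size != qx.size:
            raise LifeTableError("ages and qx must be 1-d arrays of equal length")
        if ages.size < 2:
            raise LifeTableError("a life table needs at least 2 rows")
        uniq, counts = np.unique(ages, return_counts=True)
        dup = uniq[counts > 1]
        if dup.size:
            raise LifeTableError(f"duplicate age {int(dup[0])}")
        order = np.argsort(ages)
        ages = ages[order]
        qx = qx[order]
        gaps = np.flatnonzero(np.diff(ages) != 1)
        if gaps.size:
            raise LifeTableError(f"non-contiguous ages at {int(ages[gaps[0] + 1])}")
        bad = np.flatnonzero((qx < 0.0) | (qx > 1.0))
        if bad.size:
            raise LifeTableError(f"qx out of range at age {int(ages[bad[0]])}")
        if qx[-1] != 1.0:
            logger.warning(
                "terminal qx at age %d was %g; forcing absorbing value 1.0",
                int(ages[-1]),
                qx[-1],
            )
            qx = qx.copy()
            qx[-1] = 1.0
        qx.setflags(write=False)
        ages.setflags(write=False)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def a_min(self) -> int:
        return int(self.ages[0])

    @property
    def a_max(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """``q_x`` at a single tabulated age; raises outside the table."""
        if not self.a_min <= age <= self.a_max:
            raise AgeRangeError(
                f"age {age} outside tabulated range [{self.a_min}, {self.a_max}]"
            )
        return float(self.qx[age - self.a_min])

    def q_path(self, age: int, horizon: int, overflow: str = "clamp") -> np.ndarray:
        """``q`` along the attained-age path ``age .. age + horizon - 1``.

        Under ``overflow="clamp"`` ages beyond ``a_max`` contribute ``q = 1``
        (the terminal age is absorbing); ``overflow="strict"`` raises instead.
        Ages below ``a_min`` always raise.
        """
        if overflow not in ("clamp", "strict"):
            raise ValueError(f"unknown overflow policy {overflow!r}")
        if horizon < 0:
            raise ValueError("horizon must be >= 0")
        if not self.a_min <= age <= self.a_max:
            raise AgeRangeError(
                f"age {age} outside tabulated range [{self.a_min}, {self.a_max}]"
            )
        end = age + horizon - 1
        if end > self.a_max:
            if overflow == "strict":
                raise AgeRangeError(
                    f"age path reaches {end} beyond table maximum {self.a_max}"
                )
            logger.debug(
                "age path %d..%d exceeds a_max=%d; clamping q to 1 beyond the table",
                age,
                end,
                self.a_max,
            )
        idx = np.arange(age, age + horizon) - self.a_min
        out = np.ones(horizon, dtype=np.float64)
        inside = idx < self.qx.size
        out[inside] = self.qx[idx[inside]]
        return out


def read_life_table(
    path: str | Path,
    age_col: str = "age",
    qx_col: str = "qx",
    label: str | None = None,
) -> LifeTable:
    """Parse a life-table CSV (header row; configurable column names).

    Raises
    ------
    LifeTableError
        Missing columns, unparseable numbers (with the offending line
        number), duplicate / non-contiguous ages, or ``qx`` outside [0, 1].
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for col in (age_col, qx_col):
        if col not in frame.columns:
            raise LifeTableError(f"{path}: missing required column {col!r}")
    if len(frame) < 2:
        raise LifeTableError(f"{path}: a life table needs at least 2 rows")

    def _numeric(col: str, caster):
        values = []
        for i, raw in enumerate(frame[col]):
            try:
                values.append(caster(raw))
            except (TypeError, ValueError):
                # +2: one for the header, one for 1-based line numbering
                raise LifeTableError(
                    f"{path}: unparseable {col!r} value {raw!r} on line {i + 2}"
                ) from None
        return values

    ages = _numeric(age_col, lambda s: int(float(s)))
    qx = _numeric(qx_col, float)
    return LifeTable(
        ages=np.array(ages), qx=np.array(qx), label=label if label is not None else path.name
    )


def write_life_table(
    table: LifeTable, path: str | Path, age_col: str = "age", qx_col: str = "qx"
) -> None:
    """Write the canonical CSV form; round-trips ``qx`` bit-exactly."""
    frame = pd.DataFrame({age_col: table.ages, qx_col: table.qx})
    frame.to_csv(path, index=False, float_format="%.17g")


def closed_form_survival(
    table: LifeTable, age: int, horizon: int, overflow: str = "clamp"
) -> np.ndarray:
    """Exact conditional survival curve from the product-limit identity.

    Returns ``S`` of length ``horizon + 1`` with ``S[0] = 1`` and
    ``S[k] = prod_{j<k} (1 - q_{age+j})``: the probability that a person of
    exact age ``age`` is still alive ``k`` whole years later.  This is the
    deterministic limit of the Monte-Carlo survive/die chain.
    """
    q = table.q_path(age, horizon, overflow=overflow)
    return np.concatenate([[1.0], np.cumprod(1.0 - q)])
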