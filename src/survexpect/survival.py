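"""Observed-survival statistics built from first principles.

The Kaplan–Meier product-limit estimator, the two-group log-rank test, and
the Pearson chi-square test of proportions are implemented directly here
(numpy for the arithmetic, scipy only for the chi-square tail probability):
these estimators are the analysis's observational arm and are cross-checked
against an established survival library in the test suite rather than
delegated to one.

Conventions: at tied times, deaths are processed before censorings (censored
observations stay in the risk set for events at the same time); the annual
readout takes the step-function value at exactly ``k`` years, so an event at
time ``k`` is reflected in ``annual value[k]``; administrative censoring at
the horizon is not an event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SurvivalCurve", "kaplan_meier", "logrank_test", "chisquare_proportions"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier estimate over the distinct event times.

    ``times`` lists distinct event (death) times ascending; ``survival`` the
    estimate just after each, ``at_risk``/``events`` the risk-set size and
    death count at each.  ``greenwood_var`` is the Greenwood variance of the
    estimate (stored for completeness; not used in headline outputs).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def value_at(self, t: float) -> float:
        """Step-function value at time ``t`` (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def annual_values(self, horizon: int = 10) -> np.ndarray:
        """Survival read at integer years 0..horizon (percent-free scale)."""
        return np.array([self.value_at(float(k)) for k in range(horizon + 1)])


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    return times, events


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimate of the survival function under right censoring.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct death times
    ``t_i`` with ``d_i`` deaths and ``n_i`` at risk (every subject with
    follow-up >= ``t_i``, so same-time censorings count as at risk).
    """
    times, events = _validate_times_events(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    n = times.size
    # at risk at t_i: everyone whose follow-up is >= t_i
    at_risk = n - np.searchsorted(times, event_times, side="left")
    deaths = np.array([int(np.sum(events & (times == t))) for t in event_times])
    frac = np.where(at_risk > 0, deaths / np.maximum(at_risk, 1), 0.0)
    survival = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = deaths / (at_risk * (at_risk - deaths))
        gw_terms = np.where(np.isfinite(gw_terms), gw_terms, 0.0)
    greenwood = survival**2 * np.cumsum(gw_terms)
    return SurvivalCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        events=deaths,
        greenwood_var=greenwood,
        n=n,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value.

    At each distinct death time the observed group-A deaths are compared with
    the hypergeometric expectation given the pooled risk sets; the statistic
    is ``(sum(O_A - E_A))^2 / sum(V)``.  With no deaths in either group the
    test degenerates to statistic 0, p = 1.
    """
    ta, ea = _validate_times_events(times_a, events_a)
    tb, eb = _validate_times_events(times_b, events_b)
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    event_times = np.unique(all_times[all_events])
    if event_times.size == 0:
        return 0.0, 1.0
    ta_sorted = np.sort(ta)
    tb_sorted = np.sort(tb)
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = ta.size - np.searchsorted(ta_sorted, t, side="left")
        n2 = tb.size - np.searchsorted(tb_sorted, t, side="left")
        ntot = n1 + n2
        d1 = int(np.sum(ea & (ta == t)))
        d2 = int(np.sum(eb & (tb == t)))
        d = d1 + d2
        if ntot == 0 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / ntot
        if ntot > 1:
            var += d * (n1 / ntot) * (n2 / ntot) * (ntot - d) / (ntot - 1)
    if var == 0.0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def chisquare_proportions(contingency) -> tuple[float, float]:
    """Pearson chi-square for an r x c count table, no continuity correction.

    Degrees of freedom ``(r-1)(c-1)``; a zero marginal row or column makes
    the expected counts degenerate and raises.
    """
    obs = np.asarray(contingency, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margin: zero row or column total")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, float(stats.chi2.sf(statistic, df=df))
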