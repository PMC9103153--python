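"""Survival stratification: Kaplan-Meier, log-rank, optimal-cutoff scan.

The dichotomization procedure mirrors the Cutoff Finder approach: every
midpoint between consecutive distinct marker values that leaves at least a
``min_group_frac`` fraction of the cohort on each side is an admissible
cutoff; the log-rank test is evaluated at each; the cutoff minimizing the
log-rank p is reported. The reported optimal p is UNADJUSTED for the scan
multiplicity — minimizing over many correlated tests makes it
anti-conservative, which is a documented property of the method, not
corrected here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cernet")

__all__ = [
    "km_estimate",
    "logrank_test",
    "optimal_cutoff",
    "spearman_rho",
    "CutoffScanResult",
]


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    return t, e


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of the survival function.

    Returns one row per distinct *event* time with columns
    ``time, n_at_risk, n_events, survival``; censored times reduce the risk
    set but create no step. S(0) = 1 and S is non-increasing by
    construction. Tied censorings at an event time remain in the risk set
    at that time.
    """
    t, e = _as_time_event(times, events)
    event_times = np.unique(t[e])
    rows = []
    s = 1.0
    for ti in event_times:
        n_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & e))
        s *= 1.0 - d / n_risk
        rows.append((float(ti), n_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    The statistic is (O_A - E_A)^2 / V with the hypergeometric variance
    summed over distinct event times; p from chi-square with 1 df. With no
    comparable risk sets (zero variance) the test is uninformative and
    returns p = 1 with a warning.
    """
    ta, ea = _as_time_event(times_a, events_a)
    tb, eb = _as_time_event(times_b, events_b)
    if not (ea.any() or eb.any()):
        warnings.warn("log-rank: no events in either group; p = 1", stacklevel=2)
        return 0.0, 1.0

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(t_all[e_all])

    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = t_all >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (t_all == ti) & e_all
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        warnings.warn("log-rank: zero variance (no comparable risk sets); p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutoffScanResult:
    """Result of the optimal-cutoff scan over a continuous marker.

    ``optimal_p`` is the minimum log-rank p over the admissible cutoffs and
    is unadjusted for the multiplicity of the scan.
    """

    cutoffs: np.ndarray
    logrank_p: np.ndarray
    group_sizes: list[tuple[int, int]]
    optimal_cutoff: float
    optimal_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "logrank_p": self.logrank_p,
                "n_low": [g[0] for g in self.group_sizes],
                "n_high": [g[1] for g in self.group_sizes],
            }
        )


def optimal_cutoff(table: pd.DataFrame, min_group_frac: float = 0.10) -> CutoffScanResult:
    """Scan all admissible expression cutoffs and pick the log-rank argmin.

    ``table`` needs columns ``time``, ``event``, ``expression``. Candidate
    cutoffs are midpoints between consecutive distinct expression values
    whose induced split leaves at least ``min_group_frac`` of samples on
    each side. Ties in the minimum p are broken toward the cutoff closest
    to the median expression (then toward the smaller cutoff).
    """
    if not 0.0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in (0, 0.5)")
    t, e = _as_time_event(table["time"], table["event"])
    x = np.asarray(table["expression"], dtype=float)
    n = x.size

    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs, pvals, sizes = [], [], []
    for c in mids:
        low = x <= c
        n_low = int(low.sum())
        n_high = n - n_low
        if n_low < min_group_frac * n or n_high < min_group_frac * n:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = logrank_test(t[low], e[low], t[~low], e[~low])
        cutoffs.append(float(c))
        pvals.append(p)
        sizes.append((n_low, n_high))
    if not cutoffs:
        raise ValueError(
            "no admissible cutoff: expression too concentrated for "
            f"min_group_frac={min_group_frac}"
        )
    cutoffs_arr = np.asarray(cutoffs)
    pvals_arr = np.asarray(pvals)
    best_p = pvals_arr.min()
    tied = np.flatnonzero(pvals_arr == best_p)
    med = float(np.median(x))
    # toward the median cutoff, then toward the smaller value
    order = sorted(tied, key=lambda i: (abs(cutoffs_arr[i] - med), cutoffs_arr[i]))
    best = order[0]
    return CutoffScanResult(
        cutoffs=cutoffs_arr,
        logrank_p=pvals_arr,
        group_sizes=sizes,
        optimal_cutoff=float(cutoffs_arr[best]),
        optimal_p=float(best_p),
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; p via t-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired scores must have equal length")
    if x.size < 3:
        raise ValueError("spearman_rho requires at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
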