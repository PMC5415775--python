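"""Kaplan-Meier estimation and the two-group log-rank test."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import chi2

from ..errors import ConfigError
from .fisher import TestResult


@dataclass
class KMCurve:
    """Product-limit estimate for one group: S(t) step function."""
    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    n_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); S(0) = 1, right-continuous steps at event times."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(times: np.ndarray) -> None:
    if (times < 0).any():
        raise ConfigError("negative survival time")


def km_estimate(times: Sequence[float], events: Sequence[int],
                group: Optional[Sequence] = None) -> Dict[object, KMCurve]:
    """Kaplan-Meier curves, one per group (single group "all" if None)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    _check_times(times)
    groups = np.asarray(group) if group is not None else np.array(["all"] * len(times))
    out: Dict[object, KMCurve] = {}
    for g in sorted(set(groups.tolist()), key=str):
        sel = groups == g
        t, e = times[sel], events[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        ev_times = np.unique(t[e == 1])
        surv = []
        n_risk = []
        n_ev = []
        s = 1.0
        for et in ev_times:
            at_risk = int((t >= et).sum())
            d = int(((t == et) & (e == 1)).sum())
            s *= 1.0 - d / at_risk
            surv.append(s)
            n_risk.append(at_risk)
            n_ev.append(d)
        out[g] = KMCurve(ev_times, np.array(surv), np.array(n_risk, dtype=int),
                         np.array(n_ev, dtype=int))
    return out


def logrank_test(times: Sequence[float], events: Sequence[int],
                 group: Sequence) -> TestResult:
    """Two-group log-rank test: chi-squared O-E statistic on 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(group)
    _check_times(times)
    labels = sorted(set(groups.tolist()), key=str)
    if len(labels) != 2:
        raise ConfigError(f"log-rank test needs exactly two groups, got {len(labels)}")
    if events.sum() < 1:
        raise ConfigError("log-rank test needs at least one event")
    in1 = groups == labels[0]

    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == et) & (events == 1)).sum())
        d1 = int(((times == et) & (events == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return TestResult(p_value=1.0, method="log-rank", statistic=0.0)
    stat = o_minus_e ** 2 / var
    return TestResult(p_value=float(chi2.sf(stat, df=1)), method="log-rank",
                      statistic=float(stat))
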