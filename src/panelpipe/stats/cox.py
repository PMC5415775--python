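"""Cox proportional-hazards regression by Newton maximization of the
partial likelihood, with Breslow (default) or Efron tie handling, plus
forward stepwise covariate selection by likelihood-ratio testing."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ..errors import ConfigError, ConvergenceError

MAX_ITER = 50
SCORE_TOL = 1e-6
_Z95 = 1.959963984540054


@dataclass
class StepRecord:
    step: int
    covariate: str
    lr_statistic: float
    p_value: float
    entered: bool


@dataclass
class CoxModel:
    covariates: List[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    steps: List[StepRecord] = field(default_factory=list)

    @property
    def rr(self) -> np.ndarray:
        """Relative risks exp(coef)."""
        return np.exp(self.coef)

    @property
    def ci(self) -> np.ndarray:
        """Wald 95% CIs for the relative risks, shape (p, 2)."""
        lo = np.exp(self.coef - _Z95 * self.se)
        hi = np.exp(self.coef + _Z95 * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.ci if len(self.covariates) else np.zeros((0, 2))
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "rr": self.rr,
            "ci_lower": ci[:, 0] if len(self.covariates) else [],
            "ci_upper": ci[:, 1] if len(self.covariates) else [],
        }, index=self.covariates)


def _prepare(times, events, X) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if (times < 0).any():
        raise ConfigError("negative survival time")
    if events.sum() < 1:
        raise ConfigError("no events")
    if not np.isfinite(X).all():
        raise ConfigError("non-finite covariate values")
    return times, events, X, names


def _loglik_score_info(beta: np.ndarray, times: np.ndarray, events: np.ndarray,
                       X: np.ndarray, ties: str) -> Tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score vector, and observed information."""
    n, p = X.shape
    order = np.argsort(-times, kind="stable")  # descending: risk sets are prefixes
    t_s, e_s, X_s = times[order], events[order], X[order]
    eta = X_s @ beta
    w = np.exp(eta)
    wx = X_s * w[:, None]
    wxx = np.einsum("ij,ik,i->ijk", X_s, X_s, w)

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # everyone with this time joins the risk set
        s0 += w[i:j].sum()
        s1 += wx[i:j].sum(axis=0)
        s2 += wxx[i:j].sum(axis=0)
        ev = np.flatnonzero(e_s[i:j] == 1) + i
        d = len(ev)
        if d:
            sx = X_s[ev].sum(axis=0)
            ll += float(eta[ev].sum())
            if ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                score += sx - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
            elif ties == "efron":
                wd = w[ev].sum()
                s1d = wx[ev].sum(axis=0)
                s2d = wxx[ev].sum(axis=0)
                for k in range(d):
                    f = k / d
                    s0k = s0 - f * wd
                    s1k = s1 - f * s1d
                    s2k = s2 - f * s2d
                    ll -= np.log(s0k)
                    score += sx / d - s1k / s0k
                    info += s2k / s0k - np.outer(s1k, s1k) / s0k ** 2
            else:
                raise ConfigError(f"unknown tie method {ties!r}")
        i = j
    return ll, score, info


def _null_loglik(times: np.ndarray, events: np.ndarray, ties: str) -> float:
    ll, _, _ = _loglik_score_info(np.zeros(1), times, events,
                                  np.zeros((len(times), 1)), ties)
    return ll


def cox_fit(times, events, X, ties: str = "breslow",
            max_iter: int = MAX_ITER, tol: float = SCORE_TOL) -> CoxModel:
    """Fit a Cox model by Newton iteration.

    Convergence requires max |score| < ``tol`` within ``max_iter``
    iterations; separation or a singular information matrix raises
    :class:`ConvergenceError`.
    """
    times, events, X, names = _prepare(times, events, X)
    n, p = X.shape
    beta = np.zeros(p)
    ll_null = _null_loglik(times, events, ties)
    ll, score, info = _loglik_score_info(beta, times, events, X, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            break
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, score_new, info_new = _loglik_score_info(cand, times, events, X, ties)
            # near the optimum the loglik gain falls below float resolution;
            # a shrinking score norm is equally valid progress
            if np.isfinite(ll_new) and (
                    ll_new >= ll - 1e-9 * max(1.0, abs(ll))
                    or np.max(np.abs(score_new)) < np.max(np.abs(score))):
                break
            step /= 2.0
        else:
            raise ConvergenceError("step-halving failed")
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > 30:
            raise ConvergenceError("separation: coefficient diverging")
    else:
        if np.max(np.abs(score)) >= tol:
            raise ConvergenceError(f"no convergence in {max_iter} iterations")
    if p and np.max(np.abs(beta)) > 15:
        # monotone likelihood: the score can vanish on the plateau while
        # the coefficient runs away
        raise ConvergenceError("separation: coefficient unbounded")
    # pinv: degenerate covariates (e.g. identically zero) converge with a
    # singular information matrix and get SE 0 rather than a failure
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxModel(covariates=names, coef=beta, se=se, loglik=float(ll),
                    loglik_null=float(ll_null), n=n, n_events=int(events.sum()),
                    ties=ties, n_iter=n_iter)


def cox_stepwise_forward_lr(times, events, X: Union[pd.DataFrame, np.ndarray],
                            candidates: Optional[Sequence[str]] = None,
                            p_enter: float = 0.05,
                            ties: str = "breslow") -> CoxModel:
    """Forward stepwise Cox model selection by likelihood-ratio tests.

    Starting from the empty model, each step adds the candidate with the
    smallest LR p-value (2 x loglik gain against chi-squared on 1 df) if
    it is below ``p_enter``; selection stops otherwise.  There is no
    removal step.  The per-step trail is recorded on the returned model.
    """
    times_a, events_a, X_a, names = _prepare(times, events, X)
    if candidates is None:
        candidates = names
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ConfigError("stepwise selection needs >= 2 candidate covariates")
    unknown = set(candidates) - set(names)
    if unknown:
        raise ConfigError(f"unknown candidate covariates: {sorted(unknown)}")
    col = {name: i for i, name in enumerate(names)}

    included: List[str] = []
    trail: List[StepRecord] = []
    ll_current = _null_loglik(times_a, events_a, ties)
    step_no = 0
    while True:
        remaining = [c for c in candidates if c not in included]
        if not remaining:
            break
        best: Optional[Tuple[float, float, str, CoxModel]] = None
        for cand in remaining:
            cols = [col[c] for c in included + [cand]]
            try:
                model = cox_fit(times_a, events_a, X_a[:, cols], ties=ties)
            except ConvergenceError:
                continue
            lr = 2.0 * (model.loglik - ll_current)
            p = float(chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[0]:
                best = (p, lr, cand, model)
        if best is None:
            break
        p, lr, cand, model = best
        step_no += 1
        entered = p < p_enter
        trail.append(StepRecord(step_no, cand, lr, p, entered))
        if not entered:
            break
        included.append(cand)
        ll_current = model.loglik

    if included:
        cols = [col[c] for c in included]
        final = cox_fit(times_a, events_a, X_a[:, cols], ties=ties)
        final.covariates = included
    else:
        final = CoxModel(covariates=[], coef=np.zeros(0), se=np.zeros(0),
                         loglik=float(ll_current), loglik_null=float(ll_current),
                         n=len(times_a), n_events=int(events_a.sum()),
                         ties=ties, n_iter=0)
    final.steps = trail
    return final
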