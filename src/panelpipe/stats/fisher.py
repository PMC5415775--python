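"""Fisher exact tests for 2x2 and general r x c tables.

Two-sided p-values follow the probability-based convention: the sum of
point probabilities (margins fixed) of all tables at most as probable as
the observed one, with a small relative tolerance for floating-point
ties.  For r x c tables the fixed-margin space can be enumerated
exactly, or the p-value estimated by Monte-Carlo sampling of tables
under the fixed-margin null (sequential multivariate hypergeometric
sampling, equivalent in distribution to random permutation pairing of
row and column labels) with the add-one estimator
p = (1 + #{P(sampled) <= P(observed)}) / (replicates + 1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

from ..errors import ConfigError
from .contingency import ContingencyTable

#: Monte-Carlo replicate default matching the study configuration.
DEFAULT_MC_REPLICATES = 25_000_000
#: Relative tolerance for probability ties (applied on the log scale).
TIE_TOLERANCE = 1e-7
#: Largest fixed-margin state space allowed for exact enumeration.
MAX_ENUM_STATES = 10_000_000


@dataclass
class TestResult:
    p_value: float
    method: str                       # "exact-enumeration" | "monte-carlo" | ...
    statistic: Optional[float] = None
    replicates: Optional[int] = None
    seed: Optional[int] = None
    mc_se: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ConfigError(f"p-value {self.p_value} outside [0,1]")


def _as_array(table: Union[ContingencyTable, np.ndarray, list]) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        arr = table.counts
    else:
        arr = np.asarray(table, dtype=int)
    if arr.ndim != 2:
        raise ConfigError("table must be 2-dimensional")
    if (arr < 0).any():
        raise ConfigError("table entries must be non-negative")
    return arr


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table via the hypergeometric
    distribution (probability-based two-sided convention)."""
    t = _as_array(table)
    if t.shape != (2, 2):
        raise ConfigError(f"expected a 2x2 table, got {t.shape}")
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    if n == 0:
        raise ConfigError("empty table")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(t[0, 0], n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + TIE_TOLERANCE)].sum())
    return TestResult(p_value=min(p, 1.0), method="exact-enumeration")


def _log_prob_core(cells: np.ndarray) -> float:
    """log P(table) minus the margin-dependent constant."""
    return -float(gammaln(cells + 1.0).sum())


def enumerate_rxc(table, max_states: int = MAX_ENUM_STATES) -> TestResult:
    """Exact two-sided p over all tables with the observed margins."""
    t = _as_array(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    r, c = t.shape
    n = int(t.sum())
    lfact = gammaln(np.arange(n + 2, dtype=float) + 1.0)  # lfact[k] = log k!
    const = float(lfact[rows].sum() + lfact[cols].sum() - lfact[n])
    obs_core = _log_prob_core(t)
    threshold = obs_core + TIE_TOLERANCE
    acc = {"p": 0.0, "states": 0}

    def rec(i: int, remcols: list, core: float) -> None:
        if i == r - 1:
            acc["states"] += 1
            if acc["states"] > max_states:
                raise ConfigError(
                    "fixed-margin table space too large to enumerate; "
                    "use the monte-carlo method")
            core2 = core - sum(lfact[k] for k in remcols)
            if core2 <= threshold:
                acc["p"] += float(np.exp(const + core2))
            return

        def comp(j: int, left: int, rc: list, sub: float) -> None:
            if j == c - 1:
                if left <= rc[j]:
                    rc2 = rc.copy()
                    rc2[j] -= left
                    rec(i + 1, rc2, sub - lfact[left])
                return
            for x in range(min(left, rc[j]) + 1):
                rc2 = rc.copy()
                rc2[j] -= x
                comp(j + 1, left - x, rc2, sub - lfact[x])

        comp(0, int(rows[i]), remcols, core)

    rec(0, [int(x) for x in cols], 0.0)
    return TestResult(p_value=min(acc["p"], 1.0), method="exact-enumeration")


def _sample_tables_logprob(rows: np.ndarray, cols: np.ndarray, m: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Core log-probabilities of m fixed-margin tables sampled under the
    null, via sequential multivariate hypergeometric allocation."""
    r, c = len(rows), len(cols)
    remaining = np.tile(cols, (m, 1)).astype(np.int64)
    logp = np.zeros(m)
    for i in range(r - 1):
        quota = np.full(m, rows[i], dtype=np.int64)
        for j in range(c - 1):
            ngood = remaining[:, j]
            nbad = remaining[:, j + 1:].sum(axis=1)
            x = rng.hypergeometric(ngood, nbad, quota)
            logp -= gammaln(x + 1.0)
            remaining[:, j] -= x
            quota -= x
        logp -= gammaln(quota + 1.0)
        remaining[:, c - 1] -= quota
    logp -= gammaln(remaining + 1.0).sum(axis=1)
    return logp


def monte_carlo_rxc(table, replicates: int = DEFAULT_MC_REPLICATES,
                    seed: Optional[int] = None,
                    chunk: int = 1_000_000) -> TestResult:
    """Monte-Carlo two-sided Fisher p for an r x c table."""
    t = _as_array(table)
    rows = t.sum(axis=1).astype(np.int64)
    cols = t.sum(axis=0).astype(np.int64)
    if (rows == 0).any() or (cols == 0).any():
        raise ConfigError("drop empty rows/columns before testing")
    obs_core = _log_prob_core(t)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        logp = _sample_tables_logprob(rows, cols, m, rng)
        hits += int((logp <= obs_core + TIE_TOLERANCE).sum())
        done += m
    p = (1.0 + hits) / (replicates + 1.0)
    se = float(np.sqrt(p * (1.0 - p) / replicates))
    return TestResult(p_value=p, method="monte-carlo", replicates=replicates,
                      seed=seed, mc_se=se)


def fisher_exact_rxc(table, method: str = "enumerate",
                     replicates: int = DEFAULT_MC_REPLICATES,
                     seed: Optional[int] = None,
                     max_states: int = MAX_ENUM_STATES,
                     chunk: int = 1_000_000) -> TestResult:
    """Fisher exact test on an r x c table.

    ``method`` is ``"enumerate"`` (exact; errors out when the
    fixed-margin space exceeds ``max_states``) or ``"monte-carlo"``.
    """
    if method == "enumerate":
        return enumerate_rxc(table, max_states=max_states)
    if method == "monte-carlo":
        return monte_carlo_rxc(table, replicates=replicates, seed=seed, chunk=chunk)
    raise ConfigError(f"unknown method {method!r}")
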