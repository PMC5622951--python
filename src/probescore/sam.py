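"""One-class Significance Analysis of Microarrays (SAM) on replicate S-scores.

Tests, per transcript cluster, whether the mean replicate S-score differs
from zero.  The statistic is the fudge-factor-stabilized one-sample t,

    d_i = x̄_i / (se_i + s0),

with s0 chosen on the Tusher grid of se percentiles to make the spread of d
as independent of se as possible.  The null distribution comes from sign
flips of the replicate columns (the one-class design has no labels to
permute): when the full 2^k enumeration fits inside the permutation budget
it is used exactly and the result is seed-independent.  FDR at a symmetric
threshold Δ is estimated SAM-style as

    FDR(Δ) = π̂0 · median_b #{i : |d_i^b| ≥ Δ} / #{i : |d_i| ≥ Δ},

with π̂0 estimated from the central 50% of the observed d against the null
and capped at 1; a cluster's q-value is the smallest estimated FDR at which
it would be called.  Calling is two-sided with a single symmetric Δ by
default (asymmetric cutoffs exist in full SAM but are not the default here).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe_io import ValidationError
from .sscore import SScoreSet

logger = logging.getLogger(__name__)

S0_PERCENTILES = np.arange(0, 101, 5)


def _as_matrix(sscores: SScoreSet | pd.DataFrame) -> pd.DataFrame:
    return sscores.scores if isinstance(sscores, SScoreSet) else sscores


@dataclass
class SamResult:
    """Output of a one-class SAM run at a target FDR."""

    d: pd.Series
    s0: float
    delta: float
    q_value: pd.Series
    n_permutations: int
    exact: bool
    pi0: float
    seed: int | None
    target_fdr: float

    @property
    def called_set(self) -> list[str]:
        return list(self.d.index[np.abs(self.d.to_numpy()) >= self.delta])

    def to_frame(self) -> pd.DataFrame:
        called = np.abs(self.d.to_numpy()) >= self.delta
        return pd.DataFrame(
            {"d": self.d, "q": self.q_value, "called": called}, index=self.d.index
        )


def _mean_se(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = x.shape[1]
    mean = x.mean(axis=1)
    se = x.std(axis=1, ddof=1) / np.sqrt(k)
    return mean, se


def compute_d(sscores: SScoreSet | pd.DataFrame, s0: float) -> pd.Series:
    """One-class d statistic per cluster: row mean over (row SE + s0)."""
    m = _as_matrix(sscores)
    if m.shape[1] < 2:
        raise ValidationError("need >= 2 replicate columns for a standard error")
    mean, se = _mean_se(m.to_numpy(dtype=float))
    denom = se + s0
    if np.any(denom == 0):
        raise ValidationError("zero denominator: se = 0 with s0 = 0")
    return pd.Series(mean / denom, index=m.index, name="d")


def choose_s0(
    sscores: SScoreSet | pd.DataFrame, n_windows: int = 100, tie_tol: float = 0.05
) -> float:
    """Tusher s0: the se percentile minimizing the coefficient of variation of
    the d statistic's MAD across se quantile windows.

    Windows are defined by fixed se-quantile edges (inverted-CDF quantiles),
    which makes the selection invariant to row duplication.  Among candidates
    whose CV is within ``tie_tol`` (relative) of the minimum, the smallest s0
    is chosen — on homoscedastic data the criterion is flat and the smallest
    stabilizer is the conservative choice.
    """
    m = _as_matrix(sscores)
    if m.shape[0] < 10:
        raise ValidationError("need >= 10 rows to tune s0")
    x = m.to_numpy(dtype=float)
    mean, se = _mean_se(x)
    if np.ptp(se) == 0:
        return float(se[0])
    candidates = np.unique(np.quantile(se, S0_PERCENTILES / 100.0, method="inverted_cdf"))
    edges = np.quantile(se, np.linspace(0, 1, n_windows + 1)[1:-1], method="inverted_cdf")
    win = np.searchsorted(edges, se, side="left")
    wins = [np.flatnonzero(win == w) for w in np.unique(win)]
    wins = [w for w in wins if len(w) > 1]
    if len(wins) < 2:
        logger.warning("too few se windows to tune s0; falling back to median se")
        return float(np.median(se))
    cvs = np.full(len(candidates), np.inf)
    for i, s0 in enumerate(candidates):
        d = mean / (se + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in wins])
        mu = mads.mean()
        if mu > 0:
            cvs[i] = mads.std(ddof=1) / mu
    best = cvs.min()
    if not np.isfinite(best):
        return float(np.median(se))
    return float(candidates[np.flatnonzero(cvs <= best * (1.0 + tie_tol))[0]])


def _sign_patterns(k: int, n_perm: int, seed: int | None) -> tuple[np.ndarray, bool]:
    if 2 ** k <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_perm, k))
    return signs, False


def permutation_null(
    sscores: SScoreSet | pd.DataFrame,
    s0: float,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, bool]:
    """Sign-flip null d matrix (clusters × permutations).

    Each permutation multiplies every replicate column by ±1 and recomputes d
    with the same s0.  If 2^k ≤ n_perm the full enumeration is used exactly
    (seed-irrelevant); otherwise patterns are sampled.
    """
    m = _as_matrix(sscores)
    x = m.to_numpy(dtype=float)
    k = x.shape[1]
    signs, exact = _sign_patterns(k, n_perm, seed)
    null = np.empty((x.shape[0], signs.shape[0]))
    for b, sg in enumerate(signs):
        mean, se = _mean_se(x * sg)
        null[:, b] = mean / (se + s0)
    return null, exact


def _estimate_pi0(d_obs: np.ndarray, null: np.ndarray) -> float:
    """π̂0 from the central 50% of the null: fraction of observed d falling in
    the null interquartile range, divided by 0.5; capped at 1."""
    q25, q75 = np.quantile(null, [0.25, 0.75])
    frac = np.mean((d_obs >= q25) & (d_obs <= q75))
    return float(min(1.0, frac / 0.5)) if frac > 0 else 1.0


def call_significant(
    d: pd.Series,
    null: np.ndarray,
    target_fdr: float = 0.05,
    s0: float = np.nan,
    n_permutations: int | None = None,
    exact: bool = True,
    seed: int | None = None,
) -> SamResult:
    """Select the smallest symmetric delta achieving the target FDR and
    assign per-cluster q-values."""
    d_obs = d.to_numpy(dtype=float)
    abs_d = np.abs(d_obs)
    abs_null = np.abs(null)
    pi0 = _estimate_pi0(d_obs, null)

    # candidate thresholds: each observed |d| (calling exactly the clusters at
    # or beyond it), evaluated from the largest down with a running minimum
    order = np.argsort(abs_d)[::-1]
    sorted_abs = abs_d[order]
    asc = sorted_abs[::-1]
    obs_counts = len(abs_d) - np.searchsorted(asc, sorted_abs, side="left")
    # per-permutation counts of null |d| >= threshold, then median across perms
    n_null_rows, n_perm_cols = abs_null.shape
    sorted_cols = np.sort(abs_null, axis=0)
    counts = np.empty((len(sorted_abs), n_perm_cols))
    for b in range(n_perm_cols):
        counts[:, b] = n_null_rows - np.searchsorted(sorted_cols[:, b], sorted_abs, side="left")
    med_counts = np.median(counts, axis=1)
    fdr_at = np.minimum(1.0, pi0 * med_counts / obs_counts)
    # a cluster is called at every threshold at or below its |d|, so its
    # q-value is the minimum FDR over thresholds from its own downward
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    achieving = sorted_abs[q_sorted <= target_fdr]
    if len(achieving):
        delta = float(achieving[-1])  # smallest threshold still meeting target
    else:
        delta = np.inf
        logger.info("no delta achieves FDR <= %.3g; empty called set", target_fdr)

    return SamResult(
        d=d,
        s0=float(s0),
        delta=delta,
        q_value=pd.Series(q, index=d.index, name="q"),
        n_permutations=n_permutations if n_permutations is not None else null.shape[1],
        exact=exact,
        pi0=pi0,
        seed=seed,
        target_fdr=target_fdr,
    )


def one_class_sam(
    sscores: SScoreSet | pd.DataFrame,
    target_fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    s0: float | None = None,
) -> SamResult:
    """End-to-end one-class SAM: tune s0, build the sign-flip null, call at FDR."""
    m = _as_matrix(sscores)
    if s0 is None:
        s0 = choose_s0(m)
    d = compute_d(m, s0)
    null, exact = permutation_null(m, s0, n_perm=n_perm, seed=seed)
    return call_significant(
        d, null, target_fdr=target_fdr, s0=s0,
        n_permutations=null.shape[1], exact=exact, seed=seed,
    )
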