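"""Gene-level track: cluster summarization and two-factor linear models.

Summarization is a documented stand-in for vendor signal generation:
log2(x+1) transform, quantile normalization across samples, then a per-cluster
median polish (probe effect + sample effect), returning the sample effects as
the cluster's log2 expression.

Per-cluster testing fits a 2×2 treatment × sex linear model with sum-to-zero
contrasts and reports Type-III F tests for both main effects and the
interaction.  Because each term carries one degree of freedom, the Type-III F
is the squared t of the corresponding coefficient; the fit is vectorized over
clusters.  Residual variances are moderated by default with an
empirical-Bayes scaled-inverse-chi-square prior (prior df and scale estimated
by moment matching on log variances), giving limma-style moderated F tests;
ordinary ANOVA F is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .probe_io import DesignTable, ProbeMatrix, ValidationError

TERMS = ("treatment", "sex", "interaction")


# ---------------------------------------------------------------------------
# Summarization
# ---------------------------------------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution."""
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    return pd.DataFrame(mean_sorted[ranks], index=df.index, columns=df.columns)


def median_polish(mat: np.ndarray, max_iter: int = 10, tol: float = 0.01) -> np.ndarray:
    """Robust additive decomposition; returns overall + column (sample) effects."""
    resid = mat.astype(float).copy()
    overall = 0.0
    row_eff = np.zeros(mat.shape[0])
    col_eff = np.zeros(mat.shape[1])
    last = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row_eff += rmed
        resid -= rmed[:, None]
        cmed_of_row = np.median(row_eff)
        overall += cmed_of_row
        row_eff -= cmed_of_row
        cmed = np.median(resid, axis=0)
        col_eff += cmed
        resid -= cmed[None, :]
        rmed_of_col = np.median(col_eff)
        overall += rmed_of_col
        col_eff -= rmed_of_col
        total = np.abs(resid).sum()
        if last == 0 or abs(last - total) < tol * last:
            break
        last = total
    return overall + col_eff


def summarize_clusters(
    pm: ProbeMatrix,
    quantile_normalization: bool = True,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Summarize probe intensities into a clusters × samples log2 expression matrix."""
    logged = np.log2(pm.intensities.astype(float) + log_offset)
    if quantile_normalization:
        logged = quantile_normalize(logged)
    rows = {}
    vals = logged.to_numpy()
    codes, uniques = pd.factorize(pm.cluster_map.to_numpy())
    for g, cid in enumerate(uniques):
        block = vals[codes == g]
        rows[cid] = block[0] if block.shape[0] == 1 else median_polish(block)
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=logged.columns)
    expr.index.name = "cluster_id"
    return expr


# ---------------------------------------------------------------------------
# Two-factor model
# ---------------------------------------------------------------------------

@dataclass
class LmResult:
    """Per-cluster effects, F statistics and p-values for the 2×2 model."""

    table: pd.DataFrame          # effect_/F_/p_ columns per term
    moderated: bool
    df_resid: float
    df_prior: float = 0.0
    s2_prior: float = np.nan

    def p(self, term: str) -> pd.Series:
        return self.table[f"p_{term}"]


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-inverse-chi-square variance prior.

    Returns (prior df d0, prior scale s0²); d0 = inf means complete pooling.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s02 = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s02)


def fit_two_factor(
    expr: pd.DataFrame,
    design: DesignTable,
    age_group: str | None = None,
    moderated: bool = True,
    prior_df: float | None = None,
) -> LmResult:
    """Per-cluster treatment × sex model with Type-III tests, one age at a time.

    ``prior_df`` overrides the estimated prior df (np.inf pools variances
    completely); ``moderated=False`` gives the ordinary per-cluster ANOVA F.
    """
    t = design.table.set_index("sample_id").loc[list(expr.columns)]
    if age_group is not None:
        keep = t["age_group"] == age_group
        t = t[keep]
        expr = expr.loc[:, keep.index[keep]]
    if t["age_group"].nunique() > 1:
        raise ValidationError("design spans multiple ages; pass age_group to analyze one")

    trt = np.where(t["treatment"] == "ethanol", 1.0, -1.0)
    sex = np.where(t["sex"] == "M", 1.0, -1.0)
    cells = pd.Series(zip(t["treatment"], t["sex"])).value_counts()
    for a in ("ethanol", "control"):
        for s in ("M", "F"):
            if cells.get((a, s), 0) == 0:
                raise ValidationError(f"empty design cell (treatment={a}, sex={s})")
    if (cells >= 2).sum() < 3:
        raise ValidationError("need >= 2 samples in at least 3 of the 4 design cells")

    X = np.column_stack([np.ones_like(trt), trt, sex, trt * sex])
    n, p = X.shape
    if n <= p:
        raise ValidationError("not enough samples for residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = X @ xtx_inv                       # n × p
    Y = expr.to_numpy(dtype=float)
    B = Y @ hat                             # clusters × p coefficients
    resid = Y - B @ X.T
    df_resid = n - p
    s2 = np.einsum("ij,ij->i", resid, resid) / df_resid

    d0, s02 = 0.0, np.nan
    if moderated:
        if prior_df is not None:
            d0 = float(prior_df)
            s02 = float(np.mean(s2)) if not np.isfinite(d0) else fit_variance_prior(s2, df_resid)[1]
        else:
            d0, s02 = fit_variance_prior(s2, df_resid)
        if np.isfinite(d0):
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        else:
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
    else:
        s2_post, df_total = s2, df_resid

    out = {}
    for j, term in enumerate(TERMS, start=1):
        cjj = xtx_inv[j, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(s2_post > 0, B[:, j] ** 2 / (s2_post * cjj), 0.0)
        if np.isfinite(df_total):
            pval = stats.f.sf(F, 1, df_total)
        else:
            pval = stats.chi2.sf(F, 1)
        out[f"effect_{term}"] = B[:, j]
        out[f"F_{term}"] = F
        out[f"p_{term}"] = np.clip(pval, np.finfo(float).tiny, 1.0)
    out["s2"] = s2
    out["s2_post"] = s2_post
    table = pd.DataFrame(out, index=expr.index)
    return LmResult(
        table=table, moderated=moderated, df_resid=df_resid,
        df_prior=d0 if moderated else 0.0, s2_prior=s02,
    )


def select_significant(lm: LmResult, alpha: float = 0.01, term: str = "treatment") -> list[str]:
    """Clusters with uncorrected p_term below alpha, sorted by p."""
    if term not in TERMS:
        raise ValidationError(f"term must be one of {TERMS}")
    p = lm.p(term)
    hits = p[p < alpha].sort_values()
    return list(hits.index)


def intersect_lists(a, b) -> tuple[list, list, list]:
    """Set-semantics intersection: (common, a_only, b_only), each sorted."""
    sa, sb = set(a), set(b)
    return sorted(sa & sb), sorted(sa - sb), sorted(sb - sa)
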