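"""Behavioral endpoints and their statistics.

Endpoint derivations: novel-object discrimination index, loss-of-righting-
reflex (LORR) duration, and light–dark box percentage metrics.  Group
comparisons use two- or three-way Type-III ANOVA (sum-to-zero contrasts, via
statsmodels) followed by Student–Newman–Keuls (SNK) stepwise post hoc tests.
SNK critical values are computed numerically from the studentized-range
distribution — not hard-coded tables — so any (α, span, df) combination is
supported; unbalanced cells use the harmonic-mean cell size.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .probe_io import ValidationError


class DataError(ValueError):
    """A measurement violates a physical constraint (e.g. recovery before onset)."""


# ---------------------------------------------------------------------------
# Endpoint derivations
# ---------------------------------------------------------------------------

def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """(novel − familiar) / (novel + familiar) interaction time; in [−1, 1].

    Zero means no discrimination; zero or negative values indicate failure to
    recognize the novel object.
    """
    total = t_novel + t_familiar
    if total <= 0:
        raise DataError("total interaction time must be positive to define the index")
    return (t_novel - t_familiar) / total


def apply_nor_exclusion(
    table: pd.DataFrame, min_training_s: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop animals that did not investigate objects for *more than* 10 s in
    training; an exactly-10.0-s animal is excluded.  Returns (filtered table,
    excluded animal ids)."""
    if "training_investigation_s" not in table.columns:
        raise ValidationError("table lacks column 'training_investigation_s'")
    keep = table["training_investigation_s"] > min_training_s
    excluded = list(table.loc[~keep, "animal_id"])
    return table[keep].reset_index(drop=True), excluded


def lorr_duration(onset_s: float, recovery_s: float) -> float:
    """Sedation duration: recovery time minus LORR onset time, in seconds."""
    if recovery_s < onset_s:
        raise DataError("recovery time precedes LORR onset")
    return recovery_s - onset_s


def lightdark_metrics(
    time_light: float, time_total: float, dist_light: float, dist_total: float
) -> tuple[float, float]:
    """Percent time and percent distance in the light compartment."""
    if time_total <= 0 or dist_total <= 0:
        raise DataError("totals must be positive")
    if time_light > time_total or dist_light > dist_total:
        raise DataError("part exceeds total")
    return 100.0 * time_light / time_total, 100.0 * dist_light / dist_total


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
) -> pd.DataFrame:
    """Two- or three-way Type-III ANOVA with sum-to-zero contrasts.

    Returns a DataFrame indexed by term with columns F, df, df_resid, p,
    covering every main effect and interaction of the given factors.
    """
    if len(factors) not in (2, 3):
        raise ValidationError("factors must name 2 or 3 columns")
    rhs = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{response} ~ {rhs}", data=table).fit()
    if model.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    tab = sm.stats.anova_lm(model, typ=3)
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    total_scale = max(1.0, float(np.abs(table[response]).max()) ** 2)
    degenerate = resid_ss <= 1e-12 * total_scale  # constant response: F := 0, p := 1
    rows = {}
    for raw in tab.index:
        if raw in ("Intercept", "Residual"):
            continue
        term = ":".join(
            part.replace("C(", "").replace(", Sum)", "") for part in raw.split(":")
        )
        F = tab.loc[raw, "F"]
        if degenerate and tab.loc[raw, "sum_sq"] <= 1e-12 * total_scale:
            rows[term] = dict(
                F=0.0, df=float(tab.loc[raw, "df"]),
                df_resid=float(model.df_resid), p=1.0,
            )
            continue
        if not np.isfinite(F):
            raise ValidationError(f"aliased or inestimable term {term!r}")
        rows[term] = dict(
            F=float(F), df=float(tab.loc[raw, "df"]),
            df_resid=float(model.df_resid), p=float(tab.loc[raw, "PR(>F)"]),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Student–Newman–Keuls
# ---------------------------------------------------------------------------

@dataclass
class PosthocResult:
    """Ordered group means and stepwise SNK decisions."""

    means: pd.Series                  # sorted ascending
    n_harmonic: float
    mse: float
    df_error: float
    alpha: float
    comparisons: pd.DataFrame         # group_a, group_b, span, diff, critical, significant


def snk_critical(alpha: float, span: int, df: float) -> float:
    """Studentized-range quantile q(1−α; span, df), computed numerically."""
    return float(stats.studentized_range.ppf(1.0 - alpha, span, df))


def snk_posthoc(
    table: pd.DataFrame,
    response: str,
    group: str,
    alpha: float = 0.05,
    require_omnibus: bool = True,
) -> PosthocResult:
    """SNK stepwise comparisons of group means.

    Critical difference for a comparison of span r is q(α, r, df_e)·√(MSE/ñ)
    with ñ the harmonic mean cell size.  The stepwise protection rule is
    enforced: a pair inside a non-significant span is never declared
    significant.  ``require_omnibus`` runs a one-way F gate first.
    """
    groups = table.groupby(group)[response]
    means = groups.mean().sort_values()
    ns = groups.size()
    if len(means) < 2:
        raise ValidationError("SNK needs at least two groups")
    k = len(means)
    n_total = ns.sum()
    df_error = n_total - k
    if df_error <= 0:
        raise ValidationError("no error degrees of freedom")
    sse = sum(((g - g.mean()) ** 2).sum() for _, g in groups)
    mse = sse / df_error
    if require_omnibus:
        F, p = stats.f_oneway(*[g.to_numpy() for _, g in groups])
        if p >= alpha:
            raise ValidationError(
                f"omnibus one-way F not significant (p={p:.3g}); "
                "pass require_omnibus=False to override"
            )
    n_h = k / np.sum(1.0 / ns)

    order = list(means.index)
    sig: dict[tuple[int, int], bool] = {}
    rows = []
    # widest spans first so protection can block inner comparisons
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            blocked = any(
                not sig[(a, b)]
                for (a, b) in sig
                if a <= i and j <= b and (a, b) != (i, j)
            )
            diff = means.iloc[j] - means.iloc[i]
            crit = snk_critical(alpha, span, df_error) * np.sqrt(mse / n_h)
            decision = (not blocked) and (diff > crit)
            sig[(i, j)] = decision
            rows.append(
                dict(group_a=order[i], group_b=order[j], span=span,
                     diff=float(diff), critical=float(crit), significant=decision)
            )
    comparisons = pd.DataFrame(rows)
    return PosthocResult(
        means=means, n_harmonic=float(n_h), mse=float(mse),
        df_error=float(df_error), alpha=alpha, comparisons=comparisons,
    )
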