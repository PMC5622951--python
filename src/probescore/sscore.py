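"""Probe-level S-scores between paired chips on PM-only transcriptome arrays.

The S-score compares a treated and a control chip at the probe level: each
between-chip probe difference is standardized by an intensity-dependent
error estimate ("equalized errors"), and the standardized differences are
summed per transcript cluster and divided by the square root of the probe
count,

    z_j = (s_T I_{j,T} − s_C I_{j,C}) / ε_j,
    ε_j = γ (s_T I_{j,T} + s_C I_{j,C}) + α,
    S_g = Σ_{j∈g} z_j / √(n_g),

so that under the null (no expression change) S follows a standard normal
distribution across clusters.  Classic formulations of this statistic used
the PM−MM probe-pair difference within a chip; these arrays carry
perfect-match probes only, so the probe-pair difference becomes a
between-chip per-probe difference.  The error-model parameters are:

γ    multiplicative-error coefficient (dimensionless), dominating at high
     intensity where noise is proportional to signal;
α    additive floor (intensity units) preventing low-intensity probes from
     being over-dispersed;
s_T, s_C  per-chip scale factors equalizing overall brightness.

Parameters are fitted robustly on the chip pair itself (differentially
expressed probes are outliers under the null fit, so medians are used, never
least squares).  A final per-pair standardization of the S-score vector
(subtract median, divide by MAD/0.6745) is applied by default, guaranteeing
the advertised N(0,1) null behavior even when the error model is
misspecified; it can be disabled per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .probe_io import DegenerateInputError, DesignTable, ProbeMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Φ⁻¹(0.75): MAD of a standard normal; converts median absolute deviations
#: to normal-equivalent standard deviations.
NORMAL_MAD = 0.6745


@dataclass
class ErrorModelParams:
    """Fitted parameters of the intensity-dependent error model for one chip pair."""

    gamma: float
    alpha: float
    scale_treated: float = 1.0
    scale_control: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValidationError("gamma must be > 0")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.scale_treated <= 0 or self.scale_control <= 0:
            raise ValidationError("scale factors must be > 0")


@dataclass
class SScoreSet:
    """Per-cluster S-scores, one column per biological replicate (pair_id)."""

    scores: pd.DataFrame            # clusters × pairs
    params: dict[str, ErrorModelParams]
    n_probes: pd.Series             # probes per cluster

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("S-score matrix contains non-finite values")


def _trimmed_mean(x: np.ndarray, trim: float = 0.02) -> float:
    return float(stats.trim_mean(x, trim))


def estimate_error_model(
    chip_treated: np.ndarray | pd.Series,
    chip_control: np.ndarray | pd.Series,
    trim: float = 0.02,
) -> ErrorModelParams:
    """Fit (γ, α, scale factors) from one treated/control chip pair.

    Scale factors equalize the trimmed mean intensity of the two chips
    (geometric-mean target, so the pair is symmetric).  γ is calibrated so
    the median absolute standardized difference over the central 50% of
    summed intensities equals the standard-normal reference value 0.6745;
    α is then set from the lowest summed-intensity quartile so that probes
    there are not over-dispersed relative to N(0,1).
    """
    t = np.asarray(chip_treated, dtype=float)
    c = np.asarray(chip_control, dtype=float)
    if t.shape != c.shape:
        raise ValidationError("chips must share the probe set")
    mt, mc = _trimmed_mean(t, trim), _trimmed_mean(c, trim)
    if mt <= 0 or mc <= 0:
        raise DegenerateInputError("all-zero (or near-zero) chip; cannot fit error model")
    target = np.sqrt(mt * mc)
    s_t, s_c = target / mt, target / mc

    d = s_t * t - s_c * c
    s = s_t * t + s_c * c
    q25, q75 = np.quantile(s, [0.25, 0.75])
    central = (s >= q25) & (s <= q75)
    if central.sum() < 10:
        central = np.ones_like(s, dtype=bool)
    # median |d|/s on the central band scaled so median |z| = 0.6745 there
    ratio = np.median(np.abs(d[central]) / np.maximum(s[central], np.finfo(float).tiny))
    gamma = float(ratio / NORMAL_MAD)
    if gamma <= 0:
        # identical chips: no dispersion to calibrate; fall back to a tiny
        # positive coefficient so the params object is well formed
        gamma = np.finfo(float).eps

    low = s <= q25
    if low.sum() >= 10:
        sigma_low = np.median(np.abs(d[low])) / NORMAL_MAD
        alpha = max(0.0, float(sigma_low - gamma * np.median(s[low])))
    else:
        alpha = 0.0
    return ErrorModelParams(gamma=gamma, alpha=alpha, scale_treated=s_t, scale_control=s_c)


def compute_sscore_pair(
    pm: ProbeMatrix,
    pair: tuple[str, str],
    params: ErrorModelParams,
    standardize: bool = True,
) -> pd.Series:
    """Per-cluster S-scores for one (treated, control) chip pair.

    Positive scores mean higher intensity in the treated chip.  With
    ``standardize`` the score vector is centered on its median and scaled by
    MAD/0.6745, enforcing the standard-normal null calibration.
    """
    treated_id, control_id = pair
    t = params.scale_treated * pm.intensities[treated_id].to_numpy(dtype=float)
    c = params.scale_control * pm.intensities[control_id].to_numpy(dtype=float)
    eps = params.gamma * (t + c) + params.alpha
    if np.any(eps <= 0):
        raise DegenerateInputError(
            "zero error estimate: both intensities and alpha vanish for some probe"
        )
    z = (t - c) / eps
    grouped = pd.Series(z, index=pm.cluster_map.to_numpy()).groupby(level=0, sort=False)
    n_g = grouped.size()
    scores = grouped.sum() / np.sqrt(n_g)
    if standardize:
        med = float(np.median(scores))
        mad = float(np.median(np.abs(scores - med))) / NORMAL_MAD
        if mad > 0:
            scores = (scores - med) / mad
            logger.debug(
                "pair (%s, %s): standardized S-scores (median %.4g, MAD-sd %.4g)",
                treated_id, control_id, med, mad,
            )
        else:
            scores = scores - med
    scores.index.name = "cluster_id"
    return scores


def assemble_replicate_sscores(
    pm: ProbeMatrix,
    design: DesignTable,
    age_group: str | None = None,
    standardize: bool = True,
) -> SScoreSet:
    """Pairwise S-scores for every treated↔control pair in the design.

    Scores are computed within sex (pairs never cross sexes by design-table
    invariant); each pair_id is one biological replicate and contributes one
    column.  Sexes are not averaged here — they enter as separate columns
    and are collapsed only downstream, in the one-class SAM call.  Treated
    samples without a pair are excluded with a logged warning.
    """
    pairs = design.pairs(age_group)
    if pairs.empty:
        raise ValidationError("design contains no treated/control pairs")
    unpaired = design.table[
        (design.table["treatment"] == "ethanol")
        & (design.table["pair_id"].isna() | (design.table["pair_id"] == ""))
    ]
    if age_group is not None:
        unpaired = unpaired[unpaired["age_group"] == age_group]
    for sid in unpaired["sample_id"]:
        logger.warning("treated sample %s has no control pair; excluded from S-scores", sid)

    cols, params = {}, {}
    for row in pairs.itertuples(index=False):
        p = estimate_error_model(
            pm.intensities[row.treated_id], pm.intensities[row.control_id]
        )
        cols[row.pair_id] = compute_sscore_pair(
            pm, (row.treated_id, row.control_id), p, standardize=standardize
        )
        params[row.pair_id] = p
    scores = pd.DataFrame(cols)
    scores.index.name = "cluster_id"
    return SScoreSet(scores=scores, params=params, n_probes=pm.probes_per_cluster())
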