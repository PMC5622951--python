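"""Relative qPCR quantification and ELISA standard-curve back-calculation.

qPCR quantities are computed by the multi-reference ΔΔCt scheme: technical
replicate wells are averaged per sample×gene, target Ct is normalized against
the arithmetic mean of the reference-gene Cts (equivalent to geometric-mean
normalization on the expression scale), converted to 2^−ΔCt, and rescaled so
the designated baseline group's mean is exactly 1.

ELISA concentrations are back-calculated from a linear least-squares fit of
optical density on standard concentration, then divided by the protein input
to give ng/μg.  A 4-parameter logistic curve is a possible extension; the
linear curve is the documented default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe_io import DegenerateInputError, ValidationError

DEFAULT_REFERENCE_GENES = ("PPP2r2p", "Ublcp1", "B2M")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

CT_COLUMNS = ("sample_id", "target", "well", "ct")


def _check_ct_table(ct: pd.DataFrame) -> None:
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    if (ct["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")


def relative_expression(
    ct: pd.DataFrame,
    refs: Sequence[str] = DEFAULT_REFERENCE_GENES,
    groups: Mapping[str, str] | pd.Series | None = None,
    baseline_group: str | None = None,
) -> pd.DataFrame:
    """ΔΔCt relative quantities per sample × target.

    Parameters
    ----------
    ct
        Long-format Ct table with columns sample_id, target, well, ct.
    refs
        Endogenous control genes; every sample must have a Ct for each.
    groups
        sample_id → group label (e.g. ``control_male``); required together with
        ``baseline_group`` for baseline rescaling.
    baseline_group
        Group whose mean relative quantity is fixed at 1 after rescaling.

    Returns
    -------
    DataFrame with columns sample_id, target, rel_expr.
    """
    _check_ct_table(ct)
    mean_ct = ct.groupby(["sample_id", "target"], sort=False)["ct"].mean().unstack("target")
    for ref in refs:
        if ref not in mean_ct.columns or mean_ct[ref].isna().any():
            missing = (
                mean_ct.index[mean_ct[ref].isna()].tolist() if ref in mean_ct.columns else "all samples"
            )
            raise ValidationError(f"missing reference Ct for gene {ref!r} in sample(s) {missing}")
    ref_mean = mean_ct[list(refs)].mean(axis=1)
    targets = [t for t in mean_ct.columns if t not in refs]
    out = []
    for tgt in targets:
        sub = mean_ct[tgt].dropna()
        dct = sub - ref_mean.loc[sub.index]
        rq = np.power(2.0, -dct)
        if baseline_group is not None:
            if groups is None:
                raise ValidationError("baseline_group requires a sample→group mapping")
            g = pd.Series(groups).loc[sub.index]
            base_mean = rq[g == baseline_group].mean()
            if not np.isfinite(base_mean) or base_mean <= 0:
                raise DegenerateInputError(f"baseline group {baseline_group!r} absent or degenerate")
            rq = rq / base_mean
        out.append(pd.DataFrame({"sample_id": sub.index, "target": tgt, "rel_expr": rq.to_numpy()}))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["sample_id", "target", "rel_expr"]
    )


# ---------------------------------------------------------------------------
# ELISA
# ---------------------------------------------------------------------------

@dataclass
class ElisaPlate:
    """A colorimetric plate: standards (conc ng/mL, OD) and samples (id, OD, μg protein)."""

    standard_conc: np.ndarray
    standard_od: np.ndarray
    sample_ids: list[str]
    sample_od: np.ndarray
    protein_ug: np.ndarray

    def __post_init__(self) -> None:
        self.standard_conc = np.asarray(self.standard_conc, dtype=float)
        self.standard_od = np.asarray(self.standard_od, dtype=float)
        self.sample_od = np.asarray(self.sample_od, dtype=float)
        self.protein_ug = np.asarray(self.protein_ug, dtype=float)
        if len(self.standard_conc) < 3:
            raise ValidationError("at least 3 standards required")
        if not np.all(np.diff(self.standard_conc) > 0):
            raise ValidationError("standard concentrations must be strictly increasing")


def elisa_concentration(plate: ElisaPlate, allow_extrapolation: bool = False) -> pd.DataFrame:
    """Back-calculate sample concentrations (ng/μg protein) from the standard curve.

    Sample ODs outside the standards' OD range are rejected unless
    ``allow_extrapolation`` is set.
    """
    fit = stats.linregress(plate.standard_conc, plate.standard_od)
    if fit.slope <= 0:
        raise DegenerateInputError("standard curve slope is non-positive")
    lo, hi = plate.standard_od.min(), plate.standard_od.max()
    if not allow_extrapolation:
        out_of_range = (plate.sample_od < lo) | (plate.sample_od > hi)
        if out_of_range.any():
            bad = [plate.sample_ids[i] for i in np.flatnonzero(out_of_range)]
            raise ValidationError(f"sample OD outside standard range for {bad}; extrapolation disabled")
    conc = (plate.sample_od - fit.intercept) / fit.slope
    return pd.DataFrame(
        {
            "sample_id": plate.sample_ids,
            "conc_ng_ml": conc,
            "ng_per_ug": conc / plate.protein_ug,
        }
    )
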