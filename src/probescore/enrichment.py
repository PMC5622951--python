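"""Local gene-set over-representation analysis.

For a query list against each gene set, the upper-tail hypergeometric
probability P[X ≥ k] is computed with X ~ Hypergeometric(N, K, n), where N is
the universe size (all clusters on the array — the standard array-background
convention), K the set size after intersecting with the universe, n the query
size, and k the overlap.  One-sided over-representation only; p-values are
Benjamini–Hochberg adjusted across all tested sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .probe_io import GeneSetCollection, ValidationError


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Returns a DataFrame with columns set_id, set_name, k, K, n, N, p, q,
    sorted by p.  Sets with no members in the universe are dropped.
    """
    uni = set(universe)
    qset = set(query)
    offenders = qset - uni
    if offenders:
        raise ValidationError(
            f"query not a subset of the universe: {sorted(offenders)[:10]}"
        )
    N, n = len(uni), len(qset)
    rows = []
    for sid, members in sets.items():
        in_uni = members & uni
        K = len(in_uni)
        if K == 0:
            continue
        k = len(in_uni & qset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(set_id=sid, set_name=sets.names.get(sid, sid),
                         k=k, K=K, n=n, N=N, p=min(1.0, max(p, 0.0))))
    res = pd.DataFrame(rows, columns=["set_id", "set_name", "k", "K", "n", "N", "p"])
    if len(res):
        res["p"] = res["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
        res["q"] = bh_adjust(res["p"].to_numpy())
        res = res.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        res["q"] = pd.Series(dtype=float)
    return res
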