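"""Correlation of cluster mean expression (or single genes) with traits.

Each unit (cluster or gene) is correlated against the ten trait variables
— seven liver/body physiology measures and the arcuate-nucleus expression of
three appetite-regulating genes.  Arrays map one-to-one to individuals (each
bird is a biological replicate), so per-array expression aligns directly
with trait rows.  Significance uses a Bonferroni correction over the trait
family: with the default family-wise level 0.05 over 10 traits the per-test
threshold is 0.005.  Missing trait values are dropped pairwise; the pairs
actually used (n) are reported and tests use n − 2 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .params import AnalysisParams


def correlate(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """Correlation of two vectors with pairwise deletion of missing values.

    Returns (r, two-sided p, n used).  p comes from the t transform
    t = r·sqrt((n−2)/(1−r²)) on n − 2 df; |r| = 1 gives p = 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be 'pearson' or 'spearman', got {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined: zero variance")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0)), n


def correlate_units(
    units: pd.DataFrame,
    traits: pd.DataFrame,
    sheet: pd.DataFrame,
    params: AnalysisParams | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate every (unit, trait) pair with Bonferroni-flagged significance.

    ``units`` is units × arrays (cluster mean expression or single-gene rows);
    ``traits`` is individuals × traits; ``sheet`` maps arrays to individuals.
    The Bonferroni family size m is the number of trait columns tested per
    unit (falling back to ``params.m_corr`` for an empty table), so with the
    ten standard traits the per-test threshold is 0.05 / 10 = 0.005.
    """
    params = params or AnalysisParams()
    individuals = sheet.loc[units.columns, "individual_id"]
    overlap = set(individuals) & set(traits.index)
    if not overlap:
        raise ValidationError("no overlapping individuals between arrays and traits")
    m = len(traits.columns) if len(traits.columns) else params.m_corr
    threshold = params.alpha_corr_family / m
    rows = []
    for unit in units.index:
        expr = units.loc[unit].to_numpy(dtype=float)
        for trait in traits.columns:
            tvals = traits[trait].reindex(individuals).to_numpy(dtype=float)
            try:
                r, p, n = correlate(expr, tvals, method=method)
            except (InsufficientDataError, ValidationError):
                ok = np.isfinite(expr) & np.isfinite(tvals)
                rows.append(
                    {
                        "unit": unit,
                        "trait": trait,
                        "n": int(ok.sum()),
                        "r": np.nan,
                        "p": np.nan,
                        "significant": False,
                    }
                )
                continue
            rows.append(
                {
                    "unit": unit,
                    "trait": trait,
                    "n": n,
                    "r": r,
                    "p": p,
                    "significant": bool(p < threshold),
                }
            )
    out = pd.DataFrame(rows, columns=["unit", "trait", "n", "r", "p", "significant"])
    out.attrs["bonferroni_m"] = m
    out.attrs["threshold"] = threshold
    return out
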