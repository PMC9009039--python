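"""Four-group linear model with empirical-Bayes variance moderation.

Per gene g the model is a one-way layout over the four treatments: the group
means μ̂_t are within-group averages and s²_g is the pooled within-group
residual variance on d = N − 4 degrees of freedom.  Moderation follows the
standard empirical-Bayes treatment of microarray data: gene variances are
assumed exchangeable with a scaled inverse-chi-square prior (d0, s0²),
estimated by method of moments on z_g = log s²_g, and each gene's posterior
variance

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)

replaces s²_g in the pairwise t-statistics, which gain d0 extra degrees of
freedom.  With d0 = 0 ("ordinary" mode) the moderated t reduces exactly to
the pooled-variance t; with d0 = ∞ all genes share s0² and the reference
distribution is normal.

All six unordered treatment pairs are tested; p-values are two-sided and
Benjamini–Hochberg adjusted per pair across genes.  The inclusion filter
keeps a gene when some pair meets the significance criterion jointly with a
fold change of at least ``fc_min`` in that same pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateDataError, DesignError, ValidationError
from .params import PAIRS, TREATMENTS, AnalysisParams, pair_key

log = logging.getLogger(__name__)


@dataclass
class GroupFit:
    """Per-gene group means and pooled residual variance.

    ``means`` is genes × 4 (columns AL, CR, F2, SK, log2 units), ``s2`` the
    pooled within-group residual variance, ``df_residual`` = N − 4, and
    ``n_per_group`` the surviving array counts.
    """

    means: pd.DataFrame
    s2: pd.Series
    df_residual: int
    n_per_group: dict


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior of gene-wise variances.

    ``d0`` may be 0 (no moderation), finite, or ``inf`` (complete shrinkage
    to ``s0sq``).
    """

    d0: float
    s0sq: float

    def moderate(self, s2: pd.Series, df_residual: int) -> pd.Series:
        """Posterior (moderated) variances s̃²."""
        if np.isinf(self.d0):
            return pd.Series(self.s0sq, index=s2.index)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0sq + df_residual * s2) / (self.d0 + df_residual)


def fit_linear_model(matrix: pd.DataFrame, sheet: pd.DataFrame) -> GroupFit:
    """Fit the one-way four-group model to every gene."""
    unlabeled = matrix.columns.difference(sheet.index)
    if len(unlabeled):
        raise ValidationError(f"arrays missing from sample sheet: {list(unlabeled[:10])}")
    treatments = sheet.loc[matrix.columns, "treatment"]
    n_per = treatments.value_counts().to_dict()
    for t in TREATMENTS:
        if n_per.get(t, 0) < 2:
            raise DesignError(f"treatment {t} has {n_per.get(t, 0)} array(s); need >= 2")
    vals = matrix.to_numpy(dtype=float)
    means = {}
    rss = np.zeros(vals.shape[0])
    for t in TREATMENTS:
        cols = np.flatnonzero((treatments == t).to_numpy())
        sub = vals[:, cols]
        mu = sub.mean(axis=1)
        means[t] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df_residual = vals.shape[1] - len(TREATMENTS)
    s2 = rss / df_residual
    return GroupFit(
        means=pd.DataFrame(means, index=matrix.index),
        s2=pd.Series(s2, index=matrix.index, name="s2"),
        df_residual=df_residual,
        n_per_group={t: int(n_per[t]) for t in TREATMENTS},
    )


def estimate_variance_prior(fit: GroupFit, min_genes: int = 100) -> VariancePrior:
    """Method-of-moments estimate of (d0, s0²) from the gene-wise variances.

    Under the exchangeable-variance model, z_g = log s²_g has
    var(z) = trigamma(d/2) + trigamma(d0/2) and
    E[z] = log s0² + digamma(d/2) − log(d/2) − digamma(d0/2) + log(d0/2),
    so d0 solves trigamma(d0/2) = var(z) − trigamma(d/2) (monotone bisection)
    and s0² follows from the mean of z with the matching digamma corrections.
    Non-positive excess dispersion gives d0 = ∞.
    """
    s2 = fit.s2[fit.s2 > 0]
    if len(fit.s2) and len(s2) == 0:
        raise DegenerateDataError("all residual variances are zero")
    if len(s2) < min_genes:
        log.warning(
            "only %d genes with positive variance (< %d); falling back to "
            "ordinary (unmoderated) variances",
            len(s2),
            min_genes,
        )
        return VariancePrior(d0=0.0, s0sq=float(s2.mean()) if len(s2) else 0.0)
    d = fit.df_residual
    z = np.log(s2.to_numpy())
    mean_z = z.mean()
    excess = z.var(ddof=1) - special.polygamma(1, d / 2.0)
    correction_d = special.digamma(d / 2.0) - np.log(d / 2.0)
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0sq=float(np.exp(mean_z - correction_d)))
    # trigamma(d0/2) = excess, trigamma decreasing: bisect on d0
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid / 2.0) > excess:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8 * max(1.0, lo):
            break
    d0 = 0.5 * (lo + hi)
    correction_d0 = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    s0sq = float(np.exp(mean_z - correction_d + correction_d0))
    return VariancePrior(d0=float(d0), s0sq=s0sq)


def pairwise_contrasts(
    fit: GroupFit,
    prior: VariancePrior,
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Moderated t-tests for all six treatment pairs.

    Returns a long table with one row per (gene, pair): ``delta_log2``
    (mean_X − mean_Y), ``fold_change`` = 2^|delta|, ``t``, two-sided ``p``
    from the t distribution on d + d0 df (normal when d0 = ∞), ``p_adj``
    (BH within each pair across genes) and the joint ``passes`` flag of the
    inclusion filter.
    """
    params = params or AnalysisParams()
    s2_mod = prior.moderate(fit.s2, fit.df_residual).to_numpy()
    df_total = fit.df_residual + prior.d0
    frames = []
    for x, y in PAIRS:
        delta = (fit.means[x] - fit.means[y]).to_numpy()
        se = np.sqrt(
            s2_mod * (1.0 / fit.n_per_group[x] + 1.0 / fit.n_per_group[y])
        )
        # zero moderated variance: t is 0 for a zero difference, ±inf otherwise
        t = np.divide(delta, se, out=np.zeros_like(delta), where=se > 0)
        t[(se <= 0) & (delta > 0)] = np.inf
        t[(se <= 0) & (delta < 0)] = -np.inf
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.means.index,
                    "pair": pair_key(x, y),
                    "group_a": x,
                    "group_b": y,
                    "delta_log2": delta,
                    "fold_change": np.exp2(np.abs(delta)),
                    "t": t,
                    "p": p,
                    "p_adj": adjust_bh(p),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    crit_p = table["p_adj"] if params.use_adjusted_p else table["p"]
    table["passes"] = (crit_p < params.alpha_de) & (
        table["fold_change"] >= params.fc_min
    )
    return table


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) · n / j, clipped at 1; ties broken by stable
    sort.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("adjust_bh expects a 1-d vector")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def filter_de(table: pd.DataFrame, params: AnalysisParams | None = None) -> set:
    """Genes passing the joint p / fold-change criterion in at least one pair."""
    params = params or AnalysisParams()
    crit_p = table["p_adj"] if params.use_adjusted_p else table["p"]
    passing = (crit_p < params.alpha_de) & (table["fold_change"] >= params.fc_min)
    return set(table.loc[passing, "gene"])


def updown_counts(
    table: pd.DataFrame, params: AnalysisParams | None = None
) -> pd.DataFrame:
    """Up/down-regulated gene counts per pair plus union rows.

    "Up" for pair (X, Y) means higher in the first-named group X.  The union
    rows count genes up (resp. down) in at least one pair; a gene may
    contribute to both unions via different pairs.
    """
    params = params or AnalysisParams()
    crit_p = table["p_adj"] if params.use_adjusted_p else table["p"]
    passing = (crit_p < params.alpha_de) & (table["fold_change"] >= params.fc_min)
    sub = table[passing]
    rows = []
    for x, y in PAIRS:
        k = pair_key(x, y)
        pp = sub[sub["pair"] == k]
        rows.append(
            {
                "pair": k,
                "up": int((pp["delta_log2"] > 0).sum()),
                "down": int((pp["delta_log2"] < 0).sum()),
            }
        )
    rows.append(
        {
            "pair": "union",
            "up": sub.loc[sub["delta_log2"] > 0, "gene"].nunique(),
            "down": sub.loc[sub["delta_log2"] < 0, "gene"].nunique(),
        }
    )
    return pd.DataFrame(rows)
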