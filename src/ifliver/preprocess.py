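"""Probe-set summarization, log transform, array QC and exclusion.

The QC stage codifies the usual visual checks on single-color arrays (log
box plots, PCA of arrays) as two automatable rules: an array is flagged when
its median inter-array correlation falls below a threshold, or when its PC1
score is a robust outlier (beyond ``pc_mad_multiplier`` MADs from the median
PC1 score).  A hard guard refuses to flag more than 25% of arrays — at that
point the data, not individual arrays, are suspect.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    FormatError,
    InsufficientDataError,
    QCFailureError,
    ValidationError,
)

log = logging.getLogger(__name__)


def summarize_probesets(
    probes: pd.DataFrame, probe_map: pd.Series, method: str = "median"
) -> pd.DataFrame:
    """Aggregate probe rows to one row per probe set (per-array median or mean)."""
    if method not in ("median", "mean"):
        raise ValidationError(f"method must be 'median' or 'mean', got {method!r}")
    unmapped = probes.index.difference(probe_map.index)
    if len(unmapped):
        raise ValidationError(
            f"{len(unmapped)} probe(s) missing from the probe map; "
            f"first offenders: {list(unmapped[:10])}"
        )
    groups = probe_map.reindex(probes.index)
    agg = probes.groupby(groups.to_numpy()).median() if method == "median" else (
        probes.groupby(groups.to_numpy()).mean()
    )
    agg.index.name = "probeset_id"
    agg = agg.sort_index()
    agg.attrs["log2"] = probes.attrs.get("log2", True)
    return agg


def log_transform(matrix: pd.DataFrame, already_log: bool = False) -> pd.DataFrame:
    """Apply log2 exactly once; identity when the data are already log scale."""
    if already_log or matrix.attrs.get("log2", False):
        out = matrix.copy()
        out.attrs["log2"] = True
        return out
    vals = matrix.to_numpy(dtype=float)
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise FormatError(
            f"non-positive intensity at probe {matrix.index[r]!r}, "
            f"array {matrix.columns[c]!r}; cannot log-transform"
        )
    out = pd.DataFrame(np.log2(vals), index=matrix.index, columns=matrix.columns)
    out.attrs["log2"] = True
    return out


def array_qc_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-array QC statistics.

    Returns a DataFrame indexed by array id with median log2 intensity,
    interquartile range, median pairwise inter-array correlation, the first
    two principal-component scores of the gene-centered data, and empty
    flag/reason columns (filled by :func:`flag_failed_arrays`).
    """
    if matrix.shape[1] < 3:
        raise InsufficientDataError("array QC needs at least 3 arrays")
    vals = matrix.to_numpy(dtype=float)
    med = np.median(vals, axis=0)
    q75, q25 = np.percentile(vals, [75, 25], axis=0)
    corr = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    med_corr = np.nanmedian(corr, axis=0)
    centered = vals - vals.mean(axis=1, keepdims=True)  # remove gene means
    # PC scores of arrays from the SVD of the gene-centered matrix
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0] * s[0] if len(s) > 0 else np.zeros(len(med))
    pc2 = vt[1] * s[1] if len(s) > 1 else np.zeros(len(med))
    # fix sign for reproducibility: largest |loading| positive
    for pc in (pc1, pc2):
        if len(pc) and pc[np.argmax(np.abs(pc))] < 0:
            pc *= -1
    return pd.DataFrame(
        {
            "median_log2": med,
            "iqr": q75 - q25,
            "median_corr": med_corr,
            "pc1": pc1,
            "pc2": pc2,
            "flagged": False,
            "reason": "",
        },
        index=matrix.columns.rename("array_id"),
    )


def flag_failed_arrays(
    report: pd.DataFrame,
    min_median_correlation: float = 0.8,
    pc_mad_multiplier: float = 5.0,
) -> pd.DataFrame:
    """Apply the QC rules and record flags with reasons.

    An array fails when its median inter-array correlation is below
    ``min_median_correlation`` or its PC1 score deviates from the median PC1
    by more than ``pc_mad_multiplier`` MADs (with an epsilon floor on the MAD
    so identical arrays never self-flag).  Flagging more than 25% of the
    arrays raises :class:`QCFailureError`.
    """
    out = report.copy()
    reasons = []
    low_corr = out["median_corr"] < min_median_correlation
    pc1 = out["pc1"].to_numpy()
    med = np.median(pc1)
    mad = np.median(np.abs(pc1 - med))
    floor = 1e-12 * max(1.0, float(np.max(np.abs(pc1))) if len(pc1) else 1.0)
    pc_out = np.abs(pc1 - med) > pc_mad_multiplier * max(mad, floor)
    for i, a in enumerate(out.index):
        r = []
        if low_corr.iloc[i]:
            r.append(
                f"median inter-array correlation {out['median_corr'].iloc[i]:.3f} "
                f"< {min_median_correlation}"
            )
        if pc_out[i]:
            r.append(
                f"PC1 score {pc1[i]:.3g} deviates > {pc_mad_multiplier} MAD "
                "from the median"
            )
        reasons.append("; ".join(r))
    out["flagged"] = low_corr.to_numpy() | pc_out
    out["reason"] = reasons
    n_flag = int(out["flagged"].sum())
    if n_flag > 0.25 * len(out):
        raise QCFailureError(
            f"QC would flag {n_flag} of {len(out)} arrays (> 25%); "
            "the data, not the arrays, are suspect"
        )
    for a in out.index[out["flagged"]]:
        log.warning("array %s failed QC: %s", a, out.loc[a, "reason"])
    return out


def exclude_arrays(
    matrix: pd.DataFrame,
    report: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop flagged arrays; error if any treatment would fall below 2 arrays."""
    missing = report.index.difference(matrix.columns)
    if len(missing):
        raise ValidationError(f"QC report covers unknown arrays: {list(missing[:10])}")
    keep = [a for a in matrix.columns if not report.loc[a, "flagged"]]
    out = matrix[keep]
    out.attrs.update(matrix.attrs)
    if sample_sheet is not None:
        surviving = sample_sheet.loc[keep, "treatment"].value_counts()
        for t, n in surviving.items():
            log.info("treatment %s: %d array(s) after QC", t, n)
        low = surviving[surviving < 2]
        if len(low) or set(surviving.index) != set(
            sample_sheet["treatment"].unique()
        ):
            raise DesignError(
                "array exclusion leaves a treatment with < 2 arrays: "
                f"{surviving.to_dict()}"
            )
    return out
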