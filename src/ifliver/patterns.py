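"""Expression-pattern taxonomy over the pairwise contrasts.

Per gene, significance (``sig``) and direction (``dir``) of each of the six
treatment contrasts feed a small boolean taxonomy of intermittent-fasting
response patterns:

``switching_broad``
    F2 and SK differ from each other and at least one IF day differs from AL;
``switching_strict``
    both IF days differ from AL, in opposite directions — the profile of the
    fed/fasted metabolic switch;
``chronic`` (direction up/down)
    both IF days differ from AL in the same direction;
``chronic_and_switching`` / ``chronic_pure``
    chronic genes with / without an additional F2–SK difference;
``robust_chronic``
    chronic genes also differing from CR on both IF days, in the chronic
    direction — chronically changed relative to both control regimens.

By default ``sig(X, Y)`` is the same joint p + fold-change criterion as the
inclusion filter (the pattern analysis draws from the same filtered set);
``sig_mode="p_only"`` drops the fold-change requirement.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .params import PAIR_KEYS, AnalysisParams, pair_key

log = logging.getLogger(__name__)

FLAG_COLUMNS = (
    "switching_broad",
    "switching_strict",
    "chronic",
    "chronic_and_switching",
    "chronic_pure",
    "robust_chronic",
)


def classify_gene_patterns(
    table: pd.DataFrame,
    params: AnalysisParams | None = None,
    sig_mode: str = "joint",
    robust_mode: str = "both",
) -> pd.DataFrame:
    """Assign taxonomy flags to every gene in the contrast table.

    Parameters
    ----------
    table
        Long contrast table with all six pairs per gene.
    sig_mode
        ``"joint"`` (default): significance = p criterion AND fold change
        >= fc_min, exactly as the inclusion filter; ``"p_only"``: p criterion
        alone.
    robust_mode
        ``"both"`` (default): robust chronic requires both F2-vs-CR and
        SK-vs-CR significant in the chronic direction; ``"any"``: one CR
        contrast suffices.

    Returns a DataFrame indexed by gene with ``sig_<pair>`` and ``dir_<pair>``
    columns plus the taxonomy flags and ``chronic_direction``.
    """
    params = params or AnalysisParams()
    if sig_mode not in ("joint", "p_only"):
        raise ValidationError(f"sig_mode must be 'joint' or 'p_only', got {sig_mode!r}")
    if robust_mode not in ("both", "any"):
        raise ValidationError(f"robust_mode must be 'both' or 'any', got {robust_mode!r}")

    if len(table) == 0:
        cols = (
            [f"sig_{k}" for k in PAIR_KEYS]
            + [f"dir_{k}" for k in PAIR_KEYS]
            + list(FLAG_COLUMNS)
            + ["chronic_direction"]
        )
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene"))

    crit_p = table["p_adj"] if params.use_adjusted_p else table["p"]
    sig_vec = crit_p < params.alpha_de
    if sig_mode == "joint":
        sig_vec = sig_vec & (table["fold_change"] >= params.fc_min)

    work = table[["gene", "pair", "delta_log2"]].copy()
    work["sig"] = sig_vec.to_numpy()
    sig = work.pivot(index="gene", columns="pair", values="sig")
    delta = work.pivot(index="gene", columns="pair", values="delta_log2")
    missing = [k for k in PAIR_KEYS if k not in sig.columns]
    if missing or sig.isna().any().any():
        raise ValidationError(f"contrast table lacks pair rows for every gene: {missing}")
    sig = sig[list(PAIR_KEYS)].astype(bool)
    direction = np.sign(delta[list(PAIR_KEYS)])

    f2_al, sk_al = pair_key("F2", "AL"), pair_key("SK", "AL")
    f2_cr, sk_cr = pair_key("F2", "CR"), pair_key("SK", "CR")
    f2_sk = pair_key("F2", "SK")

    both_al = sig[f2_al] & sig[sk_al]
    same_dir = direction[f2_al] == direction[sk_al]
    calls = pd.DataFrame(index=sig.index)
    for k in PAIR_KEYS:
        calls[f"sig_{k}"] = sig[k]
        calls[f"dir_{k}"] = direction[k].astype(int)
    calls["switching_broad"] = sig[f2_sk] & (sig[f2_al] | sig[sk_al])
    calls["switching_strict"] = both_al & ~same_dir
    calls["chronic"] = both_al & same_dir
    calls["chronic_direction"] = np.where(
        calls["chronic"] & (direction[f2_al] > 0),
        "up",
        np.where(calls["chronic"] & (direction[f2_al] < 0), "down", "none"),
    )
    calls["chronic_and_switching"] = calls["chronic"] & sig[f2_sk]
    calls["chronic_pure"] = calls["chronic"] & ~sig[f2_sk]
    cr_sig = (
        (sig[f2_cr] & sig[sk_cr]) if robust_mode == "both" else (sig[f2_cr] | sig[sk_cr])
    )
    cr_dir_ok = (direction[f2_cr] == direction[f2_al]) & (
        direction[sk_cr] == direction[f2_al]
    )
    calls["robust_chronic"] = calls["chronic"] & cr_sig & cr_dir_ok
    calls.index.name = "gene"
    return calls


def dedupe_to_genes(
    calls: pd.DataFrame, symbol_map: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probe-set-level calls to gene symbols.

    A gene inherits a flag when at least one of its probe sets carries it; if
    probe sets of the same symbol disagree on chronic direction the gene is
    marked ``discordant`` and its direction set to ``none``.  With no symbol
    map the calls pass through (one symbol per probe set).

    Returns (gene-level calls, duplicate report).
    """
    if symbol_map is None:
        out = calls.copy()
        out["discordant"] = False
        report = pd.DataFrame(columns=["symbol", "probesets", "discordant"])
        return out, report

    symbols = symbol_map.reindex(calls.index)
    symbols = symbols.fillna(pd.Series(calls.index, index=calls.index))
    grouped = calls.groupby(symbols.to_numpy())
    rows, rep = [], []
    for symbol, sub in grouped:
        row = {"gene": symbol}
        for col in calls.columns:
            if col == "chronic_direction":
                continue
            if sub[col].dtype == bool:
                row[col] = bool(sub[col].any())
            else:
                row[col] = sub[col].iloc[0]
        dirs = set(sub.loc[sub["chronic"], "chronic_direction"]) - {"none"}
        discordant = len(dirs) > 1
        row["chronic_direction"] = dirs.pop() if len(dirs) == 1 else "none"
        row["discordant"] = discordant
        rows.append(row)
        if len(sub) > 1:
            rep.append(
                {
                    "symbol": symbol,
                    "probesets": ",".join(sub.index),
                    "discordant": discordant,
                }
            )
            if discordant:
                log.warning(
                    "probe sets of %s disagree on chronic direction: %s",
                    symbol,
                    list(sub.index),
                )
    out = pd.DataFrame(rows).set_index("gene")
    report = pd.DataFrame(rep, columns=["symbol", "probesets", "discordant"])
    return out, report


def summarize_patterns(calls: pd.DataFrame) -> pd.DataFrame:
    """Set-algebra counts over the taxonomy flags.

    Includes the per-flag totals, chronic direction split, the strict
    switching ∧ sig(F2, SK) overlap, and per-contrast significant-gene counts
    for the three comparisons against AL plus F2-vs-SK (the Venn family).
    """
    n = {}
    for flag in FLAG_COLUMNS:
        n[flag] = int(calls[flag].sum()) if len(calls) else 0
    n["chronic_up"] = int((calls["chronic_direction"] == "up").sum()) if len(calls) else 0
    n["chronic_down"] = (
        int((calls["chronic_direction"] == "down").sum()) if len(calls) else 0
    )
    if len(calls):
        n["switching_strict_and_f2_vs_sk"] = int(
            (calls["switching_strict"] & calls[f"sig_{pair_key('F2', 'SK')}"]).sum()
        )
        for x, y in (("F2", "AL"), ("SK", "AL"), ("CR", "AL"), ("F2", "SK")):
            n[f"n_sig_{pair_key(x, y)}"] = int(calls[f"sig_{pair_key(x, y)}"].sum())
    else:
        n["switching_strict_and_f2_vs_sk"] = 0
        for x, y in (("F2", "AL"), ("SK", "AL"), ("CR", "AL"), ("F2", "SK")):
            n[f"n_sig_{pair_key(x, y)}"] = 0
    return pd.DataFrame(
        {"count": pd.Series(n)}
    ).rename_axis("pattern")
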