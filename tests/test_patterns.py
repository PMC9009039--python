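import itertools

import numpy as np
import pandas as pd
import pytest

import ifliver as il
from ifliver import patterns
from ifliver.errors import ValidationError
from ifliver.params import PAIR_KEYS


def _table_from_states(states_per_gene):
    """Build a contrast table from {gene: {pair: state}} with state in
    {'ns', 'up', 'dn'} (significant up/down or not significant)."""
    rows = []
    for gene, states in states_per_gene.items():
        for pair in PAIR_KEYS:
            s = states[pair]
            if s == "ns":
                delta, p = 0.1, 0.9
            else:
                delta, p = (1.0, 1e-4) if s == "up" else (-1.0, 1e-4)
            rows.append(
                {
                    "gene": gene, "pair": pair, "delta_log2": delta,
                    "fold_change": 2 ** abs(delta), "p": p, "p_adj": p,
                }
            )
    return pd.DataFrame(rows)


def test_definition_cases():
    table = _table_from_states(
        {
            # strict switching: up on F2, down on SK, switch between days
            "sw": {"F2_vs_AL": "up", "SK_vs_AL": "dn", "F2_vs_SK": "up",
                   "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"},
            # pure chronic up: both days up, days not different
            "ch": {"F2_vs_AL": "up", "SK_vs_AL": "up", "F2_vs_SK": "ns",
                   "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"},
            # chronic + switching, robust vs CR
            "cas": {"F2_vs_AL": "up", "SK_vs_AL": "up", "F2_vs_SK": "dn",
                    "CR_vs_AL": "ns", "F2_vs_CR": "up", "SK_vs_CR": "up"},
        }
    )
    calls = il.classify_gene_patterns(table)
    sw = calls.loc["sw"]
    assert sw.switching_strict and sw.switching_broad and not sw.chronic
    ch = calls.loc["ch"]
    assert ch.chronic and ch.chronic_pure and not ch.chronic_and_switching
    assert ch.chronic_direction == "up" and not ch.robust_chronic
    cas = calls.loc["cas"]
    assert cas.chronic and cas.chronic_and_switching and cas.robust_chronic
    assert not cas.switching_strict


def test_strict_switching_and_chronic_are_exclusive_exhaustively():
    states = {}
    for i, combo in enumerate(itertools.product(["ns", "up", "dn"], repeat=6)):
        states[f"g{i}"] = dict(zip(PAIR_KEYS, combo))
    calls = il.classify_gene_patterns(_table_from_states(states))
    assert not (calls["switching_strict"] & calls["chronic"]).any()
    assert not (calls["chronic_and_switching"] & calls["chronic_pure"]).any()
    assert (
        calls["chronic_and_switching"] | calls["chronic_pure"]
    ).equals(calls["chronic"])
    # strict implies the broad AL-side requirement
    strict = calls[calls.switching_strict]
    assert (strict["sig_F2_vs_AL"] & strict["sig_SK_vs_AL"]).all()
    # robust chronic implies chronic
    assert (~calls["robust_chronic"] | calls["chronic"]).all()


def test_missing_pair_rows_rejected():
    table = _table_from_states(
        {"g": dict(zip(PAIR_KEYS, ["up"] * 6))}
    )
    with pytest.raises(ValidationError):
        il.classify_gene_patterns(table[table["pair"] != "F2_vs_SK"])


def test_counts_stable_under_reordering():
    states = {}
    rng = np.random.default_rng(3)
    for i in range(60):
        states[f"g{i}"] = dict(
            zip(PAIR_KEYS, rng.choice(["ns", "up", "dn"], size=6))
        )
    table = _table_from_states(states)
    base = il.summarize_patterns(il.classify_gene_patterns(table))
    shuffled = table.sample(frac=1, random_state=11)
    again = il.summarize_patterns(il.classify_gene_patterns(shuffled))
    pd.testing.assert_frame_equal(base, again)


def test_summary_counts_fixture():
    states = {}
    for i in range(3):  # three strict switching
        states[f"sw{i}"] = {"F2_vs_AL": "up", "SK_vs_AL": "dn", "F2_vs_SK": "up",
                            "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"}
    for i in range(2):  # two pure chronic down
        states[f"ch{i}"] = {"F2_vs_AL": "dn", "SK_vs_AL": "dn", "F2_vs_SK": "ns",
                            "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"}
    summary = il.summarize_patterns(
        il.classify_gene_patterns(_table_from_states(states))
    )["count"]
    assert summary["switching_strict"] == 3
    assert summary["chronic"] == 2
    assert summary["chronic_down"] == 2
    assert summary["chronic_up"] == 0


def test_summary_empty_calls():
    calls = il.classify_gene_patterns(_table_from_states({}))
    summary = il.summarize_patterns(calls)
    assert (summary["count"] == 0).all()


def test_dedupe_identity_and_merging():
    states = {
        "ps1": {"F2_vs_AL": "up", "SK_vs_AL": "up", "F2_vs_SK": "ns",
                "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"},
        "ps2": {"F2_vs_AL": "up", "SK_vs_AL": "up", "F2_vs_SK": "ns",
                "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"},
        "ps3": {"F2_vs_AL": "dn", "SK_vs_AL": "dn", "F2_vs_SK": "ns",
                "CR_vs_AL": "ns", "F2_vs_CR": "ns", "SK_vs_CR": "ns"},
    }
    calls = il.classify_gene_patterns(_table_from_states(states))
    # identity map: output equals input
    ident, report = il.dedupe_to_genes(calls, None)
    assert len(ident) == 3 and not ident["discordant"].any()
    # ps1+ps2 same symbol, same direction -> one concordant call
    symbol_map = pd.Series({"ps1": "GENE_A", "ps2": "GENE_A", "ps3": "GENE_B"})
    merged, report = il.dedupe_to_genes(calls, symbol_map)
    assert len(merged) == 2
    assert merged.loc["GENE_A", "chronic"] and not merged.loc["GENE_A", "discordant"]
    assert merged.loc["GENE_A", "chronic_direction"] == "up"
    # opposite chronic directions -> discordant, direction dropped
    symbol_map2 = pd.Series({"ps1": "G", "ps2": "G", "ps3": "G"})
    merged2, report2 = il.dedupe_to_genes(calls, symbol_map2)
    assert merged2.loc["G", "discordant"]
    assert merged2.loc["G", "chronic_direction"] == "none"
    assert report2["discordant"].iloc[0]


def test_pattern_recovery_on_default_simulation(default_run):
    # planted chronic/switching classes should be called with near-perfect
    # precision; the companion recall bounds are exercised at full strength
    # by the acceptance suite
    truth = default_run["truth"]
    table = default_run["contrasts"]
    deg = default_run["deg"]
    calls = il.classify_gene_patterns(table[table["gene"].isin(deg)])
    chronic_truth = set(
        truth.index[
            truth.pattern_class.isin(
                ["chronic_up", "chronic_down", "chronic_and_switching_up"]
            )
        ]
    )
    called = set(calls.index[calls["chronic"]])
    assert len(called & chronic_truth) / max(len(called), 1) > 0.95
    assert len(called & chronic_truth) / len(chronic_truth) > 0.75
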