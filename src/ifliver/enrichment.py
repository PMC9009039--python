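"""Local pathway over-representation analysis (ORA).

A hypergeometric upper-tail test replaces the web-service annotation step:
for a cluster of n genes drawn from a universe of N annotated genes, a
pathway with K universe members and k overlap genes scores

    p = Σ_{i=k..min(K,n)} C(K,i)·C(N−K,n−i) / C(N,n).

An EASE-style variant (scoring k−1 instead of k, more conservative for small
overlaps) is available by flag.  p-values are BH-adjusted across pathways
within each tested gene set, and the overlap genes of the significant
pathways are partitioned into "shared" (appearing in two or more significant
pathways of that set) and "unique" (one pathway only).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .diffexpr import adjust_bh


def ora(
    cluster_genes: set,
    pathways: dict,
    universe: set,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of one gene set.

    Pathways are restricted to universe members; pathways with no overlap are
    reported with p = 1.  Returns one row per pathway: pathway, name, k
    (overlap), K (pathway size in universe), n (selected genes in universe),
    N (universe), p, p_adj, genes (comma-joined overlap).
    """
    if not universe:
        raise ValidationError("empty gene universe")
    universe = set(universe)
    selected = set(cluster_genes) & universe
    n, big_n = len(selected), len(universe)
    rows = []
    for pid in sorted(pathways):
        pw = pathways[pid]
        members = pw.genes & universe
        overlap = sorted(members & selected)
        k, big_k = len(overlap), len(members)
        if k == 0:
            p = 1.0
        else:
            shift = 1 if ease else 0
            # upper tail including k (sf is strictly-greater, hence k-1)
            p = float(stats.hypergeom.sf(k - 1 - shift, big_n, big_k, n))
            p = min(p, 1.0)
        rows.append(
            {
                "pathway": pid,
                "name": pw.name,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": p,
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "name", "k", "K", "n", "N", "p", "genes"]
    )
    table["p_adj"] = adjust_bh(table["p"].to_numpy()) if len(table) else []
    return table[["pathway", "name", "k", "K", "n", "N", "p", "p_adj", "genes"]]


def shared_unique(table: pd.DataFrame, significance: float = 0.05) -> pd.DataFrame:
    """Shared/unique partition of the overlap genes of significant pathways.

    A gene is "shared" when it occurs in two or more of the significant
    pathways of this gene set, "unique" when in exactly one; per pathway,
    unique + shared = k.
    """
    sig = table[table["p_adj"] < significance]
    membership: dict[str, int] = {}
    gene_lists = {}
    for _, row in sig.iterrows():
        genes = [g for g in str(row["genes"]).split(",") if g]
        gene_lists[row["pathway"]] = genes
        for g in genes:
            membership[g] = membership.get(g, 0) + 1
    rows = []
    for _, row in sig.iterrows():
        genes = gene_lists[row["pathway"]]
        shared = sum(1 for g in genes if membership[g] >= 2)
        rows.append(
            {
                "pathway": row["pathway"],
                "k": row["k"],
                "unique": len(genes) - shared,
                "shared": shared,
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "k", "unique", "shared"])


def coverage_stats(
    cluster_genes: set, pathways: dict, enriched: pd.DataFrame | None = None,
    significance: float = 0.05,
) -> tuple[float, float]:
    """Annotation coverage of a gene set.

    ``covered`` = fraction of the set's genes appearing in at least one
    pathway; ``tested`` = fraction of the covered genes appearing in at least
    one significant pathway (0 when nothing is covered or no enrichment table
    is given).
    """
    cluster_genes = set(cluster_genes)
    if not cluster_genes:
        return 0.0, 0.0
    annotated = set()
    for pw in pathways.values():
        annotated |= pw.genes
    covered_genes = cluster_genes & annotated
    covered = len(covered_genes) / len(cluster_genes)
    if not covered_genes or enriched is None:
        return covered, 0.0
    sig = enriched[enriched["p_adj"] < significance]
    in_sig = set()
    for g in sig["genes"]:
        in_sig |= {x for x in str(g).split(",") if x}
    tested = len(covered_genes & in_sig) / len(covered_genes)
    return covered, tested


def annotated_universe(pathways: dict, candidates: set | None = None) -> set:
    """Default gene universe: everything carrying at least one pathway
    annotation, optionally intersected with a candidate set (e.g. all probe
    sets on the array)."""
    universe: set = set()
    for pw in pathways.values():
        universe |= pw.genes
    if candidates is not None:
        universe &= set(candidates)
    return universe
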