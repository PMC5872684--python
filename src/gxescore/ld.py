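"""Linkage-disequilibrium pruning within a category's selected SNPs.

LD is measured as the squared Pearson correlation (r²) of additive allele
counts across pairwise-complete individuals — the composite-LD estimate one
gets directly from unphased genotypes. Pairs with r² strictly above the
threshold (0.7 by convention) are edges of an LD graph; within each
connected component only the SNP with the smallest screening p-value is
retained (ties broken by snp_id), so every correlated group contributes
exactly one SNP to the risk score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .containers import CategorySelection, GenotypeMatrix


def compute_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of allele counts; NaN when undefined.

    Undefined when fewer than two pairwise-complete individuals remain or
    either SNP has zero variance among them.
    """
    a = genotypes.column(snp_a)
    b = genotypes.column(snp_b)
    mask = a.notna() & b.notna()
    if int(mask.sum()) < 2:
        return float("nan")
    x = a[mask].to_numpy(dtype=float)
    y = b[mask].to_numpy(dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_edges(
    genotypes: GenotypeMatrix, snp_ids: list[str], threshold: float = 0.7
) -> pd.DataFrame:
    """All pairs among ``snp_ids`` with r² strictly above ``threshold``.

    r² exactly equal to the threshold is not an edge. Returns a DataFrame
    (snp_a, snp_b, r2) with snp_a < snp_b lexicographically.
    """
    rows = []
    ordered = sorted(snp_ids)
    for i, sa in enumerate(ordered):
        for sb in ordered[i + 1:]:
            r2 = compute_r2(genotypes, sa, sb)
            if np.isfinite(r2) and r2 > threshold:
                rows.append({"snp_a": sa, "snp_b": sb, "r2": r2})
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def prune_by_ld(
    selection: CategorySelection,
    genotypes: GenotypeMatrix,
    threshold: float = 0.7,
) -> CategorySelection:
    """Keep one SNP per LD connected component: the smallest-p member.

    Components are taken over the graph whose edges are pairs with
    r² > threshold. Grouping by connected components (rather than greedy
    sequential pruning) is deterministic and order-independent; p ties
    break lexicographically by snp_id. Survivors keep their coefficient,
    p-value and sign. Idempotent: pruning a pruned selection is a no-op.
    """
    table = selection.table
    if len(table) <= 1:
        return CategorySelection(category=selection.category, table=table.copy())
    edges = ld_edges(genotypes, list(table["snp_id"]), threshold)
    graph = nx.Graph()
    graph.add_nodes_from(table["snp_id"])
    graph.add_edges_from(edges[["snp_a", "snp_b"]].itertuples(index=False, name=None))

    by_id = table.set_index("snp_id")
    keep: list[str] = []
    for component in nx.connected_components(graph):
        ranked = sorted(component, key=lambda s: (by_id.loc[s, "p"], s))
        keep.append(ranked[0])
    pruned = table[table["snp_id"].isin(keep)].reset_index(drop=True)
    return CategorySelection(category=selection.category, table=pruned)
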