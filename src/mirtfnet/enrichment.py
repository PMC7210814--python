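"""Hypergeometric over-representation analysis against GMT annotations.

For each annotation term, the probability of observing at least the realized
overlap between the query set and the term's genes, out of the universe, is
the same hypergeometric upper tail used for the shared-TF statistic; BH
adjustment runs across all tested terms. A miRNA's query set is derived from
the refined network: its interacting mRNAs plus the TFs they share.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from mirtfnet.diffexpr import bh_adjust
from mirtfnet.regnet import hypergeom_upper_tail

__all__ = ["ora", "mirna_gene_set", "read_gmt"]


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: term id -> (description, gene set)."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return terms


def ora(
    query: set[str],
    universe: set[str],
    annotation: dict[str, tuple[str, set[str]]],
) -> pd.DataFrame:
    """Over-representation of the query set in each annotation term.

    Terms are intersected with the universe before testing; terms with no
    overlap with the query are omitted. Returns one row per tested term with
    counts and the BH-adjusted p-value.
    """
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term_id, (term_name, genes) in sorted(annotation.items()):
        term_genes = genes & universe
        overlap = len(term_genes & query)
        if overlap == 0:
            continue
        p = hypergeom_upper_tail(len(universe), len(term_genes), len(query), overlap)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "n_universe": len(universe),
                "n_term": len(term_genes),
                "n_query": len(query),
                "n_overlap": overlap,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "n_universe",
            "n_term",
            "n_query",
            "n_overlap",
            "p_value",
        ],
    )
    out["fdr"] = bh_adjust(out["p_value"]) if len(out) else pd.Series(dtype=float)
    return out.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def mirna_gene_set(
    mirna_id: str,
    refined_pairs: pd.DataFrame,
    network: nx.Graph,
) -> set[str]:
    """Gene set submitted to ORA for one miRNA.

    The union of the miRNA's refined mRNA partners and the TFs it shares with
    each of them in the triple network.
    """
    mine = refined_pairs[refined_pairs["mirna"] == mirna_id]
    if len(mine) == 0:
        raise KeyError(f"miRNA {mirna_id!r} absent from refined pairs")
    mirna_tfs = {
        nb for nb in network.neighbors(mirna_id) if network.nodes[nb]["ntype"] == "TF"
    }
    out: set[str] = set()
    for gene in mine["gene"]:
        gene_tfs = {
            nb for nb in network.neighbors(gene) if network.nodes[nb]["ntype"] == "TF"
        }
        out.add(gene)
        out |= mirna_tfs & gene_tfs
    return out
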