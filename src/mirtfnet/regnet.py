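"""Tripartite mRNA-TF-miRNA regulatory network assembly and refinement.

The network has three node classes and only two edge types: mRNA-TF edges
from promoter motif scanning and miRNA-TF edges from integrated candidate
tables. Candidate miRNA-TF pairs are retained when the miRNA is
differentially expressed and the pair is confirmed in at least one of two
validation tables. miRNA-mRNA pairs are never edges; instead each pair is
scored by the hypergeometric tail probability of the number of TFs its two
endpoints share, out of the TF universe.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd
from scipy import stats
from scipy.special import comb

__all__ = [
    "integrate_mirna_tf",
    "build_triple_network",
    "bridge_tfs",
    "shared_tf_pvalue",
    "hypergeom_upper_tail",
    "refine_pairs",
    "network_stats",
    "to_edge_list",
]

NODE_TYPES = ("mRNA", "TF", "miRNA")


def _pair_set(table: pd.DataFrame, a: str, b: str) -> set[tuple[str, str]]:
    return set(zip(table[a].astype(str), table[b].astype(str)))


def integrate_mirna_tf(
    primary: pd.DataFrame,
    val1: pd.DataFrame,
    val2: pd.DataFrame,
    de_mirnas: set[str],
) -> pd.DataFrame:
    """Retain primary miRNA-TF pairs that are DE and validated at least once.

    All tables need ``mirna`` and ``tf`` columns. A primary pair survives when
    its miRNA is in ``de_mirnas`` and the pair appears in val1 or val2;
    provenance flags record which validation table(s) confirmed it.
    """
    for name, table in (("primary", primary), ("val1", val1), ("val2", val2)):
        if not {"mirna", "tf"}.issubset(table.columns):
            raise ValueError(f"{name} table must have 'mirna' and 'tf' columns")
    v1 = _pair_set(val1, "mirna", "tf")
    v2 = _pair_set(val2, "mirna", "tf")
    rows = []
    seen = set()
    for mirna, tf in _pair_set(primary, "mirna", "tf"):
        if (mirna, tf) in seen:
            continue
        seen.add((mirna, tf))
        in1, in2 = (mirna, tf) in v1, (mirna, tf) in v2
        if mirna in de_mirnas and (in1 or in2):
            rows.append(
                {
                    "mirna": mirna,
                    "tf": tf,
                    "in_primary": True,
                    "validated_db1": in1,
                    "validated_db2": in2,
                }
            )
    out = pd.DataFrame(
        rows, columns=["mirna", "tf", "in_primary", "validated_db1", "validated_db2"]
    )
    return out.sort_values(["mirna", "tf"]).reset_index(drop=True)


def build_triple_network(mrna_tf: pd.DataFrame, mirna_tf: pd.DataFrame) -> nx.Graph:
    """Assemble the tripartite graph from the two typed edge tables.

    ``mrna_tf`` needs columns gene/tf, ``mirna_tf`` needs mirna/tf. TF ids
    occurring in both tables become single TF nodes. Edges are deduplicated.
    An id used as both an mRNA (or miRNA) and a TF is an identity clash.
    """
    g = nx.Graph()
    if len(mrna_tf) == 0 and len(mirna_tf) == 0:
        warnings.warn("both edge tables empty; returning empty network")
        return g
    mrnas = set(mrna_tf["gene"].astype(str)) if len(mrna_tf) else set()
    mirnas = set(mirna_tf["mirna"].astype(str)) if len(mirna_tf) else set()
    tfs = set()
    if len(mrna_tf):
        tfs |= set(mrna_tf["tf"].astype(str))
    if len(mirna_tf):
        tfs |= set(mirna_tf["tf"].astype(str))
    clash = (mrnas | mirnas) & tfs
    if clash:
        raise ValueError(f"ids used as both TF and mRNA/miRNA: {sorted(clash)[:5]}")
    if mrnas & mirnas:
        raise ValueError(
            f"ids used as both mRNA and miRNA: {sorted(mrnas & mirnas)[:5]}"
        )
    for node_set, ntype in ((mrnas, "mRNA"), (tfs, "TF"), (mirnas, "miRNA")):
        g.add_nodes_from(node_set, ntype=ntype)
    if len(mrna_tf):
        g.add_edges_from(_pair_set(mrna_tf, "gene", "tf"))
    if len(mirna_tf):
        g.add_edges_from(_pair_set(mirna_tf, "mirna", "tf"))
    assert_edge_types(g)
    return g


def assert_edge_types(g: nx.Graph) -> None:
    """Raise if the graph contains a forbidden edge type."""
    allowed = {frozenset(("mRNA", "TF")), frozenset(("miRNA", "TF"))}
    for u, v in g.edges:
        kinds = frozenset((g.nodes[u]["ntype"], g.nodes[v]["ntype"]))
        if kinds not in allowed:
            raise ValueError(f"forbidden edge {u}-{v} of types {sorted(kinds)}")


def _nodes_of_type(g: nx.Graph, ntype: str) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("ntype") == ntype}


def bridge_tfs(g: nx.Graph) -> set[str]:
    """TFs adjacent to at least one mRNA and at least one miRNA."""
    out = set()
    for tf in _nodes_of_type(g, "TF"):
        kinds = {g.nodes[nb]["ntype"] for nb in g.neighbors(tf)}
        if "mRNA" in kinds and "miRNA" in kinds:
            out.add(tf)
    return out


def _check_counts(N: int, m: int, n: int, k: int) -> None:
    if not (0 <= k <= min(m, n) and m <= N and n <= N and N >= 0):
        raise ValueError(f"invalid hypergeometric counts N={N}, m={m}, n={n}, k={k}")


def hypergeom_upper_tail(N: int, m: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n)."""
    _check_counts(N, m, n, k)
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def shared_tf_pvalue(N: int, m: int, n: int, k: int, mode: str = "upper_tail") -> float:
    """Significance of a miRNA-mRNA pair sharing k TFs.

    Out of N TFs, m interact with the mRNA and n with the miRNA; k are
    shared. ``upper_tail`` (default) is the proper enrichment tail
    P(X >= k) of the hypergeometric; ``paper_literal`` is the single-term
    complement 1 - C(m,k) C(N-m, n-k) / C(N,n) kept for fidelity
    experiments.
    """
    if mode == "upper_tail":
        return hypergeom_upper_tail(N, m, n, k)
    if mode == "paper_literal":
        _check_counts(N, m, n, k)
        term = comb(m, k, exact=True) * comb(N - m, n - k, exact=True)
        return 1.0 - term / comb(N, n, exact=True)
    raise ValueError(f"unknown mode {mode!r}")


def refine_pairs(
    g: nx.Graph,
    alpha: float = 0.05,
    mode: str = "upper_tail",
    tf_universe: int | None = None,
) -> pd.DataFrame:
    """Score every miRNA-mRNA pair sharing >= 1 TF with the shared-TF test.

    The TF universe N defaults to the number of TF nodes in the network;
    pass ``tf_universe`` to use the full motif-library size instead. Output
    has one row per pair with counts (N, m, n, k), the p-value, and a
    ``significant`` flag at raw p < alpha, sorted by p then ids.
    """
    mrnas = _nodes_of_type(g, "mRNA")
    mirnas = _nodes_of_type(g, "miRNA")
    if not mrnas or not mirnas:
        raise ValueError("network needs at least one mRNA and one miRNA")
    all_tfs = _nodes_of_type(g, "TF")
    N = tf_universe if tf_universe is not None else len(all_tfs)
    rows = []
    for mirna in sorted(mirnas):
        mirna_tfs = set(g.neighbors(mirna)) & all_tfs
        for mrna in sorted(mrnas):
            mrna_tfs = set(g.neighbors(mrna)) & all_tfs
            k = len(mirna_tfs & mrna_tfs)
            if k == 0:
                continue
            m, n = len(mrna_tfs), len(mirna_tfs)
            p = shared_tf_pvalue(N, m, n, k, mode=mode)
            rows.append(
                {
                    "mirna": mirna,
                    "gene": mrna,
                    "N": N,
                    "m": m,
                    "n": n,
                    "k": k,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["mirna", "gene", "N", "m", "n", "k", "p_value", "significant"],
    )
    return out.sort_values(["p_value", "mirna", "gene"]).reset_index(drop=True)


def network_stats(g: nx.Graph) -> dict:
    """Node counts by type, edge count, and the per-node degree table."""
    degrees = pd.Series(dict(g.degree), dtype=int).sort_index()
    return {
        "n_mrna": len(_nodes_of_type(g, "mRNA")),
        "n_tf": len(_nodes_of_type(g, "TF")),
        "n_mirna": len(_nodes_of_type(g, "miRNA")),
        "n_edges": g.number_of_edges(),
        "degrees": degrees,
    }


def to_edge_list(g: nx.Graph) -> pd.DataFrame:
    """Edge table (source, target, source_type, target_type) for export."""
    rows = [
        {
            "source": u,
            "target": v,
            "source_type": g.nodes[u]["ntype"],
            "target_type": g.nodes[v]["ntype"],
        }
        for u, v in sorted(g.edges)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "source_type", "target_type"])
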