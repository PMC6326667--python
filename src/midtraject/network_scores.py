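"""Interaction-network scoring of environment-responsive transducer genes.

Builds an undirected interaction graph over class-assigned genes (self-loops
are stored but excluded from every topological measure) and computes, per
gene: topological relevance (degree by default), the class-2/3 neighbourhood
ratio n2/(n2+n3), and the relative enrichment-compensation score
clip(1 - |fc_residual| / |fc_disturbance|, 0, 1), where the disturbance
fold-change is TG-12-SE vs WT-12-SE and the residual one TG-12-EE vs
WT-12-SE. Candidates are ranked by EE responsiveness, then topological
relevance, then compensation.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "MalformedEdgeError",
    "read_sif",
    "read_edge_tsv",
    "build_graph",
    "topological_relevance",
    "neighbourhood_ratio",
    "compensation_score",
    "score_genes",
    "rank_candidates",
    "write_sif",
]


class MalformedEdgeError(ValueError):
    """An edge row could not be parsed; carries the 1-based line number."""


def read_sif(path) -> pd.DataFrame:
    """Read a simple-interaction-format file (node TAB relation TAB node)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not parts[0] or not parts[2]:
                raise MalformedEdgeError(f"line {lineno}: malformed SIF row {line[:60]!r}")
            rows.append({"source": parts[0], "target": parts[2], "interaction": parts[1]})
    return pd.DataFrame(rows, columns=["source", "target", "interaction"])


def read_edge_tsv(path) -> pd.DataFrame:
    """Read a two/three-column edge list (source, target[, interaction])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise MalformedEdgeError("edge table needs at least two columns")
    df = df.rename(columns=dict(zip(df.columns[:3], ["source", "target", "interaction"])))
    if "interaction" not in df.columns:
        df["interaction"] = "pp"
    return df[["source", "target", "interaction"]]


def build_graph(edges: pd.DataFrame, node_annotations: pd.DataFrame | None = None) -> nx.Graph:
    """Deduplicated undirected graph with class/cluster node attributes.

    Self-loops are kept in the graph (so the input is echoed faithfully) but
    marked ``self_loop`` and ignored by all metrics. Endpoints missing from
    the annotation table are flagged ``known=False``. Malformed rows (empty
    or missing ids) raise with their row number.
    """
    G = nx.Graph()
    for i, row in enumerate(edges.itertuples(index=False), start=1):
        u, v = row.source, row.target
        if not isinstance(u, str) or not isinstance(v, str) or not u or not v:
            raise MalformedEdgeError(f"row {i}: malformed edge ({u!r}, {v!r})")
        interaction = getattr(row, "interaction", "pp")
        G.add_edge(u, v, interaction=interaction, self_loop=(u == v))
    if node_annotations is not None:
        for n in G.nodes:
            known = n in node_annotations.index
            G.nodes[n]["known"] = known
            if known:
                G.nodes[n]["class_label"] = int(node_annotations.loc[n, "class_label"])
                if "cluster" in node_annotations.columns:
                    G.nodes[n]["cluster"] = node_annotations.loc[n, "cluster"]
    return G


def _loopless(G: nx.Graph) -> nx.Graph:
    H = G.copy()
    H.remove_edges_from(nx.selfloop_edges(H))
    return H


def topological_relevance(G: nx.Graph, method: str = "degree") -> pd.Series:
    """Per-node topological relevance: degree (default) or betweenness,
    always ignoring self-loops."""
    H = _loopless(G)
    if method == "degree":
        values = dict(H.degree())
    elif method == "betweenness":
        values = nx.betweenness_centrality(H)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(values, name="topological_relevance").sort_index()


def neighbourhood_ratio(G: nx.Graph) -> pd.Series:
    """Fraction of a node's class-2-or-3 neighbours that are class 2;
    NaN when a node has no class-2/3 neighbour (self excluded)."""
    out = {}
    for n in G.nodes:
        n2 = n3 = 0
        for m in G.neighbors(n):
            if m == n:
                continue
            c = G.nodes[m].get("class_label")
            if c == 2:
                n2 += 1
            elif c == 3:
                n3 += 1
        out[n] = n2 / (n2 + n3) if (n2 + n3) else np.nan
    return pd.Series(out, name="neighbourhood_ratio").sort_index()


def compensation_score(fc_disturbance, fc_residual):
    """Relative compensation through enriched housing, on the log2 scale:
    clip(1 - |residual| / |disturbance|, 0, 1); NaN where the disturbance
    fold-change is zero."""
    dist = np.asarray(fc_disturbance, dtype=float)
    res = np.asarray(fc_residual, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.clip(1.0 - np.abs(res) / np.abs(dist), 0.0, 1.0)
    score = np.where(dist == 0, np.nan, score)
    return score if score.ndim else float(score)


def score_genes(
    G: nx.Graph,
    fc_disturbance: pd.Series,
    fc_residual: pd.Series,
    ee_deg_genes,
    method: str = "degree",
) -> pd.DataFrame:
    """Assemble the per-gene network score table for all graph nodes."""
    nodes = pd.Index(sorted(G.nodes), name="gene_id")
    dist = fc_disturbance.reindex(nodes)
    res = fc_residual.reindex(nodes)
    comp = compensation_score(dist.fillna(0.0).to_numpy(), res.fillna(0.0).to_numpy())
    comp = np.where(dist.isna() | res.isna(), np.nan, comp)
    return pd.DataFrame(
        {
            "topological_relevance": topological_relevance(G, method).reindex(nodes),
            "neighbourhood_ratio": neighbourhood_ratio(G).reindex(nodes),
            "compensation": comp,
            "ee_responsive": nodes.isin(set(ee_deg_genes)),
            "class_label": [G.nodes[n].get("class_label", -1) for n in nodes],
        },
        index=nodes,
    )


def rank_candidates(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank transducer candidates: EE-responsive first, then by degree, then
    by compensation; lexicographic gene id breaks ties. Non-responsive genes
    are retained at the bottom, flagged by the ee_responsive column."""
    out = scores.copy()
    comp = out["compensation"].fillna(-1.0)
    out = out.assign(_comp=comp)
    out = out.sort_values(
        by=["ee_responsive", "topological_relevance", "_comp"],
        ascending=[False, False, False],
        kind="stable",
    )
    # stable sort keeps the lexicographic index order within ties
    out = out.drop(columns="_comp")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def write_sif(G: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(G.edges(data=True)):
            fh.write(f"{u}\t{data.get('interaction', 'pp')}\t{v}\n")
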