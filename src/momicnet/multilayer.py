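"""Cross-layer module integration.

After each omics layer has been reduced to module eigengenes, modules from
different layers are linked by directly correlating their eigengenes. The
reduction to a handful of eigengenes keeps the number of tests small, which
is what gives the cross-layer correlations their statistical power. Edges
surviving a joint Benjamini-Hochberg filter form a multilayer module graph,
anchored to a contextual trait: each node carries its module-trait
correlation, and the hive layout places one axis per layer with modules
ordered radially by that correlation. Any two linked modules can then be
expanded into a bipartite feature-level network by correlating their member
features two by two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, correlation_pvalues, cross_correlation
from .preprocess import OmicsLayer
from .wcna import ModulePartition, ModuleTraitReport

__all__ = [
    "MultiLayerGraph",
    "eigengene_cross_correlation",
    "build_multilayer_graph",
    "hive_layout",
    "bipartite_feature_network",
]


@dataclass
class MultiLayerGraph:
    """Module nodes across layers plus significant eigengene-correlation edges.

    ``nodes`` columns: layer, module, size, trait_r, trait_q, trait_column.
    ``edges`` columns: layer_a, module_a, layer_b, module_b, r, p, q.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    anchor_trait: str
    alpha: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(anchor_trait=self.anchor_trait, alpha=self.alpha)
        for _, row in self.nodes.iterrows():
            g.add_node(
                f"{row['layer']}:{row['module']}",
                layer=row["layer"],
                module=int(row["module"]),
                size=int(row["size"]),
                trait_r=float(row["trait_r"]),
                trait_q=float(row["trait_q"]),
            )
        for _, row in self.edges.iterrows():
            g.add_edge(
                f"{row['layer_a']}:{row['module_a']}",
                f"{row['layer_b']}:{row['module_b']}",
                r=float(row["r"]),
                p=float(row["p"]),
                q=float(row["q"]),
            )
        return g


def eigengene_cross_correlation(
    eigengene_sets: dict[str, pd.DataFrame], method: str = "pearson"
) -> pd.DataFrame:
    """Correlate every module eigengene with every module of *other* layers.

    Returns one row per inter-layer module pair with r, t-based p, and BH q
    adjusted jointly over all inter-layer pairs. Within-layer pairs are
    never tested. Layer order does not affect the result.
    """
    names = sorted(eigengene_sets)
    if len(names) < 2:
        raise ValueError("need eigengenes from at least 2 layers")
    index = eigengene_sets[names[0]].index
    for nm in names[1:]:
        if list(eigengene_sets[nm].index) != list(index):
            raise ValueError("eigengene matrices must share sample order")
    n = len(index)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for i, la in enumerate(names):
        for lb in names[i + 1 :]:
            ea, eb = eigengene_sets[la], eigengene_sets[lb]
            if ea.shape[1] == 0 or eb.shape[1] == 0:
                continue
            r = cross_correlation(ea.to_numpy(), eb.to_numpy(), method=method)
            p = correlation_pvalues(r, n)
            for ai, ma in enumerate(ea.columns):
                for bi, mb in enumerate(eb.columns):
                    rows.append(
                        {
                            "layer_a": la,
                            "module_a": int(str(ma).removeprefix("ME")),
                            "layer_b": lb,
                            "module_b": int(str(mb).removeprefix("ME")),
                            "r": r[ai, bi],
                            "p": p[ai, bi],
                        }
                    )
    edges = pd.DataFrame(rows)
    if len(edges):
        edges["q"] = bh_adjust(edges["p"].to_numpy())
    else:
        edges["q"] = pd.Series(dtype=float)
    return edges


def _anchor_association(
    report: ModuleTraitReport, module: int, anchor_trait: str
) -> tuple[float, float, str]:
    """Trait r/q for one module; qualitative anchors use the max-|r| level."""
    name = f"ME{module}"
    cols = [
        c
        for c in report.r.columns
        if c == anchor_trait or str(c).startswith(f"{anchor_trait}=")
    ]
    if not cols:
        raise KeyError(f"anchor trait {anchor_trait!r} not in trait report")
    rs = report.r.loc[name, cols].astype(float)
    best = rs.abs().idxmax()
    return float(report.r.loc[name, best]), float(report.q.loc[name, best]), str(best)


def build_multilayer_graph(
    edges: pd.DataFrame,
    trait_reports: dict[str, ModuleTraitReport],
    module_sizes: dict[str, dict[int, int]],
    anchor_trait: str,
    alpha: float = 0.05,
) -> MultiLayerGraph:
    """Filter eigengene edges at BH ``q <= alpha`` and anchor nodes to a trait.

    Isolated nodes are kept only when their own trait association passes
    ``alpha``; everything else is dropped, matching the display rule that
    modules with no significant association are not shown.
    """
    node_rows = []
    for layer, report in trait_reports.items():
        sizes = module_sizes.get(layer, {})
        for name in report.r.index:
            module = int(str(name).removeprefix("ME"))
            r, q, col = _anchor_association(report, module, anchor_trait)
            node_rows.append(
                {
                    "layer": layer,
                    "module": module,
                    "size": sizes.get(module, 0),
                    "trait_r": r,
                    "trait_q": q,
                    "trait_column": col,
                }
            )
    nodes = pd.DataFrame(node_rows)
    kept_edges = (
        edges[edges["q"] <= alpha].reset_index(drop=True)
        if len(edges)
        else edges.copy()
    )
    connected = set()
    for _, e in kept_edges.iterrows():
        connected.add((e["layer_a"], int(e["module_a"])))
        connected.add((e["layer_b"], int(e["module_b"])))
    if len(nodes):
        keep = nodes.apply(
            lambda row: (row["layer"], int(row["module"])) in connected
            or (np.isfinite(row["trait_q"]) and row["trait_q"] <= alpha),
            axis=1,
        )
        nodes = nodes[keep].reset_index(drop=True)
    return MultiLayerGraph(
        nodes=nodes, edges=kept_edges, anchor_trait=anchor_trait, alpha=alpha
    )


def hive_layout(graph: MultiLayerGraph) -> pd.DataFrame:
    """Polar node positions: one axis per layer, radius = trait-r rank.

    Axes sit at 120-degree nominal angles; on each axis modules are ranked
    by their anchor-trait correlation (ties by module id) and the radius is
    the rank scaled to (0, 1], so the strongest association lies outermost.
    """
    if graph.nodes.empty:
        raise ValueError("cannot lay out an empty graph")
    layers = sorted(graph.nodes["layer"].unique())
    if len(layers) > 3:
        raise ValueError("hive layout supports at most 3 layers")
    angles = {ly: 90.0 + 120.0 * i for i, ly in enumerate(layers)}
    rows = []
    for ly in layers:
        sub = graph.nodes[graph.nodes["layer"] == ly].copy()
        sub = sub.sort_values(["trait_r", "module"], kind="mergesort")
        k = len(sub)
        for rank, (_, row) in enumerate(sub.iterrows(), start=1):
            rows.append(
                {
                    "layer": ly,
                    "module": int(row["module"]),
                    "angle_deg": angles[ly] % 360.0,
                    "radius": rank / k,
                    "trait_r": float(row["trait_r"]),
                }
            )
    return pd.DataFrame(rows)


def bipartite_feature_network(
    layer_a: OmicsLayer,
    partition_a: ModulePartition,
    module_a: int,
    layer_b: OmicsLayer,
    partition_b: ModulePartition,
    module_b: int,
    method: str = "spearman",
    threshold: float = 0.35,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level links between two modules from different layers.

    All member features of the two modules are correlated two by two;
    pairs with ``|r| > threshold`` become edges (p and BH q over the full
    cross matrix are attached for optional post-filtering). Returns
    ``(edges, dense correlation matrix)``; the matrix feeds the heatmap view.
    """
    if layer_a.sample_ids != layer_b.sample_ids:
        raise ValueError("layers must share the same samples in the same order")
    feats_a = partition_a.members(module_a)
    feats_b = partition_b.members(module_b)
    if not feats_a or not feats_b:
        raise ValueError("both modules must be nonempty")
    xa = layer_a.data[feats_a].to_numpy(dtype=float)
    xb = layer_b.data[feats_b].to_numpy(dtype=float)
    r = cross_correlation(xa, xb, method=method)
    p = correlation_pvalues(r, xa.shape[0])
    q = bh_adjust(p)
    matrix = pd.DataFrame(r, index=feats_a, columns=feats_b)
    ia, ib = np.where(np.abs(r) > threshold)
    edges = pd.DataFrame(
        {
            "feature_a": np.asarray(feats_a)[ia],
            "feature_b": np.asarray(feats_b)[ib],
            "r": r[ia, ib],
            "p": p[ia, ib],
            "q": q[ia, ib],
        }
    )
    edges.attrs["method"] = method
    edges.attrs["threshold"] = threshold
    return edges, matrix
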