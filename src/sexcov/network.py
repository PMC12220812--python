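"""Networks of significantly sex-biased covariance edges.

Regions enter the graph only through a significant edge (isolated
regions are excluded); nodes carry the volumetric sex-bias status, edges
the direction of the covariance difference. Connected components are
ranked deterministically and summarized as tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .sexdiff import SexDiffResult, _sign_factor
from .volumetrics import VolumetricEffects


def build_graph(sexdiff: SexDiffResult,
                effects: VolumetricEffects | None = None) -> nx.Graph:
    """Graph over exactly the FDR-significant edges.

    Node attribute ``sex_biased`` comes from the volumetric effects
    (``none`` if not supplied); edge attributes: ``bias``
    (female_biased / male_biased from the sign of D under the result's
    convention), ``abs_D`` and ``q``.
    """
    sign = _sign_factor(sexdiff.sign_convention)
    g = nx.Graph()
    for _, row in sexdiff.significant_edges().iterrows():
        d_mmf = sign * row["D"]  # on the male-minus-female scale
        bias = "male_biased" if d_mmf > 0 else "female_biased"
        g.add_edge(row["region_i"], row["region_j"],
                   bias=bias, abs_D=abs(row["D"]), q=row["q"])
    if effects is not None:
        status = effects.table["sex_biased"]
        for node in g.nodes:
            g.nodes[node]["sex_biased"] = str(status.get(node, "none"))
    else:
        nx.set_node_attributes(g, "none", "sex_biased")
    return g


def connected_components(graph: nx.Graph, top_k: int = 1) -> list[nx.Graph]:
    """Top-k connected components, ranked by node count, then edge count,
    then lexicographically smallest member id; deterministic."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    comps = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-c.number_of_nodes(), -c.number_of_edges(),
                              min(c.nodes)))
    return comps[:top_k]


@dataclass
class ComponentSummary:
    n_nodes: int
    n_edges: int
    female_edges: int
    male_edges: int
    male_biased_nodes: int
    female_biased_nodes: int
    edges_both_endpoints_biased: int
    edges_one_endpoint_biased: int
    edges_neither_endpoint_biased: int
    centers: list[str]

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["centers"] = ";".join(self.centers)
        return d


def summarize_component(component: nx.Graph) -> ComponentSummary:
    """Counts of nodes, edge-bias directions, volumetrically biased nodes,
    the edge cross-tabulation by endpoint bias, and the maximum-degree
    "center" nodes (ties reported jointly)."""
    if component.number_of_nodes() == 0:
        raise ValueError("component is empty")
    female_e = male_e = 0
    both = one = neither = 0
    for u, v, attrs in component.edges(data=True):
        if attrs.get("bias") == "female_biased":
            female_e += 1
        else:
            male_e += 1
        biased = sum(
            component.nodes[x].get("sex_biased", "none") != "none" for x in (u, v)
        )
        if biased == 2:
            both += 1
        elif biased == 1:
            one += 1
        else:
            neither += 1
    male_n = sum(1 for _, a in component.nodes(data=True)
                 if a.get("sex_biased") == "male")
    female_n = sum(1 for _, a in component.nodes(data=True)
                   if a.get("sex_biased") == "female")
    degrees = dict(component.degree())
    max_deg = max(degrees.values())
    centers = sorted(n for n, d in degrees.items() if d == max_deg)
    return ComponentSummary(
        n_nodes=component.number_of_nodes(),
        n_edges=component.number_of_edges(),
        female_edges=female_e, male_edges=male_e,
        male_biased_nodes=male_n, female_biased_nodes=female_n,
        edges_both_endpoints_biased=both,
        edges_one_endpoint_biased=one,
        edges_neither_endpoint_biased=neither,
        centers=centers,
    )


def graph_edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Edge-list export with node- and edge-attribute columns."""
    rows = []
    for u, v, attrs in sorted(graph.edges(data=True),
                              key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        a, b = sorted((u, v))
        rows.append({
            "region_i": a, "region_j": b,
            "bias": attrs.get("bias"), "abs_D": attrs.get("abs_D"),
            "q": attrs.get("q"),
            "region_i_sex_biased": graph.nodes[a].get("sex_biased", "none"),
            "region_j_sex_biased": graph.nodes[b].get("sex_biased", "none"),
        })
    return pd.DataFrame(
        rows, columns=["region_i", "region_j", "bias", "abs_D", "q",
                       "region_i_sex_biased", "region_j_sex_biased"],
    )
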