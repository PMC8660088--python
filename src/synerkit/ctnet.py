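"""Component–target (C-T) network construction and topology analytics.

The C-T network is an undirected bipartite graph linking chemical components
(labelled by their source herb) to the proteins they are predicted to act on.
Its topology carries the synergy argument: targets wired to components of
*both* herbs ("common targets") sit disproportionately among the high-degree
hubs, and the per-component centralities feed the synergy-contribution model.

Betweenness centralities follow the Cytoscape NetworkAnalyzer convention:
shortest-path betweenness normalised by ``(n−1)(n−2)/2`` within each connected
component of the undirected graph. Per-herb centralities (``CB``/``CK``) are
recomputed on the subgraph induced by one herb's components plus all of their
targets. A chemical present in both herbs (two component records sharing a
``name``) receives a centrality from each herb subgraph; a single-herb
chemical appears in only one and gets 0 for the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .adme import HERB_A, HERB_B, ComponentRecord
from .utils import round_half_up

logger = logging.getLogger("synerkit.ctnet")

COMPONENT = "component"
TARGET = "target"


@dataclass
class TargetPartition:
    """Disjoint split of the target nodes by herb coverage."""

    common: set[str]
    unique_a: set[str]
    unique_b: set[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.common), len(self.unique_a), len(self.unique_b)


def build_graph(
    edges: Iterable[tuple[str, str]], components: Sequence[ComponentRecord]
) -> nx.Graph:
    """Assemble the bipartite C-T graph from an edge list.

    Every edge's component id must appear in ``components``; duplicate edges
    are collapsed (with a logged count) and self-pairs rejected. Component
    nodes carry ``herb`` and ``name`` attributes; all nodes carry ``kind``.
    """
    by_id = {c.id: c for c in components}
    g = nx.Graph()
    for c in components:
        # components with no edges are retained as isolated nodes so the
        # SCD table can keep them with score 0
        g.add_node(c.id, kind=COMPONENT, herb=c.herb, name=c.name)
    n_dup = 0
    for cid, tid in edges:
        if cid not in by_id:
            raise ValueError(f"edge references unknown component id {cid!r}")
        if cid == tid:
            raise ValueError(f"self-pair {cid!r}-{tid!r} is not a valid C-T edge")
        if tid in by_id:
            raise ValueError(f"edge target {tid!r} collides with a component id")
        if g.has_edge(cid, tid):
            n_dup += 1
            continue
        g.add_node(tid, kind=TARGET)
        g.add_edge(cid, tid)
    if n_dup:
        logger.warning("collapsed %d duplicate component–target pairs", n_dup)
    return g


def component_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d["kind"] == COMPONENT]


def target_nodes(g: nx.Graph) -> list[str]:
    return [n for n, d in g.nodes(data=True) if d["kind"] == TARGET]


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Shortest-path betweenness, normalised per connected component.

    Each connected component of size n is treated on its own, dividing raw
    pair counts by (n−1)(n−2)/2; components of size < 3 get all zeros.
    """
    out: dict[str, float] = {}
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def herb_subgraph(g: nx.Graph, herb: str) -> nx.Graph:
    """Subgraph induced by one herb's components plus all their targets."""
    comps = [n for n, d in g.nodes(data=True) if d["kind"] == COMPONENT and d.get("herb") == herb]
    targets = {t for c in comps for t in g.neighbors(c)}
    return g.subgraph(set(comps) | targets)


def node_topology(g: nx.Graph) -> pd.DataFrame:
    """Per-node topology table feeding the SCD model.

    Columns for every node: ``kind``, ``degree``, ``betweenness``. Component
    rows additionally carry:

    * ``Ce`` — the component's own edge count (its degree);
    * ``Te`` — summed degree of all its targets;
    * ``target_betweenness_sum`` — summed betweenness of its targets;
    * ``CB``/``CK`` — betweenness in the herb-B / herb-A subgraph. When the
      same chemical name occurs in both herbs, each record inherits the other
      herb's record centrality for the missing side and is marked
      ``single_herb = False``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute topology of an empty graph")
    bet = betweenness(g)
    bet_a = betweenness(herb_subgraph(g, HERB_A))
    bet_b = betweenness(herb_subgraph(g, HERB_B))

    # name -> {herb: [component ids]} to link cross-herb occurrences
    by_name: dict[str, dict[str, list[str]]] = {}
    for n, d in g.nodes(data=True):
        if d["kind"] == COMPONENT and d.get("name"):
            by_name.setdefault(d["name"], {}).setdefault(d["herb"], []).append(n)

    rows = []
    for n, d in sorted(g.nodes(data=True)):
        row: dict[str, object] = {
            "node": n,
            "kind": d["kind"],
            "herb": d.get("herb", ""),
            "degree": g.degree(n),
            "betweenness": bet[n],
        }
        if d["kind"] == COMPONENT:
            targets = list(g.neighbors(n))
            row["Ce"] = len(targets)
            row["Te"] = sum(g.degree(t) for t in targets)
            row["target_betweenness_sum"] = float(sum(bet[t] for t in targets))
            ck = bet_a.get(n, 0.0)
            cb = bet_b.get(n, 0.0)
            herbs_of_name = by_name.get(d.get("name") or "", {})
            single = len(herbs_of_name) <= 1
            if not single:
                # inherit the partner record's centrality for the other herb
                if d["herb"] == HERB_A:
                    partners = herbs_of_name.get(HERB_B, [])
                    cb = max((bet_b.get(p, 0.0) for p in partners), default=0.0)
                else:
                    partners = herbs_of_name.get(HERB_A, [])
                    ck = max((bet_a.get(p, 0.0) for p in partners), default=0.0)
            row["CB"] = cb
            row["CK"] = ck
            row["single_herb"] = single
        rows.append(row)
    df = pd.DataFrame(rows).set_index("node")
    return df


def partition_targets(g: nx.Graph) -> TargetPartition:
    """Split targets into common (both herbs) and herb-unique sets."""
    common: set[str] = set()
    unique_a: set[str] = set()
    unique_b: set[str] = set()
    for t in target_nodes(g):
        herbs = set()
        for c in g.neighbors(t):
            h = g.nodes[c].get("herb")
            if h is None:
                raise ValueError(f"component {c!r} has no herb label")
            herbs.add(h)
        if herbs == {HERB_A, HERB_B}:
            common.add(t)
        elif herbs == {HERB_A}:
            unique_a.add(t)
        elif herbs == {HERB_B}:
            unique_b.add(t)
        # isolated targets cannot occur: targets only enter via edges
    logger.info(
        "target partition: %d common, %d unique to herb A, %d unique to herb B",
        len(common), len(unique_a), len(unique_b),
    )
    return TargetPartition(common=common, unique_a=unique_a, unique_b=unique_b)


def threshold_sweep(g: nx.Graph, partition: TargetPartition) -> pd.DataFrame:
    """Share of each target class among targets of degree ≥ t, for t = 1…max.

    Retention uses ``degree >= t``. Shares are percentages of the retained
    target set, rounded half-up to 2 decimals; an empty retained set yields a
    row with null shares.
    """
    deg = {t: g.degree(t) for t in target_nodes(g)}
    if not deg:
        raise ValueError("graph has no targets to sweep")
    rows = []
    for t in range(1, max(deg.values()) + 1):
        kept = [x for x, d in deg.items() if d >= t]
        if not kept:
            rows.append(
                {"threshold": t, "n_retained": 0, "pct_common": np.nan,
                 "pct_unique_a": np.nan, "pct_unique_b": np.nan}
            )
            continue
        n = len(kept)
        kept_set = set(kept)
        rows.append(
            {
                "threshold": t,
                "n_retained": n,
                "pct_common": round_half_up(100 * len(kept_set & partition.common) / n, 2),
                "pct_unique_a": round_half_up(100 * len(kept_set & partition.unique_a) / n, 2),
                "pct_unique_b": round_half_up(100 * len(kept_set & partition.unique_b) / n, 2),
            }
        )
    return pd.DataFrame(rows)


def network_summary(g: nx.Graph, hub_degree: int = 120) -> dict[str, float]:
    """Headline counts and means of the C-T network.

    Means (targets per component, components per target) are rounded half-up
    to 2 decimals; the share of components with degree strictly above
    ``hub_degree`` is rounded half-up to 1 decimal.
    """
    comps = component_nodes(g)
    targets = target_nodes(g)
    if not comps or not targets:
        raise ValueError("network summary needs at least one component and one target")
    n_edges = g.number_of_edges()
    hubs = [c for c in comps if g.degree(c) > hub_degree]
    return {
        "n_components": len(comps),
        "n_targets": len(targets),
        "n_edges": n_edges,
        "mean_targets_per_component": round_half_up(n_edges / len(comps), 2),
        "mean_components_per_target": round_half_up(n_edges / len(targets), 2),
        "n_hub_components": len(hubs),
        "hub_component_pct": round_half_up(100 * len(hubs) / len(comps), 1),
    }


# ---------------------------------------------------------------------------
# extended topology parameters for the docking index
#
# The docking index aggregates eight per-node parameters as computed by
# Cytoscape's NetworkAnalyzer. networkx provides the first four directly; the
# remaining conventions (radiality, neighborhood connectivity, topological
# coefficient) are implemented here to match NetworkAnalyzer's definitions on
# undirected graphs, per connected component.

NI_PARAMETERS = (
    "degree",
    "betweenness",
    "closeness",
    "avg_shortest_path",
    "eccentricity",
    "radiality",
    "neighborhood_connectivity",
    "topological_coefficient",
)


def _topological_coefficient(g: nx.Graph, n: str) -> float:
    neigh = set(g.neighbors(n))
    if len(neigh) < 2:
        return 0.0
    shared: dict[str, int] = {}
    for v in neigh:
        for w in g.neighbors(v):
            if w != n:
                shared[w] = shared.get(w, 0) + 1
    if not shared:
        return 0.0
    total = sum(cnt + (1 if m in neigh else 0) for m, cnt in shared.items())
    return total / (len(shared) * len(neigh))


def extended_topology(g: nx.Graph) -> pd.DataFrame:
    """The eight NetworkAnalyzer-style topology parameters for every node."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute topology of an empty graph")
    bet = betweenness(g)
    rows: dict[str, dict[str, float]] = {
        n: {"degree": float(g.degree(n)), "betweenness": bet[n]} for n in g.nodes
    }
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        n_sub = sub.number_of_nodes()
        if n_sub == 1:
            (lone,) = nodes
            rows[lone].update(
                closeness=0.0, avg_shortest_path=0.0, eccentricity=0.0, radiality=0.0
            )
            continue
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        ecc = {v: max(d.values()) for v, d in sp.items()}
        diam = max(ecc.values())
        for v in nodes:
            aspl = sum(sp[v].values()) / (n_sub - 1)
            rows[v].update(
                closeness=1.0 / aspl,
                avg_shortest_path=aspl,
                eccentricity=float(ecc[v]),
                radiality=(diam + 1.0 - aspl) / diam if diam > 0 else 0.0,
            )
    nbr_conn = nx.average_neighbor_degree(g)
    for v in g.nodes:
        rows[v]["neighborhood_connectivity"] = float(nbr_conn.get(v, 0.0))
        rows[v]["topological_coefficient"] = _topological_coefficient(g, v)
    df = pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows), list(NI_PARAMETERS)]
    df.index.name = "node"
    return df


# ---------------------------------------------------------------------------
# I/O and exports


def read_edges(path: Path | str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["component_id"], df["target_id"]))


def write_edges(edges: Iterable[tuple[str, str]], path: Path | str) -> None:
    pd.DataFrame(edges, columns=["component_id", "target_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_topology(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t")


def read_topology(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node")


def write_partition(partition: TargetPartition, path: Path | str) -> None:
    rows = [("common", t) for t in sorted(partition.common)]
    rows += [("unique_a", t) for t in sorted(partition.unique_a)]
    rows += [("unique_b", t) for t in sorted(partition.unique_b)]
    pd.DataFrame(rows, columns=["class", "target_id"]).to_csv(path, sep="\t", index=False)


def export_graphml(g: nx.Graph, path: Path | str) -> None:
    nx.write_graphml(g, path)


def export_sif(g: nx.Graph, path: Path | str) -> None:
    """Simple-interaction-format export for Cytoscape (``comp targets tgt``)."""
    with open(path, "w") as fh:
        for c in sorted(component_nodes(g)):
            for t in sorted(g.neighbors(c)):
                fh.write(f"{c}\ttargets\t{t}\n")
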