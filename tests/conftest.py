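"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
betweenness is recomputed by exhaustive BFS path enumeration, hypergeometric
tail probabilities by enumerating all draws, and the synergy score by an
explicit per-target loop.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pandas as pd
import pytest

from synerkit.adme import ComponentRecord, ScreenPolicy, screen_components
from synerkit.ctnet import (
    build_graph,
    extended_topology,
    node_topology,
    partition_targets,
)
from synerkit.dockrank import compute_cdi, compute_tri, hrdr_filter, reduce_best_pose
from synerkit.scd import compute_scd, select_hcgsc
from synerkit.synthdata import StudyConfig, generate_study

N_SWEEP_SEEDS = 20


# ---------------------------------------------------------------------------
# oracles


def brute_betweenness(g) -> dict[str, float]:
    """Betweenness by exhaustive shortest-path enumeration (no networkx
    centrality code), normalised by (n-1)(n-2)/2 per connected component."""

    def neighbors(v):
        return list(g.neighbors(v))

    def components():
        seen = set()
        for v in g.nodes:
            if v in seen:
                continue
            comp, queue = {v}, deque([v])
            while queue:
                u = queue.popleft()
                for w in neighbors(u):
                    if w not in comp:
                        comp.add(w)
                        queue.append(w)
            seen |= comp
            yield comp

    def all_shortest_paths(nodes, s, t):
        # BFS predecessor DAG from s, then recursive path expansion
        dist = {s: 0}
        preds: dict[str, list[str]] = {s: []}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in neighbors(u):
                if w not in nodes:
                    continue
                if w not in dist:
                    dist[w] = dist[u] + 1
                    preds[w] = [u]
                    queue.append(w)
                elif dist[w] == dist[u] + 1:
                    preds[w].append(u)
        if t not in dist:
            return []

        def expand(v):
            if v == s:
                return [[s]]
            return [p + [v] for u in preds[v] for p in expand(u)]

        return expand(t)

    out = {v: 0.0 for v in g.nodes}
    for comp in components():
        n = len(comp)
        if n < 3:
            continue
        for s, t in itertools.combinations(sorted(comp), 2):
            paths = all_shortest_paths(comp, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for v in comp:
                if v in (s, t):
                    continue
                out[v] += sum(1 for p in paths if v in p) / sigma
        norm = (n - 1) * (n - 2) / 2
        for v in comp:
            out[v] /= norm
    return out


def enumerate_hypergeom_tail(universe: int, term: int, query: int, observed: int) -> float:
    """P(overlap >= observed) by enumerating every possible query draw."""
    genes = list(range(universe))
    term_set = set(genes[:term])
    hits = total = 0
    for draw in itertools.combinations(genes, query):
        total += 1
        if len(term_set & set(draw)) >= observed:
            hits += 1
    return hits / total


def scd_term_by_term(records: list[dict], doses: dict[str, float]) -> dict[str, float]:
    """Per-target-loop synergy score: the spreadsheet-style oracle.

    Each record: id, C, Ce, Te, balance, T (list of per-target betweenness).
    """
    ids = [r["id"] for r in records]
    d = np.array([doses[i] for i in ids], dtype=float)
    lo, hi = d.min(), d.max()
    norm_d = np.ones_like(d) if hi == lo else (d - lo) / (hi - lo)
    out = {}
    for k, r in enumerate(records):
        total = 0.0
        for t_j in r["T"]:
            total += r["C"] * ((r["Ce"] / r["Te"] + r["balance"]) * t_j) + norm_d[k]
        out[r["id"]] = total
    return out


def random_bipartite(rng: np.random.Generator, max_nodes: int = 12):
    """A random connected-ish labelled bipartite C-T graph with <= max_nodes."""
    n_comp = int(rng.integers(1, max_nodes // 2 + 1))
    n_targ = int(rng.integers(1, max_nodes - n_comp + 1))
    comps = [
        ComponentRecord(id=f"C{i}", herb="A" if rng.random() < 0.5 else "B")
        for i in range(n_comp)
    ]
    edges = []
    for c in comps:
        k = int(rng.integers(1, n_targ + 1))
        for t in rng.choice(n_targ, size=k, replace=False):
            edges.append((c.id, f"T{t}"))
    return build_graph(edges, comps)


# ---------------------------------------------------------------------------
# pipeline-in-memory helper (no file I/O) used by the Monte-Carlo checks


def analyze_study(study) -> dict:
    """Screen -> network -> SCD/HCGSC -> docking -> TRI, all in memory."""
    result = screen_components(study.components, ScreenPolicy())
    active = set(result.passed)
    comps = [c for c in study.components if c.id in active]
    edges = [(c, t) for c, t in study.edges if c in active]
    graph = build_graph(edges, comps)
    topology = node_topology(graph)
    partition = partition_targets(graph)
    scd_table = compute_scd(topology, study.doses)
    hcgsc = select_hcgsc(scd_table, 0.95)

    out = {
        "graph": graph,
        "partition": partition,
        "scd": scd_table,
        "hcgsc": hcgsc,
        "planted": set(study.planted_core),
        "tri": None,
    }
    dock = study.docking[study.docking["component_id"].isin(hcgsc)]
    if len(dock):
        best = reduce_best_pose(dock)
        hrdr, _ = hrdr_filter(best)
        sub = set(hcgsc) | {t for c, t in edges if c in hcgsc}
        ext = extended_topology(graph.subgraph(sub & set(graph.nodes)))
        cdi, _ = compute_cdi(hrdr, ext)
        out["tri"] = compute_tri(cdi, scd_table)
    return out


@pytest.fixture(scope="session")
def seed_sweep():
    """Default-config studies analysed across 20 seeds (shared, expensive)."""
    results = []
    for seed in range(N_SWEEP_SEEDS):
        study = generate_study(StudyConfig(seed=seed))
        res = analyze_study(study)
        res["study"] = study
        results.append(res)
    return results


@pytest.fixture
def toy_components():
    return [
        ComponentRecord(id="KA1", herb="A", name="alpha"),
        ComponentRecord(id="KA2", herb="A", name="beta"),
        ComponentRecord(id="KB1", herb="B", name="gamma"),
    ]


def make_component(cid: str, herb: str = "A", **kw) -> ComponentRecord:
    kw.setdefault("caco2", 1.0)
    kw.setdefault("dl", 0.5)
    return ComponentRecord(id=cid, herb=herb, **kw)
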