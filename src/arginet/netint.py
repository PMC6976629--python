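"""Multi-omics network integration.

Hit sets from the transcriptomic and proteomic stages are mapped onto a
weighted protein-interaction network and connected by a prize-collecting
Steiner tree (PCST) heuristic: node prizes reward including hits, edge
costs (1 - interaction weight) penalize long or weak connections. The
overlap between two resulting trees is assessed against a null of
randomly grown connected subgraphs of matched size.

Two hit-set constructions mirror the study design: the recArg1 effect
set (union of significantly changed genes and proteins under arginase
treatment) and the arginine-dependent RANKL set (exclusive disjunction:
changed with arginine present but not under arginine starvation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InvalidBetaError,
    InvalidPermutationsError,
    InvalidSizeError,
    MissingContrastError,
)
from .proteome import ProteinTestResult
from .rnaseq import DEResult
from .seeding import substream

EDGE_COST_EPS = 1e-6


def load_network(graph: nx.Graph) -> nx.Graph:
    """Normalize an interaction network: drop self-loops, keep the
    largest connected component (count of dropped nodes recorded in
    ``graph.graph["n_dropped"]``), require weights in (0, 1]."""
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if not 0.0 < w <= 1.0:
            raise InvalidSizeError(f"edge ({u},{v}) weight {w} outside (0,1]")
        data["weight"] = w
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if not components:
        raise EmptyInputError("network has no nodes")
    giant = g.subgraph(components[0]).copy()
    giant.graph["n_dropped"] = graph.number_of_nodes() - giant.number_of_nodes()
    return giant


def recarg1_effect_set(
    de_genes: DEResult, da_proteins: ProteinTestResult
) -> pd.DataFrame:
    """Hits describing the recArg1 (arginase) effect: union of called DE
    genes and significant DA proteins, scored by |log2fc| and |d|
    respectively, tagged by omics layer ("rna", "protein" or "both";
    score conflicts for shared ids resolve to the maximum)."""
    gene_scores = de_genes.table.loc[de_genes.table["called"], "log2fc"].abs()
    prot_scores = da_proteins.table.loc[
        da_proteins.table["significant"], "d_stat"
    ].abs()
    rows: dict[str, dict] = {}
    for gid, score in gene_scores.items():
        rows[gid] = {"hit": gid, "score": float(score), "layer": "rna"}
    for pid, score in prot_scores.items():
        if pid in rows:
            rows[pid]["score"] = max(rows[pid]["score"], float(score))
            rows[pid]["layer"] = "both"
        else:
            rows[pid] = {"hit": pid, "score": float(score), "layer": "protein"}
    out = pd.DataFrame(list(rows.values()), columns=["hit", "score", "layer"])
    return out.set_index("hit").sort_index()


def arg_dependent_set(
    de_plus_arg: DEResult,
    de_rescue: DEResult,
    de_starvation: DEResult,
    prot_rescue: ProteinTestResult,
    prot_starvation: ProteinTestResult,
) -> pd.DataFrame:
    """Arginine-dependent RANKL hits: exclusive disjunction of calls
    with and without arginine.

    Genes: called in the M-CSF vs RANKL contrast or the Arg-Rescue
    contrast, but not in the Arg-Starvation contrast. Proteins:
    significant in the Arg-Rescue contrast but not the Arg-Starvation
    contrast. Scores are |log2fc| / |d| from the arginine-present
    contrasts.
    """
    for name, res in [("de_plus_arg", de_plus_arg), ("de_rescue", de_rescue),
                      ("de_starvation", de_starvation)]:
        if res is None:
            raise MissingContrastError(f"missing gene contrast {name}")
    if prot_rescue is None or prot_starvation is None:
        raise MissingContrastError("missing protein contrast")

    genes_present = de_plus_arg.called_genes | de_rescue.called_genes
    genes = genes_present - de_starvation.called_genes
    prots = (
        prot_rescue.significant_proteins - prot_starvation.significant_proteins
    )
    rows: dict[str, dict] = {}
    for gid in genes:
        score = 0.0
        for res in (de_plus_arg, de_rescue):
            if gid in res.called_genes:
                score = max(score, abs(float(res.table.loc[gid, "log2fc"])))
        rows[gid] = {"hit": gid, "score": score, "layer": "rna"}
    for pid in prots:
        score = abs(float(prot_rescue.table.loc[pid, "d_stat"]))
        if pid in rows:
            rows[pid]["score"] = max(rows[pid]["score"], score)
            rows[pid]["layer"] = "both"
        else:
            rows[pid] = {"hit": pid, "score": score, "layer": "protein"}
    out = pd.DataFrame(list(rows.values()), columns=["hit", "score", "layer"])
    return out.set_index("hit").sort_index()


def build_prizes_costs(
    network: nx.Graph, hits: pd.DataFrame, beta: float = 1.0
) -> tuple[dict, dict]:
    """Prize map and edge costs for the PCST step.

    prize(v) = beta * score(v) for mapped hits, 0 otherwise; cost(e) =
    1 - weight(e), clamped to [1e-6, 1] so even perfect-confidence edges
    carry a strictly positive cost. Hits absent from the network are
    dropped; callers can recover them by diffing the hit index against
    the network's node set."""
    if beta <= 0:
        raise InvalidBetaError("beta must be positive")
    prizes = {v: 0.0 for v in network.nodes}
    for hit, row in hits.iterrows():
        if hit in prizes:
            prizes[hit] = beta * float(row["score"])
    costs = {}
    for u, v, data in network.edges(data=True):
        w = float(data.get("weight", 1.0))
        costs[(u, v)] = float(np.clip(1.0 - w, EDGE_COST_EPS, 1.0))
        costs[(v, u)] = costs[(u, v)]
    return prizes, costs


@dataclass
class SteinerSolution:
    """A tree (or singleton) subnetwork with its PCST objective."""

    nodes: set = field(default_factory=set)
    edges: list = field(default_factory=list)
    objective: float = 0.0
    trace: list = field(default_factory=list)  # objective after each attachment

    @property
    def size(self) -> int:
        return len(self.nodes)


def _objective(nodes, edges, prizes, costs, lam: float) -> float:
    return sum(prizes.get(v, 0.0) for v in nodes) - lam * sum(
        costs[(u, v)] for u, v in edges
    )


def pcst_heuristic(
    network: nx.Graph,
    prizes: dict,
    costs: dict | None = None,
    lam: float = 1.0,
    n_starts: int = 8,
) -> SteinerSolution:
    """Greedy prize-collecting Steiner tree.

    From a prized root, repeatedly attaches the prized node whose
    shortest cost-path to the current tree yields the largest positive
    objective gain (path prizes collected minus lambda times path cost);
    stops when no attachment improves, then prunes leaves whose prize
    does not pay for their edge (zero-prize Steiner leaves always go).
    The greedy growth is restarted from each of the ``n_starts``
    highest-prize nodes (always including the maximum-prize node) and
    the best tree kept. If all prizes are zero, returns an empty
    solution with objective 0.
    """
    if costs is None:
        costs = {}
        for u, v, data in network.edges(data=True):
            c = float(np.clip(1.0 - float(data.get("weight", 1.0)),
                              EDGE_COST_EPS, 1.0))
            costs[(u, v)] = c
            costs[(v, u)] = c
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for u, v in network.edges:
        g.add_edge(u, v, cost=costs[(u, v)])

    prized = [v for v in network.nodes if prizes.get(v, 0.0) > 0]
    if not prized:
        return SteinerSolution(nodes=set(), edges=[], objective=0.0, trace=[])
    roots = sorted(prized, key=lambda v: (-prizes[v], str(v)))[:max(1, n_starts)]
    best: SteinerSolution | None = None
    for root in roots:
        sol = _grow_from(g, root, prized, prizes, costs, lam)
        if best is None or sol.objective > best.objective + 1e-12:
            best = sol
    return best


def _grow_from(
    g: nx.Graph, root, prized: list, prizes: dict, costs: dict, lam: float
) -> SteinerSolution:
    tree_nodes = {root}
    tree_edges: list[tuple] = []
    objective = prizes[root]
    trace = [objective]

    remaining = set(prized) - tree_nodes
    while remaining:
        dist, paths = nx.multi_source_dijkstra(g, tree_nodes, weight="cost")
        best_gain, best_target = 0.0, None
        for u in sorted(remaining, key=str):
            if u not in dist:
                continue
            new_nodes = [w for w in paths[u] if w not in tree_nodes]
            gain = sum(prizes.get(w, 0.0) for w in new_nodes) - lam * dist[u]
            if gain > best_gain + 1e-12:
                best_gain, best_target = gain, u
        if best_target is None:
            break
        path = paths[best_target]
        for a, b in zip(path, path[1:]):
            if b not in tree_nodes:
                tree_edges.append((a, b))
                tree_nodes.add(b)
        objective += best_gain
        trace.append(objective)
        remaining -= tree_nodes

    # prune unprofitable leaves (covers zero-prize Steiner leaves too)
    changed = True
    while changed and tree_edges:
        changed = False
        degree: dict = {}
        for a, b in tree_edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        for a, b in list(tree_edges):
            for leaf, other in ((a, b), (b, a)):
                if degree.get(leaf, 0) == 1 and leaf != root:
                    if lam * costs[(leaf, other)] - prizes.get(leaf, 0.0) > 1e-12:
                        tree_edges.remove((a, b))
                        tree_nodes.discard(leaf)
                        changed = True
                        break
            if changed:
                break

    objective = _objective(tree_nodes, tree_edges, prizes, costs, lam)
    return SteinerSolution(nodes=tree_nodes, edges=tree_edges,
                           objective=objective, trace=trace)


def pcst_bruteforce(
    network: nx.Graph,
    prizes: dict,
    costs: dict | None = None,
    lam: float = 1.0,
    max_nodes: int = 12,
) -> SteinerSolution:
    """Exact PCST by exhaustive enumeration (small instances only).

    Enumerates every connected vertex subset; the best tree on a subset
    is the minimum spanning tree of its induced subgraph under the edge
    costs. Intended as an oracle for validating the heuristic.
    """
    if network.number_of_nodes() > max_nodes:
        raise InvalidSizeError(
            f"brute force limited to {max_nodes} nodes, got "
            f"{network.number_of_nodes()}"
        )
    if costs is None:
        costs = {}
        for u, v, data in network.edges(data=True):
            c = float(np.clip(1.0 - float(data.get("weight", 1.0)),
                              EDGE_COST_EPS, 1.0))
            costs[(u, v)] = c
            costs[(v, u)] = c
    nodes = sorted(network.nodes, key=str)
    best = SteinerSolution(nodes=set(), edges=[], objective=0.0)
    for size in range(1, len(nodes) + 1):
        for subset in combinations(nodes, size):
            sub = network.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            t = nx.Graph()
            t.add_nodes_from(subset)
            for u, v in sub.edges:
                t.add_edge(u, v, cost=costs[(u, v)])
            mst = list(nx.minimum_spanning_edges(t, weight="cost", data=False))
            obj = _objective(set(subset), mst, prizes, costs, lam)
            if obj > best.objective + 1e-12:
                best = SteinerSolution(nodes=set(subset), edges=mst, objective=obj)
    return best


def tree_overlap(sol_a: SteinerSolution, sol_b: SteinerSolution) -> set:
    """Shared nodes of two Steiner solutions."""
    return set(sol_a.nodes) & set(sol_b.nodes)


def sample_connected_subgraph(
    network: nx.Graph, size: int, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> set:
    """Random connected node set of exactly ``size`` nodes, grown by
    seeded random neighbor expansion from a uniformly chosen start.

    The induced subgraph is connected by construction. The distribution
    over connected subgraphs is NOT uniform (uniform sampling is
    computationally hard); on a complete graph it reduces to uniform
    node subsets.
    """
    n = network.number_of_nodes()
    if size < 1 or size > n:
        raise InvalidSizeError(f"size {size} outside [1, {n}]")
    if rng is None:
        rng = substream(seed, "subgraph")
    nodes = sorted(network.nodes, key=str)
    start = nodes[int(rng.integers(n))]
    chosen = {start}
    frontier = set(network[start]) - chosen
    while len(chosen) < size:
        assert frontier, "connected network exhausted before reaching size"
        candidates = sorted(frontier, key=str)
        pick = candidates[int(rng.integers(len(candidates)))]
        chosen.add(pick)
        frontier |= set(network[pick])
        frontier -= chosen
    return chosen


@dataclass
class OverlapNull:
    """Null distribution of shared nodes between random connected
    subgraphs of matched sizes."""

    observed_overlap: int
    null_overlaps: np.ndarray = field(repr=False)
    p_empirical: float = 1.0
    n_draws: int = 0


def overlap_null(
    network: nx.Graph,
    size_a: int,
    size_b: int,
    observed_overlap: int,
    n_draws: int = 2000,
    seed: int = 0,
) -> OverlapNull:
    """Connected-subgraph randomization null for tree overlap.

    Draws ``n_draws`` independent pairs of connected subgraphs of the
    two matched sizes, counts shared nodes per pair, and reports the
    add-one empirical p-value P(null >= observed).
    """
    if n_draws < 1:
        raise InvalidPermutationsError("n_draws must be >= 1")
    n = network.number_of_nodes()
    if size_a > n or size_b > n:
        raise InvalidSizeError("subgraph size exceeds network size")
    if observed_overlap > min(size_a, size_b):
        raise InvalidSizeError("observed overlap exceeds the smaller tree")
    rng = substream(seed, "subgraph")
    overlaps = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        sa = sample_connected_subgraph(network, size_a, rng=rng)
        sb = sample_connected_subgraph(network, size_b, rng=rng)
        overlaps[i] = len(sa & sb)
    p = (1.0 + float((overlaps >= observed_overlap).sum())) / (1.0 + n_draws)
    return OverlapNull(observed_overlap=observed_overlap, null_overlaps=overlaps,
                       p_empirical=p, n_draws=n_draws)
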