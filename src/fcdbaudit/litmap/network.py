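"""Corpus-to-communities pipeline over an undirected citation graph.

Documents are nodes; an edge joins two documents of the filtered corpus when
either one's reference list contains the other. Papers of one subfield cite
each other far more than chance, so modularity-based community detection
groups the corpus into topical clusters. Communities are then labeled
A, B, C, ... in decreasing size order.

The community detector is a greedy modularity maximizer of the Louvain
family (local moving + graph aggregation), written here so its tie-breaking
and seeding are fully deterministic and inspectable. It is a heuristic: it
guarantees a local optimum of modularity, not the global one, and the
resolution parameter trades many small communities (large values) against
few large ones.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from ..model import Document
from .text import tokenize

__all__ = [
    "filter_corpus",
    "build_citation_graph",
    "remove_isolated",
    "modularity",
    "Partition",
    "detect_communities",
    "order_communities",
    "write_partition",
    "read_partition",
]

Node = Hashable


def filter_corpus(
    corpus: Sequence[Document],
    any_of: Iterable[str],
    all_of: Iterable[str] = (),
) -> list[Document]:
    """Keep documents matching (>= 1 of ``any_of``) AND (every ``all_of``).

    Matching is token-exact on the lower-cased, punctuation-stripped tokens
    of title + abstract, so "palm" does not match inside "palmitic".
    Filtering is monotone and idempotent.
    """
    any_terms = {t.lower() for t in any_of}
    all_terms = {t.lower() for t in all_of}
    if not any_terms and not all_terms:
        raise ValueError("at least one filter term is required")
    kept = []
    for doc in corpus:
        tokens = set(tokenize(doc.text))
        if any_terms and not (tokens & any_terms):
            continue
        if not all_terms <= tokens:
            continue
        kept.append(doc)
    return kept


def build_citation_graph(corpus: Sequence[Document]) -> nx.Graph:
    """Undirected citation graph over a (sub-)corpus.

    Edge {A, B} iff both are in the corpus and at least one cites the other;
    references to documents outside the corpus are ignored. No self-loops,
    no parallel edges.
    """
    g = nx.Graph()
    ids = {d.doc_id for d in corpus}
    g.add_nodes_from(d.doc_id for d in corpus)
    for doc in corpus:
        for ref in doc.references:
            if ref in ids and ref != doc.doc_id:
                g.add_edge(doc.doc_id, ref)
    return g


def remove_isolated(g: nx.Graph) -> nx.Graph:
    """Subgraph induced by nodes of degree >= 1 (idempotent; edges unchanged)."""
    keep = [n for n, d in g.degree() if d > 0]
    return g.subgraph(keep).copy()


def modularity(
    g: nx.Graph, assignment: Mapping[Node, int], resolution: float = 1.0
) -> float:
    """Newman modularity of a node->community assignment.

    ``Q = sum_c [ L_c / m  -  gamma * (D_c / 2m)^2 ]`` where ``L_c`` is the
    intra-community edge weight, ``D_c`` the community degree sum and ``m``
    the total edge weight. Returns 0 for a graph without edges.
    """
    m = g.size(weight="weight")
    if m == 0:
        return 0.0
    deg = dict(g.degree(weight="weight"))
    d_sum: Counter = Counter()
    for node, c in assignment.items():
        d_sum[c] += deg[node]
    l_sum: Counter = Counter()
    for u, v, w in g.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            l_sum[assignment[u]] += w
    return sum(
        l_sum[c] / m - resolution * (d_sum[c] / (2.0 * m)) ** 2 for c in d_sum
    )


@dataclass
class Partition:
    """A community assignment with its modularity and size-rank labels.

    ``labels`` (community index -> letter, A = largest) is populated by
    :func:`order_communities`; until then it is ``None``.
    """

    assignment: dict[Node, int]
    modularity: float
    resolution: float = 1.0
    labels: Optional[dict[int, str]] = None

    @property
    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.assignment.values()))

    @property
    def communities(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return out

    def label_of(self, node: Node) -> str:
        if self.labels is None:
            raise ValueError("partition has no size-rank labels; call order_communities")
        return self.labels[self.assignment[node]]

    def members(self, label: str) -> list[Node]:
        if self.labels is None:
            raise ValueError("partition has no size-rank labels; call order_communities")
        inv = {v: k for k, v in self.labels.items()}
        if label not in inv:
            raise KeyError(f"no community labeled {label!r}")
        return sorted(self.communities[inv[label]], key=str)


# ---------------------------------------------------------------------------
# Greedy modularity maximization (Louvain-family), implemented in-repo.
# ---------------------------------------------------------------------------


def _adjacency(g: nx.Graph) -> tuple[dict, dict]:
    """Split a graph into a loop-free neighbor map and a self-loop weight map."""
    neighbors: dict[Node, dict[Node, float]] = {n: {} for n in g.nodes()}
    loops: dict[Node, float] = {n: 0.0 for n in g.nodes()}
    for u, v, w in g.edges(data="weight", default=1.0):
        if u == v:
            loops[u] += w
        else:
            neighbors[u][v] = neighbors[u].get(v, 0.0) + w
            neighbors[v][u] = neighbors[v].get(u, 0.0) + w
    return neighbors, loops


def _local_moving(
    nodes: list,
    neighbors: dict,
    loops: dict,
    resolution: float,
    rng: random.Random,
) -> dict:
    """One level of greedy local moving; returns node -> community."""
    k = {u: sum(neighbors[u].values()) + 2.0 * loops[u] for u in nodes}
    m2 = sum(k.values())
    comm = {u: i for i, u in enumerate(nodes)}
    tot = {comm[u]: k[u] for u in nodes}
    if m2 == 0:
        return comm
    order = list(nodes)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for u in order:
            c_old = comm[u]
            w_to: dict[int, float] = {}
            for v, w in neighbors[u].items():
                w_to[comm[v]] = w_to.get(comm[v], 0.0) + w
            tot[c_old] -= k[u]
            # gain (x m) of placing u in community c
            def gain(c: int) -> float:
                return w_to.get(c, 0.0) - resolution * k[u] * tot.get(c, 0.0) / m2
            best_c, best_gain = c_old, gain(c_old)
            for c in sorted(w_to):
                gc = gain(c)
                if gc > best_gain + 1e-12:
                    best_c, best_gain = c, gc
            tot[best_c] = tot.get(best_c, 0.0) + k[u]
            if best_c != c_old:
                comm[u] = best_c
                improved = True
    return comm


def _aggregate(
    nodes: list, neighbors: dict, loops: dict, comm: dict
) -> tuple[list, dict, dict, dict]:
    """Collapse communities into super-nodes; returns the new graph + relabel map."""
    reps = sorted(set(comm.values()))
    relabel = {c: i for i, c in enumerate(reps)}
    new_nodes = list(range(len(reps)))
    new_neighbors: dict[int, dict[int, float]] = {i: {} for i in new_nodes}
    new_loops: dict[int, float] = {i: 0.0 for i in new_nodes}
    for u in nodes:
        cu = relabel[comm[u]]
        new_loops[cu] += loops[u]
        for v, w in neighbors[u].items():
            cv = relabel[comm[v]]
            if cu == cv:
                if str(u) < str(v) or u == v:
                    new_loops[cu] += w
            else:
                new_neighbors[cu][cv] = new_neighbors[cu].get(cv, 0.0) + w
    return new_nodes, new_neighbors, new_loops, relabel


def _louvain(g: nx.Graph, resolution: float, rng: random.Random) -> dict[Node, int]:
    """Full Louvain pass: local moving + aggregation until no improvement."""
    base_nodes = sorted(g.nodes(), key=str)
    neighbors, loops = _adjacency(g)
    nodes: list = list(base_nodes)
    # assignment of original nodes through all levels
    node_to_super: dict[Node, Node] = {n: n for n in base_nodes}
    while True:
        comm = _local_moving(nodes, neighbors, loops, resolution, rng)
        n_comms = len(set(comm.values()))
        if n_comms == len(nodes):
            break
        new_nodes, new_neighbors, new_loops, relabel = _aggregate(
            nodes, neighbors, loops, comm
        )
        node_to_super = {
            n: relabel[comm[node_to_super[n]]] for n in base_nodes
        }
        nodes, neighbors, loops = new_nodes, new_neighbors, new_loops
        if len(nodes) == 1:
            break
    final = {n: node_to_super[n] for n in base_nodes}
    # normalize community ids to 0..k-1 ordered by smallest member id
    groups: dict = {}
    for n, c in final.items():
        groups.setdefault(c, []).append(n)
    order = sorted(groups, key=lambda c: str(min(groups[c], key=str)))
    renum = {c: i for i, c in enumerate(order)}
    return {n: renum[c] for n, c in final.items()}


def _refine_moves(
    g: nx.Graph, assignment: dict[Node, int], resolution: float
) -> dict[Node, int]:
    """Greedy best single-node moves to *any* community (or a new singleton).

    Unlike the local-moving phase, candidate communities are not restricted
    to a node's neighbors, so a node stuck in a disconnected or suboptimal
    community can escape. Runs to convergence; strictly non-decreasing in
    modularity.
    """
    m = g.size(weight="weight")
    if m == 0:
        return assignment
    assignment = dict(assignment)
    deg = dict(g.degree(weight="weight"))
    tot: dict[int, float] = {}
    for n, c in assignment.items():
        tot[c] = tot.get(c, 0.0) + deg[n]
    nodes = sorted(g.nodes(), key=str)
    fresh = max(tot) + 1
    improved = True
    while improved:
        improved = False
        for u in nodes:
            c_old = assignment[u]
            w_to: dict[int, float] = {}
            for v, data in g[u].items():
                if v != u:
                    w_to[assignment[v]] = w_to.get(assignment[v], 0.0) + data.get("weight", 1.0)
            tot[c_old] = tot.get(c_old, 0.0) - deg[u]
            candidates = set(tot) | {fresh}
            def gain(c: int) -> float:
                return w_to.get(c, 0.0) - resolution * deg[u] * tot.get(c, 0.0) / (2.0 * m)
            best_c, best_gain = c_old, gain(c_old)
            for c in sorted(candidates):
                gc = gain(c)
                if gc > best_gain + 1e-12:
                    best_c, best_gain = c, gc
            tot[best_c] = tot.get(best_c, 0.0) + deg[u]
            if best_c != c_old:
                assignment[u] = best_c
                improved = True
                if best_c == fresh:
                    fresh += 1
    return assignment


def _merge_communities(
    g: nx.Graph, assignment: dict[Node, int], resolution: float
) -> dict[Node, int]:
    """Greedily merge community pairs while any merge increases modularity."""
    m = g.size(weight="weight")
    if m == 0:
        return assignment
    assignment = dict(assignment)
    deg = dict(g.degree(weight="weight"))
    while True:
        comms = sorted(set(assignment.values()))
        tot = {c: 0.0 for c in comms}
        for n, c in assignment.items():
            tot[c] += deg[n]
        between: dict[tuple[int, int], float] = {}
        for u, v, w in g.edges(data="weight", default=1.0):
            cu, cv = assignment[u], assignment[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                between[key] = between.get(key, 0.0) + w
        best_pair, best_gain = None, 1e-12
        for (ca, cb) in sorted(between):
            gain = between[(ca, cb)] / m - resolution * tot[ca] * tot[cb] / (2.0 * m**2)
            if gain > best_gain:
                best_pair, best_gain = (ca, cb), gain
        if best_pair is None:
            return assignment
        ca, cb = best_pair
        for n, c in assignment.items():
            if c == cb:
                assignment[n] = ca


def _kl_refine(
    g: nx.Graph, assignment: dict[Node, int], resolution: float
) -> dict[Node, int]:
    """Kernighan–Lin style refinement over single-node moves.

    Repeatedly builds a sequence of globally best moves in which every node
    moves at most once — accepting temporarily *negative* gains — then keeps
    the prefix with the highest cumulative modularity gain. This escapes
    plateaus and coordinated-rearrangement traps that pure greedy moving
    cannot (e.g. two nodes that must swap communities together).
    """
    m = g.size(weight="weight")
    if m == 0:
        return assignment
    assignment = dict(assignment)
    deg = dict(g.degree(weight="weight"))
    nodes = sorted(g.nodes(), key=str)

    while True:
        work = dict(assignment)
        tot: dict[int, float] = {}
        for n, c in work.items():
            tot[c] = tot.get(c, 0.0) + deg[n]
        fresh = max(tot) + 1
        moved: set = set()
        history: list[tuple[Node, int, int]] = []
        cum = best_cum = 0.0
        best_len = 0
        for _ in range(len(nodes)):
            best_move = None  # (gain, node, target)
            for u in nodes:
                if u in moved:
                    continue
                c_old = work[u]
                w_to: dict[int, float] = {}
                for v, data in g[u].items():
                    if v != u:
                        w_to[work[v]] = w_to.get(work[v], 0.0) + data.get("weight", 1.0)
                base = w_to.get(c_old, 0.0) - resolution * deg[u] * (
                    tot[c_old] - deg[u]
                ) / (2.0 * m)
                for c in sorted(set(w_to) | {fresh}):
                    if c == c_old:
                        continue
                    gain = (
                        w_to.get(c, 0.0)
                        - resolution * deg[u] * tot.get(c, 0.0) / (2.0 * m)
                        - base
                    ) / m
                    if best_move is None or gain > best_move[0] + 1e-15:
                        best_move = (gain, u, c)
            if best_move is None:
                break
            gain, u, c_new = best_move
            c_old = work[u]
            work[u] = c_new
            tot[c_old] -= deg[u]
            tot[c_new] = tot.get(c_new, 0.0) + deg[u]
            if c_new == fresh:
                fresh += 1
            moved.add(u)
            history.append((u, c_old, c_new))
            cum += gain
            if cum > best_cum + 1e-12:
                best_cum, best_len = cum, len(history)
        if best_cum <= 1e-12:
            return assignment
        # accept the winning prefix of moves, discard the rest
        for u, _, c_new in history[:best_len]:
            assignment[u] = c_new


def detect_communities(
    g: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 4,
) -> Partition:
    """Greedy modularity maximization, deterministic for a fixed seed.

    Each restart runs a seeded Louvain pass (local moving + aggregation)
    followed by two refinements: unrestricted single-node moves and greedy
    community merges. The best-modularity partition over the restarts is
    returned; restarts and refinement guard against the poor local optima a
    single greedy pass can hit. An empty graph yields an empty partition.
    """
    if g.number_of_nodes() == 0:
        return Partition(assignment={}, modularity=0.0, resolution=resolution)
    best: Optional[dict[Node, int]] = None
    best_q = float("-inf")
    for r in range(max(1, n_restarts)):
        rng = random.Random((seed * 1_000_003 + r) % (2**31))
        assignment = _louvain(g, resolution, rng)
        assignment = _refine_moves(g, assignment, resolution)
        assignment = _merge_communities(g, assignment, resolution)
        if g.number_of_nodes() <= 2000:
            assignment = _kl_refine(g, assignment, resolution)
            assignment = _merge_communities(g, assignment, resolution)
        q = modularity(g, assignment, resolution)
        if q > best_q + 1e-15:
            best, best_q = assignment, q
    assert best is not None
    # normalize community ids to 0..k-1 by smallest member id
    groups: dict[int, list[Node]] = {}
    for n, c in best.items():
        groups.setdefault(c, []).append(n)
    order = sorted(groups, key=lambda c: str(min(groups[c], key=str)))
    renum = {c: i for i, c in enumerate(order)}
    return Partition(
        assignment={n: renum[c] for n, c in best.items()},
        modularity=best_q,
        resolution=resolution,
    )


def _size_rank_letters(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style)."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def order_communities(p: Partition) -> Partition:
    """Relabel communities A, B, C, ... by decreasing size.

    Ties break on the smallest member id (lexicographic). The grouping of
    nodes is unchanged; only community indices and labels move. Idempotent.
    """
    groups = p.communities
    order = sorted(
        groups, key=lambda c: (-len(groups[c]), str(min(groups[c], key=str)))
    )
    renum = {c: i for i, c in enumerate(order)}
    return Partition(
        assignment={n: renum[c] for n, c in p.assignment.items()},
        modularity=p.modularity,
        resolution=p.resolution,
        labels={i: _size_rank_letters(i) for i in range(len(order))},
    )


def write_partition(p: Partition, path: Union[str, Path]) -> None:
    """TSV (doc_id, community_label); requires an ordered partition."""
    if p.labels is None:
        p = order_communities(p)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tcommunity_label\n")
        for node in sorted(p.assignment, key=str):
            fh.write(f"{node}\t{p.labels[p.assignment[node]]}\n")


def read_partition(path: Union[str, Path]) -> dict[str, str]:
    """Read a partition TSV back as doc_id -> community label."""
    out: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if line.strip():
            doc_id, label = line.split("\t")
            out[doc_id] = label
    return out
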