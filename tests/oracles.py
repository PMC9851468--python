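"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and double
loops — and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools
from collections import Counter


def set_partitions(items: list):
    """Enumerate all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_naive(edges: list[tuple], nodes: list, blocks: list[list], gamma: float = 1.0) -> float:
    """Textbook modularity from the edge list, no shared code with the package."""
    m = len(edges)
    if m == 0:
        return 0.0
    comm = {n: i for i, block in enumerate(blocks) for n in block}
    deg = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    q = 0.0
    for i, block in enumerate(blocks):
        l_c = sum(1 for u, v in edges if comm[u] == i and comm[v] == i)
        d_c = sum(deg[n] for n in block)
        q += l_c / m - gamma * (d_c / (2.0 * m)) ** 2
    return q


def exhaustive_best_modularity(edges: list[tuple], nodes: list) -> float:
    """Global modularity optimum by enumerating every partition."""
    return max(
        modularity_naive(edges, nodes, blocks) for blocks in set_partitions(list(nodes))
    )


def max_pairwise_reldiff_naive(values: dict[str, float]) -> float:
    """Brute-force |a-b|/min(a,b) over all unordered pairs."""
    worst = 0.0
    for a, b in itertools.combinations(values.values(), 2):
        worst = max(worst, abs(a - b) / min(a, b))
    return worst


def citation_edges_naive(docs) -> set[frozenset]:
    """Double loop over ordered document pairs: edge iff either cites the other."""
    ids = {d.doc_id for d in docs}
    by_id = {d.doc_id: d for d in docs}
    edges = set()
    for a in docs:
        for b in docs:
            if a.doc_id == b.doc_id:
                continue
            if b.doc_id in a.references and b.doc_id in ids:
                edges.add(frozenset((a.doc_id, b.doc_id)))
            if a.doc_id in b.references and a.doc_id in ids:
                edges.add(frozenset((a.doc_id, b.doc_id)))
    return edges


def ngram_importance_naive(docs_in, docs_out, n_range=(1, 3), stopwords=frozenset()):
    """Hand-rolled importance table: per-n normalized frequency difference.

    Tokenization duplicated on purpose (lowercase, keep alphanumeric runs).
    Returns {ngram: (freq_in, freq_out)} over the union vocabulary.
    """
    import re

    def toks(text):
        return re.findall(r"[^\W_]+", text.lower())

    def count(docs):
        c: Counter = Counter()
        for d in docs:
            tokens = toks(d.title + " " + d.abstract)
            for n in range(n_range[0], n_range[1] + 1):
                for i in range(len(tokens) - n + 1):
                    gram = tuple(tokens[i : i + n])
                    if not any(t in stopwords for t in gram):
                        c[gram] += 1
        return c

    cin, cout = count(docs_in), count(docs_out)
    tin: Counter = Counter()
    tout: Counter = Counter()
    for g, c in cin.items():
        tin[len(g)] += c
    for g, c in cout.items():
        tout[len(g)] += c
    table = {}
    for g in set(cin) | set(cout):
        fi = cin.get(g, 0) / tin[len(g)] if tin[len(g)] else 0.0
        fo = cout.get(g, 0) / tout[len(g)] if tout[len(g)] else 0.0
        table[g] = (fi, fo)
    return table


def small_graph_suite():
    """Enumerated <= 8-node graphs for the exhaustive-optimum comparison."""
    import networkx as nx

    suite = []
    for n in range(2, 8):
        suite.append((f"complete_{n}", nx.complete_graph(n)))
        suite.append((f"path_{n}", nx.path_graph(n)))
        suite.append((f"cycle_{n}", nx.cycle_graph(n)))
        suite.append((f"star_{n}", nx.star_graph(n - 1)))
    suite.append(("barbell_3_1", nx.barbell_graph(3, 1)))
    for s in range(10):
        suite.append((f"gnp7_{s}", nx.gnp_random_graph(7, 0.4, seed=s)))
    for s in range(10):
        suite.append((f"gnp8_sparse_{s}", nx.gnp_random_graph(8, 0.35, seed=s)))
    for s in range(5):
        suite.append((f"gnp8_dense_{s}", nx.gnp_random_graph(8, 0.6, seed=100 + s)))
    return [(name, g) for name, g in suite if g.number_of_edges() > 0]
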