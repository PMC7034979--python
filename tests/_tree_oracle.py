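"""Independent brute-force oracle for balanced minimum evolution.

Enumerates every unrooted binary topology by recursive edge insertion on
networkx graphs and evaluates Pauplin's balanced length directly from
shortest-path leaf distances — sharing no code with the package's tree
builder.
"""

from functools import lru_cache

import networkx as nx


@lru_cache(maxsize=None)
def all_topologies(n: int) -> tuple:
    g0 = nx.Graph()
    g0.add_edges_from([(0, n), (1, n), (2, n)])
    tops = [g0]
    for x in range(3, n):
        new = []
        for g in tops:
            for (u, v) in list(g.edges()):
                h = g.copy()
                m = n + x - 2
                h.remove_edge(u, v)
                h.add_edges_from([(u, m), (v, m), (m, x)])
                new.append(h)
        tops = new
    return tuple(tops)


def pauplin_length(g: nx.Graph, n: int, d) -> float:
    sp = dict(nx.all_pairs_shortest_path_length(g))
    return sum(
        2.0 ** (1 - sp[i][j]) * d[i, j] for i in range(n) for j in range(i + 1, n)
    )


def exhaustive_minimum(d) -> float:
    n = d.shape[0]
    return min(pauplin_length(g, n, d) for g in all_topologies(n))
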