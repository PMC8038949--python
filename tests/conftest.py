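import numpy as np
import pytest

import nmrbind as nb


@pytest.fixture(scope="session")
def td151_series():
    return nb.td151_like_series(seed=7)


@pytest.fixture(scope="session")
def td151_profile(td151_series):
    return nb.csp_profile(td151_series)


@pytest.fixture
def toy_records():
    return [
        nb.PeakRecord(18, "A", 8.123, 118.45, 1.2e6),
        nb.PeakRecord(19, "K", 7.950, 121.00, 9.5e5),
        nb.PeakRecord(20, "G", 8.310, 109.10, None),
    ]


def random_additive_instance(rng, n_taxa):
    """Random additive metric from a random unrooted binary tree.

    Built by sequential leaf attachment on a plain weighted adjacency dict;
    returns (leaf names, distance matrix, set of canonical non-trivial
    bipartitions).  Independent of the neighbor-joining implementation.
    """
    names = [f"t{i}" for i in range(n_taxa)]
    adj = {names[0]: {}, names[1]: {}}
    _add_edge(adj, names[0], names[1], float(rng.uniform(0.05, 1.0)))
    counter = [0]
    for leaf in names[2:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        s = float(rng.uniform(0.1, 0.9))
        inode = f"i{counter[0]}"
        counter[0] += 1
        del adj[u][v]
        del adj[v][u]
        adj[inode] = {}
        _add_edge(adj, u, inode, w * s)
        _add_edge(adj, inode, v, w * (1 - s))
        _add_edge(adj, inode, leaf, float(rng.uniform(0.05, 1.0)))
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(names):
        dist = _single_source(adj, a)
        for j, b in enumerate(names):
            mat[i, j] = dist[b]
    mat = (mat + mat.T) / 2.0
    parts = set()
    anchor = sorted(names)[0]
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = frozenset(n for n in _component(adj, u, (u, v)) if n.startswith("t"))
                if anchor in side:
                    side = frozenset(names) - side
                if 2 <= len(side) <= n_taxa - 2:
                    parts.add(side)
    return names, mat, parts


def _add_edge(adj, u, v, w):
    adj.setdefault(u, {})[v] = w
    adj.setdefault(v, {})[u] = w


def _single_source(adj, src):
    dist = {src: 0.0}
    stack = [src]
    while stack:
        u = stack.pop()
        for v, w in adj[u].items():
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def _component(adj, start, cut_edge):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if {u, v} == set(cut_edge):
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen
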