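import warnings

import numpy as np
import pytest

from hetscan.jackknife import run_het
from hetscan.matrices import GenotypeMatrix, LocusMatrix, TaxonGrouping
from hetscan.simulate import (
    HYBRID_SCENARIOS,
    make_hybrid_dataset,
    simulate_snp_dataset,
    tropheini_like_model,
)


def grouping_from_suffix(matrix, outgroup="out"):
    return TaxonGrouping(
        {s: s.rsplit("_", 1)[1] for s in matrix.sample_ids},
        outgroup=outgroup,
    )


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree; returns (leaf labels, distance matrix,
    canonical nontrivial splits)."""
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    # start from a star over 3 leaves; attach remaining leaves to random edges
    # represent tree as adjacency with branch lengths
    adj = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.1, 1.0))

    nxt = [0]

    def newnode():
        nxt[0] += 1
        return f"__v{nxt[0]}"

    v = newnode()
    for l in labels[:3]:
        connect(v, l, blen())
    for l in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = newnode()
        del adj[a][b], adj[b][a]
        u = float(rng.uniform(0.2, 0.8))
        connect(a, mid, w * u)
        connect(b, mid, w * (1 - u))
        connect(mid, l, blen())

    # path lengths by BFS from each leaf
    import collections

    D = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            x = dq.popleft()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    dq.append(y)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]

    # splits: remove each internal edge
    from hetscan.nj import canonical_split

    splits = set()
    internal = [(a, b) for a in adj for b in adj[a]
                if a < b and a.startswith("__") and b.startswith("__")]
    for a, b in internal:
        seen = {a}
        dq = collections.deque([a])
        while dq:
            x = dq.popleft()
            for y in adj[x]:
                if y not in seen and not (x == a and y == b):
                    seen.add(y)
                    dq.append(y)
        side = {l for l in labels if l in seen}
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(canonical_split(side, labels))
    return labels, D, splits


@pytest.fixture(scope="session")
def hybrid_run():
    """Planted-hybrid HET run (recent l x s hybrid, theta = 0.0005,
    600 SNP loci, B = 100): the workhorse fixture for support accounting."""
    mod = tropheini_like_model(theta=0.0005)
    mx, truth = make_hybrid_dataset(mod, HYBRID_SCENARIOS["l_x_s"], 600,
                                    seed=101)
    grouping = grouping_from_suffix(mx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_het(mx, grouping, B=100, seed=101)
    return res, truth, grouping, mx


@pytest.fixture(scope="session")
def nohybrid_run():
    """Hybrid-free HET run at low theta (well-resolved tree, 300 SNP loci,
    B = 50): taxa are monophyletic, exercising the SC rule."""
    mod = tropheini_like_model(theta=0.00001)
    mx = simulate_snp_dataset(mod, 300, seed=77)
    grouping = grouping_from_suffix(mx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_het(mx, grouping, B=50, seed=77)
    return res, grouping, mx


@pytest.fixture
def small_binary():
    values = np.array(
        [
            [1, 0, 1, 1, 0, 1],
            [1, 1, 0, 1, 0, 1],
            [0, 1, 1, 0, 1, 0],
            [0, 0, 1, 0, 1, 1],
            [1, 0, 0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return LocusMatrix([f"s{i}_g{i // 2}" for i in range(5)], values)
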