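"""Numba kernels for multispecies-coalescent gene trees and JC mutations.

The species tree is passed as flat arrays (see ``simulate.SpeciesTreeModel``):
``parent`` (index of parent node, -1 for the root), ``tau`` (node divergence
time in expected substitutions/site), ``theta`` (4*Ne*mu of the branch above
the node; for the root, of the ancestral population), ``order`` (node indices
sorted by increasing tau, so children are processed before their parent),
``tip_count`` (sampled haplotypes per node, 0 for internal nodes) and
``tip_offset`` (first gene-tree tip id of each species node).

Within a species branch, k lineages coalesce at total rate k*(k-1)/theta per
unit tau (pairwise rate 2/theta); survivors enter the parent branch at the
parent's tau, and coalescence continues above the root until one lineage
remains. Mutations are dropped on the resulting gene tree as a Poisson
process with rate 1 per unit branch length, each event replacing the state
by one of the three other nucleotides uniformly (Jukes-Cantor).
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _simulate_tree(parent, tau, theta, order, tip_count, tip_offset,
                   n_tips, pool_buf, pool_n, g_parent, g_time):
    """One gene tree; fills g_parent/g_time, returns total branch length."""
    S = parent.shape[0]
    for v in range(S):
        pool_n[v] = 0
    for u in range(2 * n_tips - 1):
        g_parent[u] = -1
        g_time[u] = 0.0
    next_node = n_tips
    for oi in range(S):
        v = order[oi]
        if tip_count[v] > 0:
            base = tip_offset[v]
            for i in range(tip_count[v]):
                pool_buf[v, pool_n[v]] = base + i
                pool_n[v] += 1
        k = pool_n[v]
        t = tau[v]
        p = parent[v]
        is_root = p < 0
        t1 = np.inf if is_root else tau[p]
        th = theta[v]
        while k > 1:
            rate = k * (k - 1) / th
            t += np.random.exponential(1.0 / rate)
            if t > t1:
                break
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
            u = next_node
            next_node += 1
            g_time[u] = t
            g_parent[pool_buf[v, i]] = u
            g_parent[pool_buf[v, j]] = u
            pool_buf[v, i] = u
            pool_buf[v, j] = pool_buf[v, k - 1]
            k -= 1
        if is_root:
            break
        for i in range(k):
            pool_buf[p, pool_n[p]] = pool_buf[v, i]
            pool_n[p] += 1
    total = 0.0
    for u in range(2 * n_tips - 2):
        total += g_time[g_parent[u]] - g_time[u]
    return total


@njit(cache=False)
def gene_tree_batch(seed, n_loci, parent, tau, theta, order, tip_count,
                    tip_offset, n_tips, out_parent, out_time):
    np.random.seed(seed)
    S = parent.shape[0]
    pool_buf = np.empty((S, n_tips), dtype=np.int32)
    pool_n = np.zeros(S, dtype=np.int32)
    g_parent = np.empty(2 * n_tips - 1, dtype=np.int32)
    g_time = np.empty(2 * n_tips - 1, dtype=np.float64)
    for r in range(n_loci):
        _simulate_tree(parent, tau, theta, order, tip_count, tip_offset,
                       n_tips, pool_buf, pool_n, g_parent, g_time)
        out_parent[r] = g_parent
        out_time[r] = g_time


@njit(cache=False)
def _branch_cumlen(g_parent, g_time, n_tips, cum):
    total = 0.0
    for u in range(2 * n_tips - 2):
        total += g_time[g_parent[u]] - g_time[u]
        cum[u] = total
    return total


@njit(cache=False)
def snp_batch(seed, n_loci, parent, tau, theta, order, tip_count,
              tip_offset, n_tips, out_states, out_poly):
    """Single-site JC loci; out_states (n_loci, n_tips) int8 in 0..3,
    out_poly flags loci with >= 2 observed alleles."""
    np.random.seed(seed)
    S = parent.shape[0]
    n_nodes = 2 * n_tips - 1
    pool_buf = np.empty((S, n_tips), dtype=np.int32)
    pool_n = np.zeros(S, dtype=np.int32)
    g_parent = np.empty(n_nodes, dtype=np.int32)
    g_time = np.empty(n_nodes, dtype=np.float64)
    cum = np.empty(n_nodes - 1, dtype=np.float64)
    nmut_b = np.empty(n_nodes, dtype=np.int32)
    st = np.empty(n_nodes, dtype=np.int8)
    for r in range(n_loci):
        _simulate_tree(parent, tau, theta, order, tip_count, tip_offset,
                       n_tips, pool_buf, pool_n, g_parent, g_time)
        total = _branch_cumlen(g_parent, g_time, n_tips, cum)
        nmut = np.random.poisson(total)
        if nmut == 0:
            out_poly[r] = False
            for i in range(n_tips):
                out_states[r, i] = 0
            continue
        for u in range(n_nodes):
            nmut_b[u] = 0
        for _ in range(nmut):
            x = np.random.uniform(0.0, total)
            u = np.searchsorted(cum, x)
            nmut_b[u] += 1
        st[n_nodes - 1] = np.random.randint(4)
        for u in range(n_nodes - 2, -1, -1):
            s = st[g_parent[u]]
            for _ in range(nmut_b[u]):
                s = (s + 1 + np.random.randint(3)) % 4
            st[u] = s
        poly = False
        for i in range(n_tips):
            out_states[r, i] = st[i]
            if st[i] != st[0]:
                poly = True
        out_poly[r] = poly


@njit(cache=False)
def aflp_batch(seed, n_loci, parent, tau, theta, order, tip_count,
               tip_offset, n_tips, n_sites, out_bands, out_poly):
    """Dominant binary loci from ``n_sites`` recognition positions.

    A haplotype carries the band iff all positions still match the
    ancestral (root) recognition state; a diploid individual scores 1 iff
    at least one of its two haplotypes carries the band. out_bands has one
    column per individual (n_tips // 2).
    """
    np.random.seed(seed)
    S = parent.shape[0]
    n_nodes = 2 * n_tips - 1
    n_ind = n_tips // 2
    pool_buf = np.empty((S, n_tips), dtype=np.int32)
    pool_n = np.zeros(S, dtype=np.int32)
    g_parent = np.empty(n_nodes, dtype=np.int32)
    g_time = np.empty(n_nodes, dtype=np.float64)
    cum = np.empty(n_nodes - 1, dtype=np.float64)
    nmut_bs = np.empty((n_nodes, n_sites), dtype=np.int32)
    st = np.empty((n_nodes, n_sites), dtype=np.int8)
    for r in range(n_loci):
        _simulate_tree(parent, tau, theta, order, tip_count, tip_offset,
                       n_tips, pool_buf, pool_n, g_parent, g_time)
        total = _branch_cumlen(g_parent, g_time, n_tips, cum)
        nmut = np.random.poisson(total * n_sites)
        if nmut == 0:
            out_poly[r] = False
            for i in range(n_ind):
                out_bands[r, i] = 1
            continue
        for u in range(n_nodes):
            for s in range(n_sites):
                nmut_bs[u, s] = 0
        for _ in range(nmut):
            x = np.random.uniform(0.0, total)
            u = np.searchsorted(cum, x)
            nmut_bs[u, np.random.randint(n_sites)] += 1
        for s in range(n_sites):
            st[n_nodes - 1, s] = 0  # ancestral recognition state
        for u in range(n_nodes - 2, -1, -1):
            pu = g_parent[u]
            for s in range(n_sites):
                x = st[pu, s]
                for _ in range(nmut_bs[u, s]):
                    x = (x + 1 + np.random.randint(3)) % 4
                st[u, s] = x
        poly = False
        first = np.int8(0)
        for i in range(n_ind):
            band = np.int8(0)
            for h in (2 * i, 2 * i + 1):
                intact = True
                for s in range(n_sites):
                    if st[h, s] != 0:
                        intact = False
                        break
                if intact:
                    band = np.int8(1)
                    break
            out_bands[r, i] = band
            if i == 0:
                first = band
            elif band != first:
                poly = True
        out_poly[r] = poly
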