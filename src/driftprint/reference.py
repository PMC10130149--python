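"""Naive reference implementations used for cross-validation.

Everything here is deliberately written as explicit enumeration (plain
loops, no shared code with the production paths) so it can serve as an
independent check of the vectorized implementations. These routines are
O(n^2)-ish and meant for small inputs only.
"""

from __future__ import annotations

import numpy as np


def naive_scan_roh(pos, genotypes, params):
    """Explicit window/run enumeration of the RoH definition.

    ``pos``: sorted 1-based SNV positions on one chromosome; ``genotypes``:
    the sample's calls (0 hom-ref, 1 het, 2 hom-alt, -1 missing). Returns a
    list of (start, end, n_snvs) tuples.
    """
    pos = list(map(int, pos))
    g = list(map(int, genotypes))
    n = len(g)
    if n == 0:
        return []
    W = min(params.window_size, n)
    n_windows = n - W + 1
    hom_window = []
    for i in range(n_windows):
        het = sum(1 for k in range(i, i + W) if g[k] == 1)
        miss = sum(1 for k in range(i, i + W) if g[k] == -1)
        hom_window.append(het <= params.window_het and miss <= params.window_missing)
    eligible = []
    for j in range(n):
        lo = max(0, j - W + 1)
        hi = min(j, n_windows - 1)
        cover = hi - lo + 1
        hom = sum(1 for i in range(lo, hi + 1) if hom_window[i])
        eligible.append(hom / cover >= params.hit_fraction)

    segments = []

    def close(a, b):
        n_snvs = b - a + 1
        length = pos[b] - pos[a] + 1
        if params.length_strict:
            if length <= params.min_length:
                return
        elif length < params.min_length:
            return
        if n_snvs < params.min_snvs:
            return
        if length / n_snvs > params.density_bp_per_snv:
            return
        segments.append((pos[a], pos[b], n_snvs))

    run_start = None
    prev = None
    for j in range(n):
        ok = eligible[j] and g[j] in (0, 2)
        if not ok:
            if run_start is not None:
                close(run_start, prev)
                run_start = None
            continue
        if run_start is not None and pos[j] - pos[prev] > params.max_gap:
            close(run_start, prev)
            run_start = None
        if run_start is None:
            run_start = j
        prev = j
    if run_start is not None:
        close(run_start, prev)
    return segments


def naive_allele_sharing_distance(gi, gj):
    """Site-by-site recount of the allele-sharing distance between two
    diploid genotype vectors (codes 0/1/2, -1 missing)."""
    total = 0.0
    n = 0
    for a, b in zip(gi, gj):
        if a < 0 or b < 0:
            continue
        # shared allele count between the two diploid genotypes
        if a == b:
            shared = 2
        elif abs(a - b) == 1:
            shared = 1
        else:
            shared = 0
        total += (2 - shared) / 2.0
        n += 1
    if n == 0:
        raise ValueError("no co-genotyped sites")
    return total / n


def random_additive_tree(n_taxa, rng):
    """Random binary tree topology with positive edge lengths and its exact
    path-length (additive) distance matrix. Returns (labels, matrix, newick).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # grow a tree by sequential attachment; represent as edge list on nodes
    # node 0..n_taxa-1 are leaves
    import itertools

    next_node = n_taxa
    edges = {}  # node -> list of (neighbor, length)

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def remove_edge(a, b):
        edges[a] = [(x, w) for x, w in edges[a] if x != b]
        edges[b] = [(x, w) for x, w in edges[b] if x != a]

    w = lambda: float(rng.uniform(0.1, 2.0))
    add_edge(0, 1, w())
    existing = [(0, 1)]
    for leaf in range(2, n_taxa):
        # pick a random existing edge, split it, attach the new leaf
        ei = int(rng.integers(len(existing)))
        a, b = existing[ei]
        length = next(l for x, l in edges[a] if x == b)
        mid = next_node
        next_node += 1
        remove_edge(a, b)
        cut = float(rng.uniform(0.05, 0.95)) * length
        add_edge(a, mid, cut)
        add_edge(mid, b, length - cut)
        add_edge(mid, leaf, w())
        existing[ei] = (a, mid)
        existing.append((mid, b))
        existing.append((mid, leaf))

    # path lengths by BFS from each leaf
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, wl in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + wl
                    stack.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    d = (d + d.T) / 2.0  # exact symmetry despite float summation order
    return labels, d, edges


def tree_splits_from_edges(edges, n_taxa):
    """Set of nontrivial bipartitions (frozensets of leaf indices, side not
    containing leaf 0) of the tree built by random_additive_tree."""
    splits = set()
    seen = set()
    for a in edges:
        for b, _ in edges[a]:
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            # leaves reachable from b without crossing a
            reach = set()
            stack = [b]
            visited = {a, b}
            while stack:
                u = stack.pop()
                if u < n_taxa:
                    reach.add(u)
                for v, _ in edges[u]:
                    if v not in visited:
                        visited.add(v)
                        stack.append(v)
            if 0 in reach:
                reach = set(range(n_taxa)) - reach
            if 1 < len(reach) < n_taxa - 1 or (len(reach) > 0 and len(reach) < n_taxa):
                if 2 <= len(reach) <= n_taxa - 2:
                    splits.add(frozenset(reach))
    return splits
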