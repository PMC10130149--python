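"""Pairwise genetic distances, neighbor-joining, SNV bootstrap, rooting.

The default distance is the allele-sharing distance: per site genotyped in
both samples, mismatch = (2 - number of shared alleles between the two
diploid genotypes)/2, averaged over co-genotyped sites; with dosage codes
g in {0,1,2} this is mean(|gi - gj|)/2. NJ is the classic Q-matrix
agglomeration; negative branch lengths are clamped to zero with the deficit
shifted to the sibling edge. Bootstrap pseudoreplicates resample SNV columns
with replacement; support on an internal edge of the full-data tree is the
percentage of replicate trees containing the same bipartition.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, SampleTable

log = logging.getLogger(__name__)

ALLELE_SHARING = "allele-sharing"
P_GENOTYPE = "p-genotype"


# ---------------------------------------------------------------------------
# Distances

def pairwise_distance(matrix: GenotypeMatrix, i, j, metric: str = ALLELE_SHARING) -> float:
    """Distance between two samples (names or indices)."""
    if isinstance(i, str):
        i = matrix.sample_index(i)
    if isinstance(j, str):
        j = matrix.sample_index(j)
    gi = matrix.genotypes[i].astype(np.int16)
    gj = matrix.genotypes[j].astype(np.int16)
    ok = (gi != MISSING) & (gj != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no co-genotyped sites between the two samples")
    if metric == ALLELE_SHARING:
        return float(np.abs(gi[ok] - gj[ok]).sum() / (2.0 * n))
    if metric == P_GENOTYPE:
        return float((gi[ok] != gj[ok]).sum() / n)
    raise ValueError(f"unknown metric {metric!r}")


def distance_matrix(matrix: GenotypeMatrix, metric: str = ALLELE_SHARING,
                    extra_rows: dict[str, np.ndarray] | None = None) -> tuple[list[str], np.ndarray]:
    """Full symmetric distance matrix over matrix samples plus optional
    extra pseudo-samples (e.g. the outgroup allele track as genotypes)."""
    labels = list(matrix.samples)
    G = [matrix.genotypes[k] for k in range(matrix.n_samples)]
    if extra_rows:
        for name, row in extra_rows.items():
            labels.append(name)
            G.append(np.asarray(row, dtype=np.int8))
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        ga = G[a].astype(np.int16)
        for b in range(a + 1, n):
            gb = G[b].astype(np.int16)
            ok = (ga != MISSING) & (gb != MISSING)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no co-genotyped sites between {labels[a]} and {labels[b]}")
            if metric == ALLELE_SHARING:
                d[a, b] = d[b, a] = float(np.abs(ga[ok] - gb[ok]).sum() / (2.0 * m))
            elif metric == P_GENOTYPE:
                d[a, b] = d[b, a] = float((ga[ok] != gb[ok]).sum() / m)
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return labels, d


def population_distance_matrix(labels: list[str], d: np.ndarray,
                               samples: SampleTable,
                               outgroup_label: str | None = None) -> tuple[list[str], np.ndarray]:
    """Population-level distances = mean over between-population sample pairs."""
    groups: dict[str, list[int]] = {}
    for k, s in enumerate(labels):
        if outgroup_label is not None and s == outgroup_label:
            groups.setdefault(outgroup_label, []).append(k)
            continue
        try:
            pop = samples.population_of(s)
        except KeyError:
            continue
        groups.setdefault(pop, []).append(k)
    pops = list(groups)
    n = len(pops)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            vals = [d[i, j] for i in groups[pops[a]] for j in groups[pops[b]]]
            out[a, b] = out[b, a] = float(np.mean(vals))
    return pops, out


def outgroup_genotypes(sites: pd.DataFrame, outgroup) -> np.ndarray:
    """Pseudo-diploid genotypes for the outgroup allele track: hom-ref when
    the outgroup base equals ref, hom-alt when it equals alt, else missing."""
    g = np.full(len(sites), MISSING, dtype=np.int8)
    for k, (chrom, pos, ref, alt) in enumerate(
        zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"])
    ):
        b = outgroup.base_at(str(chrom), int(pos))
        if b == ref:
            g[k] = 0
        elif b == alt:
            g[k] = 2
    return g


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(labels: list[str], d: np.ndarray) -> dendropy.Tree:
    """Classic neighbor joining; returns an unrooted dendropy tree.

    Negative branch lengths produced by the length formulas are clamped to
    zero with the subtraction shifted onto the sibling edge (logged).
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    D = d.copy()
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            log.info("nj: clamped negative branch %.4g to 0", li)
            lj += li
            li = 0.0
        if lj < 0:
            log.info("nj: clamped negative branch %.4g to 0", lj)
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # new distances
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # final three-point join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            log.info("nj: clamped negative terminal branch %.4g to 0", lk)
            lk = 0.0
        center.add_child(nodes[k])
        nodes[k].edge.length = lk
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial splits as frozensets of tip labels, normalized to the side
    not containing the lexicographically smallest label."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    all_labels = set(labels)
    anchor = labels[0]
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_labels - side)
        if 2 <= len(side) <= len(all_labels) - 2:
            splits.add(side)
    return splits


def _node_split(node, all_labels: set[str], anchor: str) -> frozenset[str]:
    side = frozenset(l.taxon.label for l in node.leaf_iter())
    if anchor in side:
        side = frozenset(all_labels - side)
    return side


def bootstrap_supports(matrix: GenotypeMatrix, n_reps: int, seed: int,
                       metric: str = ALLELE_SHARING,
                       extra_rows: dict[str, np.ndarray] | None = None,
                       tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Attach bootstrap supports (integer percent) to the full-data NJ tree.

    Each pseudoreplicate draws n_sites SNV column indices with replacement
    from ``np.random.default_rng(seed)``; supports count the replicate trees
    containing each internal bipartition of the full tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, d = distance_matrix(matrix, metric=metric, extra_rows=extra_rows)
    if tree is None:
        tree = nj_tree(labels, d)
    all_labels = set(labels)
    anchor = min(all_labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    n_sites = matrix.n_sites
    for _ in range(n_reps):
        idx = rng.integers(0, n_sites, size=n_sites)
        resampled = GenotypeMatrix(
            samples=list(matrix.samples),
            sites=matrix.sites.iloc[idx].reset_index(drop=True),
            genotypes=matrix.genotypes[:, idx],
            callable_sites=matrix.callable_sites,
        )
        extra = None
        if extra_rows:
            extra = {k: np.asarray(v)[idx] for k, v in extra_rows.items()}
        rl, rd = distance_matrix(resampled, metric=metric, extra_rows=extra)
        rep_tree = nj_tree(rl, rd)
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        split = _node_split(node, all_labels, anchor)
        if 2 <= len(split) <= len(all_labels) - 2:
            node.label = str(int(round(100.0 * counts.get(split, 0) / n_reps)))
    return tree


def root_tree(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge (at its midpoint); bipartition
    supports carry over because the split set is unchanged by rooting."""
    tree = tree.clone(depth=1)
    leaf = None
    for l in tree.leaf_node_iter():
        if l.taxon.label == outgroup_label:
            leaf = l
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_label!r} not found in tree")
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def supports_table(tree: dendropy.Tree) -> pd.DataFrame:
    rows = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        tips = sorted(l.taxon.label for l in node.leaf_iter())
        rows.append({"clade": ",".join(tips), "support": int(node.label)})
    return pd.DataFrame(rows)
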