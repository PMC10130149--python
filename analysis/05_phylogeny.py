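"""NJ phylogeny of samples and populations with SNV-bootstrap supports.

Allele-sharing distances over all pairs (outgroup included as a
pseudo-diploid from its allele track), neighbor joining, bootstrap
pseudoreplicates by resampling SNV columns, and rooting on the outgroup.
"""

import argparse
from pathlib import Path

import pandas as pd

from driftprint import io_formats, phylo


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--bootstrap", type=int, default=500)
    args = ap.parse_args()

    samples = io_formats.read_sample_table(args.bundle / "samples.tsv")
    matrix = io_formats.read_vcf(args.bundle / "cohort.vcf")
    outgroup = io_formats.read_outgroup_alleles(args.bundle / "outgroup_alleles.tsv")
    extra = {"outgroup": phylo.outgroup_genotypes(matrix.sites, outgroup)}

    labels, d = phylo.distance_matrix(matrix, extra_rows=extra)
    tree = phylo.bootstrap_supports(matrix, n_reps=args.bootstrap, seed=args.seed,
                                    extra_rows=extra)
    rooted = phylo.root_tree(tree, "outgroup")

    pops, pop_d = phylo.population_distance_matrix(labels, d, samples,
                                                   outgroup_label="outgroup")
    pop_tree = phylo.root_tree(phylo.nj_tree(pops, pop_d), "outgroup")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(d, index=labels, columns=labels).to_csv(
        args.out / "distances_samples.tsv", sep="\t")
    pd.DataFrame(pop_d, index=pops, columns=pops).to_csv(
        args.out / "distances_populations.tsv", sep="\t")
    io_formats.write_newick(rooted, args.out / "tree_samples.nwk")
    io_formats.write_newick(pop_tree, args.out / "tree_populations.nwk")

    supports = phylo.supports_table(rooted)
    full = supports.loc[supports["support"] == 100]
    print(f"sample tree: {len(supports)} internal edges, "
          f"{len(full)} with 100% bootstrap support ({args.bootstrap} replicates)")
    # report whether each deme forms a clade (unrooted bipartition check)
    splits = phylo.tree_bipartitions(rooted)
    labels_all = {l.taxon.label for l in rooted.leaf_node_iter()}
    anchor = min(labels_all)
    demes = {}
    for s in samples.non_outgroup_samples():
        demes.setdefault(samples.population_of(s), set()).add(s)
    for deme, members in sorted(demes.items()):
        side = frozenset(members if anchor not in members else labels_all - members)
        print(f"  {deme:<20s} monophyletic: {side in splits}")


if __name__ == "__main__":
    main()
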