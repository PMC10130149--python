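"""Functional classification, dN/dS diversity ratios and zygosity of the load.

SNVs are classified against the coding annotation (synonymous / missense /
LoF), per-genome dN/dS is the SNV count per class divided by the
Nei-Gojobori site totals, deleterious SNVs are conservation score > 4,
alleles are polarized with the outgroup track, and carried variants are
partitioned into homozygous-derived vs heterozygous per category.
"""

import argparse
from pathlib import Path

from driftprint import io_formats, load


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = io_formats.read_sample_table(args.bundle / "samples.tsv")
    matrix = io_formats.read_vcf(args.bundle / "cohort.vcf")
    annotation = io_formats.read_annotation(args.bundle / "annotation.gff3")
    reference = io_formats.read_fasta(args.bundle / "reference.fa")
    conservation = io_formats.read_conservation(args.bundle / "conservation.bed")
    outgroup = io_formats.read_outgroup_alleles(args.bundle / "outgroup_alleles.tsv")

    counts = load.count_sites(annotation, reference)
    effects = load.classify_sites(matrix.sites, annotation, reference)
    scores = conservation.scores_for_sites(matrix.sites)
    derived = load.polarize_sites(matrix.sites, outgroup)
    profiles = load.load_profiles(matrix, effects, counts, samples,
                                  conservation_scores=scores, derived=derived)

    args.out.mkdir(parents=True, exist_ok=True)
    effects.assign(**{c: matrix.sites[c] for c in ("chrom", "pos", "ref", "alt")}).to_csv(
        args.out / "effects.tsv", sep="\t", index=False)
    profiles.to_csv(args.out / "load_profiles.tsv", sep="\t", index=False)

    print(f"site totals: {counts.syn_sites:,.0f} synonymous, "
          f"{counts.nonsyn_sites:,.0f} nonsynonymous over {counts.n_codons:,} codons")
    print(effects["effect"].value_counts().to_string())
    by_pop = profiles.groupby("population")[
        ["dnds", "nonsynonymous_hom_fraction", "deleterious_hom_fraction",
         "LoF_hom_fraction"]].mean()
    print("per-population means (dN/dS; hom fractions nonsyn/deleterious/LoF):")
    print(by_pop.round(3).to_string())


if __name__ == "__main__":
    main()
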