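"""Runs of homozygosity per genome.

Sites are filtered like the genotyping pipeline (missingness ≤ 1%, MAF ≥
0.05 over the study samples), then each genome is scanned with the
0-heterozygote sliding window and segments above the 0.5 Mb floor are
reported with medium (0.2-1 Mb) and long (> 2 Mb) class counts, plus
Z tests of the landlocked deme against every other population.
"""

import argparse
from pathlib import Path

import pandas as pd

from driftprint import io_formats, roh, stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = io_formats.read_sample_table(args.bundle / "samples.tsv")
    matrix = io_formats.read_vcf(args.bundle / "cohort.vcf")
    params = roh.RohParameters()  # geno 0.01, maf 0.05, window-het 0, > 0.5 Mb

    filtered = roh.filter_sites(matrix, params, samples)
    segments = roh.scan_all_samples(filtered, samples, params)
    summary = roh.summarize_roh(segments, samples)

    args.out.mkdir(parents=True, exist_ok=True)
    if not segments.empty:
        bed = segments.assign(start0=segments["start"] - 1)
        bed[["chrom", "start0", "end", "sample", "length", "n_snvs"]].to_csv(
            args.out / "roh_segments.bed", sep="\t", header=False, index=False)
    summary.to_csv(args.out / "roh_summary.tsv", sep="\t", index=False)

    by_pop = summary.groupby("population")[["n_segments", "total_length"]].mean()
    print(f"retained {filtered.n_sites} of {matrix.n_sites} sites after "
          f"missingness/MAF filtering")
    print("mean RoH per population (count / total bp):")
    for pop, r in by_pop.iterrows():
        print(f"  {pop:<20s} {r['n_segments']:6.1f}  {r['total_length']:12,.0f}")

    landlocked = samples.landlocked_populations()
    rows = []
    for ll in landlocked:
        for other in by_pop.index:
            if other == ll:
                continue
            for col in ("n_segments", "total_length"):
                a = summary.loc[summary["population"] == ll, col]
                b = summary.loc[summary["population"] == other, col]
                if len(a) >= 2 and len(b) >= 2:
                    r = stats.z_test(a, b)
                    rows.append({"metric": col, "landlocked": ll, "vs": other,
                                 "z": r.z, "p": r.p})
    tests = pd.DataFrame(rows)
    tests.to_csv(args.out / "roh_z_tests.tsv", sep="\t", index=False)
    if not tests.empty:
        worst = tests.groupby("metric")["p"].max()
        for metric, p in worst.items():
            print(f"landlocked vs anadromous, {metric}: at most P = {p:.2g}")


if __name__ == "__main__":
    main()
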