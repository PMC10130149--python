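"""Significance tests across populations and the dN/dS vs Ne regression.

Z tests compare the landlocked deme against every anadromous population for
heterozygosity, RoH burden and load statistics; the per-genome dN/dS ratio
is regressed on the effective size implied by each genome's heterozygosity.
"""

import argparse
from pathlib import Path

import pandas as pd

from driftprint import stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    het = pd.read_csv(args.results / "heterozygosity.tsv", sep="\t")
    roh = pd.read_csv(args.results / "roh_summary.tsv", sep="\t")
    profiles = pd.read_csv(args.results / "load_profiles.tsv", sep="\t")

    landlocked = sorted(set(het["population"]) & {"Namsen_landlocked", "landlocked"})
    ll = landlocked[0] if landlocked else het.groupby("population")["H"].mean().idxmin()

    rows = []
    frames = {"H": het, "n_segments": roh, "total_length": roh, "dnds": profiles,
              "deleterious_hom_fraction": profiles}
    for col, frame in frames.items():
        for other in sorted(set(frame["population"]) - {ll}):
            a = frame.loc[frame["population"] == ll, col].dropna()
            b = frame.loc[frame["population"] == other, col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                r = stats.z_test(a, b)
                rows.append({"metric": col, "landlocked": ll, "vs": other,
                             "mean_landlocked": r.mean_a, "mean_other": r.mean_b,
                             "z": r.z, "p": r.p})
    tests = pd.DataFrame(rows)
    tests.to_csv(args.results / "z_tests.tsv", sep="\t", index=False)

    merged = het.merge(profiles[["sample", "dnds"]], on="sample").dropna(subset=["dnds"])
    corr = stats.pearson_with_p(merged["Ne"], merged["dnds"])
    pd.DataFrame([{"n": corr.n, "r": corr.r, "p": corr.p,
                   "slope": corr.slope, "intercept": corr.intercept}]).to_csv(
        args.results / "correlation.tsv", sep="\t", index=False)

    print(f"landlocked deme: {ll}")
    for metric, sub in tests.groupby("metric"):
        print(f"  {metric:<26s} vs anadromous: at most P = {sub['p'].max():.3g}")
    print(f"dN/dS vs Ne: r = {corr.r:.2f}, P = {corr.p:.2g} (n = {corr.n})")


if __name__ == "__main__":
    main()
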