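"""Canned simulation scenarios and the bottleneck signature-recovery harness.

``two_deme_bottleneck`` is the package's standard test condition: a stable
deme of 100 diploids and a deme reduced to 10 diploids for the last 50
generations, with deleterious nonsynonymous mutations at s = -0.01, h = 0.5.
``paper_like`` mirrors the six-population cohort layout (five anadromous
demes sampled 5/5/5/5/4 plus one landlocked deme of 5) at desk scale.

The signature-recovery harness measures, per seeded replicate, whether the
bottlenecked deme shows (i) lower mean heterozygosity, (ii) more and longer
runs of homozygosity, (iii) a higher nonsynonymous/synonymous diversity
ratio, and (iv) a higher homozygous fraction among deleterious variants.
The diversity ratio uses allele-count weighting (the πN/πS form): at short
divergence times the presence-counted ratio is dominated by the concave
carried-probability transform of rare variants, which masks relaxed purging,
whereas the frequency-weighted form responds to it directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diversity, load, roh
from .io_formats import OutgroupAlleles
from .roh import RohParameters
from .synthetic import (
    DemeSpec,
    DemographyModel,
    MutationModel,
    RecombinationModel,
    SimulatedCohort,
    simulate_cohort,
)

#: the two-deme scenario chromosome; 10 Mb gives roughly 5-6 thousand SNVs
#: and a few hundred recombinationally independent blocks. Heterozygosity,
#: RoH and zygosity contrasts are resolved comfortably at this scale; the
#: diversity-ratio contrast after only 50 bottleneck generations is a
#: few-percent effect of the same order as between-replicate drift noise
#: (see the methods note).
TWO_DEME_LENGTH = 10_000_000

STABLE = "stable"
BOTTLENECK = "landlocked"


def two_deme_demography(n_stable: int = 100, n_bottleneck: int = 10,
                        split_gens: int = 50, n_anc: int = 100,
                        samples_per_deme: int = 10) -> DemographyModel:
    return DemographyModel(
        n_anc=n_anc,
        demes=[
            DemeSpec(STABLE, n_stable, 0, "anadromous", samples_per_deme),
            DemeSpec(BOTTLENECK, n_bottleneck, split_gens, "landlocked",
                     min(samples_per_deme, n_bottleneck)),
        ],
        outgroup_divergence=15_000,
    )


def two_deme_bottleneck(seed: int, length: int = TWO_DEME_LENGTH) -> SimulatedCohort:
    return simulate_cohort(
        two_deme_demography(),
        MutationModel(s_deleterious=-0.01, h=0.5),
        RecombinationModel(length=length),
        seed=seed,
    )


def paper_like_demography() -> DemographyModel:
    """Six demes: one landlocked (recent bottleneck to 10 diploids) and five
    anadromous, sampled 5/5/5/5/5/4, splitting off a common trunk."""
    return DemographyModel(
        n_anc=100,
        demes=[
            DemeSpec("Namsen_Bjoera", 100, 0, "anadromous", 5),
            DemeSpec("Namsen_landlocked", 10, 50, "landlocked", 5),
            DemeSpec("Suldalslaagen", 100, 120, "anadromous", 5),
            DemeSpec("Baltic_Sea", 100, 200, "anadromous", 5),
            DemeSpec("Tana", 100, 280, "anadromous", 5),
            DemeSpec("White_Sea", 100, 360, "anadromous", 4),
        ],
        outgroup_divergence=15_000,
    )


def paper_like_cohort(seed: int, length: int = 4_000_000) -> SimulatedCohort:
    return simulate_cohort(
        paper_like_demography(),
        MutationModel(s_deleterious=-0.01, h=0.5),
        RecombinationModel(length=length),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signature recovery

def replicate_summary(cohort: SimulatedCohort,
                      roh_params: RohParameters | None = None) -> pd.DataFrame:
    """Per-deme means of the four bottleneck-footprint statistics."""
    params = roh_params or RohParameters()
    het = diversity.heterozygosity_table(cohort.matrix, cohort.samples)
    filt = roh.filter_sites(cohort.matrix, params, cohort.samples)
    segs = roh.scan_all_samples(filt, cohort.samples, params)
    rsum = roh.summarize_roh(segs, cohort.samples)

    counts = load.count_sites(cohort.annotation, cohort.reference)
    effects = load.classify_sites(cohort.matrix.sites, cohort.annotation, cohort.reference)
    scores = (
        cohort.conservation.set_index("end")["score"]
        .reindex(cohort.matrix.sites["pos"])
        .to_numpy()
    )
    og = OutgroupAlleles(table={
        (str(r.chrom), int(r.pos)): str(r.base) for r in cohort.outgroup_table.itertuples()
    })
    derived = load.polarize_sites(cohort.matrix.sites, og)
    profiles = load.load_profiles(
        cohort.matrix, effects, counts, cohort.samples,
        conservation_scores=scores, derived=derived, weighting="allele-count",
    )

    merged = het.merge(rsum, on=["sample", "population"]).merge(
        profiles, on=["sample", "population"]
    )
    return merged.groupby("population")[
        ["H", "n_segments", "total_length", "dnds", "deleterious_hom_fraction"]
    ].mean()


def signature_recovery(n_replicates: int, seed: int,
                       length: int = TWO_DEME_LENGTH) -> pd.DataFrame:
    """Run seeded replicates of the two-deme scenario and score, for each,
    whether every bottleneck footprint points the expected way."""
    rows = []
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    for k, rep_seed in enumerate(rep_seeds):
        cohort = two_deme_bottleneck(int(rep_seed), length=length)
        by_pop = replicate_summary(cohort)
        b, s = by_pop.loc[BOTTLENECK], by_pop.loc[STABLE]
        rows.append({
            "replicate": k,
            "seed": int(rep_seed),
            "het_lower": bool(b["H"] < s["H"]),
            "roh_count_higher": bool(b["n_segments"] > s["n_segments"]),
            "roh_length_higher": bool(b["total_length"] > s["total_length"]),
            "dnds_higher": bool(b["dnds"] > s["dnds"]),
            "hom_deleterious_higher": bool(
                b["deleterious_hom_fraction"] > s["deleterious_hom_fraction"]
            ),
            "het_bottleneck": float(b["H"]),
            "het_stable": float(s["H"]),
            "dnds_bottleneck": float(b["dnds"]),
            "dnds_stable": float(s["dnds"]),
        })
    return pd.DataFrame(rows)
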