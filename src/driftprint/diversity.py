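"""Per-sample genomic heterozygosity, population summaries, and Ne estimation.

Under neutrality per-site heterozygosity H relates to the effective
population size through H = 4·Ne·μ. The paper-facing Ne conversion exists
in two conventions (see ``estimate_ne``) because the source study's printed
numbers follow H/μ while its stated formula is H/(4μ); the caller must pick
one explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HET, MISSING, GenotypeMatrix, SampleTable, warn

TEXTBOOK = "textbook"
PAPER_CALIBRATED = "paper-calibrated"


@dataclass
class HeterozygosityResult:
    sample: str
    het_count: int
    callable_sites: int
    H: float
    population: str | None = None


@dataclass
class NeEstimate:
    H: float
    mu: float
    convention: str
    Ne: float


def per_sample_heterozygosity(matrix: GenotypeMatrix, sample: str,
                              population: str | None = None) -> HeterozygosityResult:
    """H = (# heterozygous genotypes at retained biallelic sites) / callable sites."""
    i = matrix.sample_index(sample)
    callable_sites = matrix.get_callable(sample)
    if callable_sites <= 0:
        raise ValueError(f"sample {sample!r} has no callable sites")
    het = int(np.count_nonzero(matrix.genotypes[i] == HET))
    return HeterozygosityResult(
        sample=sample, het_count=het, callable_sites=callable_sites,
        H=het / callable_sites, population=population,
    )


def heterozygosity_table(matrix: GenotypeMatrix, samples: SampleTable) -> pd.DataFrame:
    rows = []
    for s in samples.non_outgroup_samples():
        if s not in matrix.samples:
            continue
        r = per_sample_heterozygosity(matrix, s, population=samples.population_of(s))
        rows.append(
            {"sample": r.sample, "population": r.population, "het_count": r.het_count,
             "callable": r.callable_sites, "H": r.H}
        )
    return pd.DataFrame(rows)


def population_summary(values: pd.DataFrame, value_col: str = "H",
                       order: list[str] | None = None) -> pd.DataFrame:
    """Per-population mean and SEM (sd/√n, ddof=1). SEM is NaN (with a
    warning) for single-sample populations. ``order`` fixes row order, e.g.
    following the phylogeny."""
    if values.empty:
        raise ValueError("empty input to population_summary")
    out = []
    for pop, sub in values.groupby("population", sort=False):
        v = sub[value_col].to_numpy(dtype=float)
        n = len(v)
        if n == 0:
            raise ValueError(f"population {pop!r} has no samples")
        if n == 1:
            warn(f"population {pop!r} has a single sample; SEM undefined")
            sem = np.nan
        else:
            sem = float(np.std(v, ddof=1) / np.sqrt(n))
        out.append({"population": pop, "n": n, "mean": float(np.mean(v)), "sem": sem})
    frame = pd.DataFrame(out)
    if order is not None:
        known = [p for p in order if p in set(frame["population"])]
        rest = [p for p in frame["population"] if p not in set(known)]
        frame = frame.set_index("population").loc[known + rest].reset_index()
    return frame


def estimate_ne(H: float, mu: float, convention: str) -> NeEstimate:
    """Convert per-site heterozygosity to a diploid effective size.

    convention='textbook':          Ne = H / (4μ)   (from H = 4·Ne·μ)
    convention='paper-calibrated':  Ne = H / μ      (the relation that
        reproduces the source study's printed effective sizes)
    """
    if mu <= 0:
        raise ValueError(f"mutation rate must be positive, got {mu}")
    if convention == TEXTBOOK:
        ne = H / (4.0 * mu)
    elif convention == PAPER_CALIBRATED:
        ne = H / mu
    else:
        raise ValueError(
            f"unknown convention {convention!r}; use {TEXTBOOK!r} or {PAPER_CALIBRATED!r}"
        )
    return NeEstimate(H=H, mu=mu, convention=convention, Ne=ne)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for headline Ne values)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
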