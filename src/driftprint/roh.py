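"""Runs-of-homozygosity detection with a plink-style SNV sliding window.

Site filtering mirrors ``--geno 0.01 --maf 0.05``; the scan mirrors
``--homozyg`` with ``--homozyg-window-het 0``: windows of ``window_size``
consecutive SNVs are labelled homozygous when they contain at most
``window_het`` heterozygous and ``window_missing`` missing calls; a SNV is
run-eligible when the fraction of windows covering it that are homozygous
reaches ``hit_fraction``. Maximal stretches of eligible, observed-homozygous
SNVs are reported as segments once they satisfy the span, SNV-count, gap and
density constraints. Segment coordinates are SNV-to-SNV spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import HET, MISSING, GenotypeMatrix, SampleTable

MEDIUM_CLASS = (200_000, 1_000_000)  # inclusive bounds, bp
LONG_CLASS = 2_000_000  # strict lower bound, bp


@dataclass(frozen=True)
class RohParameters:
    """Scanner parameters. geno, maf, window_het and the 0.5 Mb floor follow
    the replication configuration; the rest are plink-convention defaults."""

    geno: float = 0.01            # max per-site missingness to retain
    maf: float = 0.05             # drop sites with MAF strictly below this
    window_het: int = 0           # het calls allowed per window
    window_size: int = 50         # SNVs per window
    window_missing: int = 5       # missing calls allowed per window
    min_length: int = 500_000     # bp; strict ("> 0.5 Mb") by default
    length_strict: bool = True
    min_snvs: int = 100
    max_gap: int = 1_000_000      # bp between consecutive SNVs in a run
    density_bp_per_snv: int = 50_000
    hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.maf < 0.5):
            raise ValueError("maf must be in [0, 0.5)")
        if not (0 < self.hit_fraction <= 1):
            raise ValueError("hit_fraction must be in (0, 1]")
        for name in ("geno", "window_het", "window_size", "window_missing",
                     "min_length", "min_snvs", "max_gap", "density_bp_per_snv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def scaled(self, **kwargs) -> "RohParameters":
        return replace(self, **kwargs)


def filter_sites(matrix: GenotypeMatrix, params: RohParameters,
                 samples: SampleTable | None = None) -> GenotypeMatrix:
    """Drop sites with missingness > geno or minor-allele frequency < maf.

    Frequencies are computed from non-missing genotypes across the study
    samples (outgroup excluded when a sample table is provided). A site
    whose MAF equals the threshold exactly is retained.
    """
    if samples is not None:
        study = [s for s in samples.non_outgroup_samples() if s in matrix.samples]
        idx = np.asarray([matrix.sample_index(s) for s in study], dtype=int)
    else:
        idx = np.arange(matrix.n_samples)
    g = matrix.genotypes[idx]
    n = len(idx)
    missing = (g == MISSING).sum(axis=0)
    miss_frac = missing / max(n, 1)
    called = n - missing
    alt_alleles = np.where(g == MISSING, 0, g).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(called > 0, alt_alleles / (2.0 * called), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (miss_frac <= params.geno) & (maf >= params.maf) & (called > 0)
    return matrix.subset_sites(keep)


def _window_eligibility(g: np.ndarray, params: RohParameters) -> np.ndarray:
    """Per-SNV run eligibility from the sliding-window hit fraction."""
    n = g.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    W = min(params.window_size, n)
    het = (g == HET).astype(np.int64)
    miss = (g == MISSING).astype(np.int64)
    # sliding sums over windows [i, i+W)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_windows = n - W + 1
    wh = chet[W:] - chet[:-W]
    wm = cmiss[W:] - cmiss[:-W]
    hom_window = (wh <= params.window_het) & (wm <= params.window_missing)
    # windows covering SNV j: i in [max(0, j-W+1), min(j, n_windows-1)]
    chw = np.concatenate([[0], np.cumsum(hom_window.astype(np.int64))])
    j = np.arange(n)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n_windows - 1)
    cover = hi - lo + 1
    hom_cover = chw[hi + 1] - chw[lo]
    frac = hom_cover / cover
    return frac >= params.hit_fraction


def scan_roh(matrix: GenotypeMatrix, sample: str, params: RohParameters) -> pd.DataFrame:
    """Detect RoH segments for one sample.

    Returns a frame with columns sample, chrom, start, end, length, n_snvs
    (positions 1-based inclusive at the first/last SNV of the run). Input
    sites must be sorted by (chrom, pos).
    """
    if not matrix.is_sorted():
        raise ValueError("sites must be sorted by (chrom, pos) for RoH scanning")
    i = matrix.sample_index(sample)
    rows = []
    sites = matrix.sites
    for chrom in sites["chrom"].unique():
        mask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[mask, "pos"].to_numpy(dtype=np.int64)
        g = matrix.genotypes[i, mask]
        eligible = _window_eligibility(g, params)
        rows.extend(
            _emit_runs(str(chrom), pos, g, eligible, params, sample)
        )
    frame = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "length", "n_snvs"])
    return frame


def _emit_runs(chrom, pos, g, eligible, params, sample):
    """Split into maximal eligible-homozygous runs and apply segment filters."""
    out = []
    run_start = None  # index of first SNV in current run
    prev_idx = None
    hom = (g == 0) | (g == 2)
    ok = hom & eligible

    def close(a, b):  # run over site indices [a, b]
        n_snvs = b - a + 1
        length = int(pos[b] - pos[a] + 1)
        long_enough = length > params.min_length if params.length_strict else length >= params.min_length
        if not long_enough or n_snvs < params.min_snvs:
            return
        if length / n_snvs > params.density_bp_per_snv:
            return
        out.append({"sample": sample, "chrom": chrom, "start": int(pos[a]),
                    "end": int(pos[b]), "length": length, "n_snvs": int(n_snvs)})

    for j in range(g.size):
        if not ok[j]:
            if run_start is not None:
                close(run_start, prev_idx)
                run_start = None
            continue
        if run_start is not None and pos[j] - pos[prev_idx] > params.max_gap:
            close(run_start, prev_idx)
            run_start = None
        if run_start is None:
            run_start = j
        prev_idx = j
    if run_start is not None:
        close(run_start, prev_idx)
    return out


def scan_all_samples(matrix: GenotypeMatrix, samples: SampleTable,
                     params: RohParameters) -> pd.DataFrame:
    frames = [scan_roh(matrix, s, params) for s in samples.non_outgroup_samples()
              if s in matrix.samples]
    if not frames:
        return pd.DataFrame(columns=["sample", "chrom", "start", "end", "length", "n_snvs"])
    return pd.concat(frames, ignore_index=True)


def summarize_roh(segments: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Per-sample RoH summary: count, total length, and size-class counts
    (medium 0.2–1 Mb inclusive; long > 2 Mb strict)."""
    rows = []
    by_sample = dict(tuple(segments.groupby("sample"))) if not segments.empty else {}
    for s in samples.non_outgroup_samples():
        sub = by_sample.get(s)
        if sub is None or sub.empty:
            rows.append({"sample": s, "population": samples.population_of(s),
                         "n_segments": 0, "total_length": 0,
                         "n_medium": 0, "n_long": 0})
            continue
        lengths = sub["length"].to_numpy()
        rows.append({
            "sample": s,
            "population": samples.population_of(s),
            "n_segments": int(len(sub)),
            "total_length": int(lengths.sum()),
            "n_medium": int(((lengths >= MEDIUM_CLASS[0]) & (lengths <= MEDIUM_CLASS[1])).sum()),
            "n_long": int((lengths > LONG_CLASS).sum()),
        })
    return pd.DataFrame(rows)
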