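"""Core in-memory containers: genotype matrix, sample table, annotation, tracks.

Genotype encoding (int8): 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
VCF positions are 1-based; conservation intervals are BED 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples × biallelic SNV sites with per-sample callable-site counts.

    ``callable_sites`` is the denominator used for per-site heterozygosity;
    when it was not supplied by the user it is derived from the VCF
    (non-missing genotyped sites per sample) and ``callable_fallback`` is
    flagged so reports can say so.
    """

    samples: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    genotypes: np.ndarray  # int8, shape (n_samples, n_sites)
    callable_sites: np.ndarray | None = None
    callable_fallback: bool = False
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in genotype matrix") from None

    def get_callable(self, sample: str) -> int:
        i = self.sample_index(sample)
        if self.callable_sites is not None:
            return int(self.callable_sites[i])
        return int(np.count_nonzero(self.genotypes[i] != MISSING))

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, mask],
            callable_sites=None if self.callable_sites is None else self.callable_sites.copy(),
            callable_fallback=self.callable_fallback,
            dropped=dict(self.dropped),
        )

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in names]
        return GenotypeMatrix(
            samples=list(names),
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx],
            callable_sites=None if self.callable_sites is None else self.callable_sites[idx],
            callable_fallback=self.callable_fallback,
            dropped=dict(self.dropped),
        )

    def is_sorted(self) -> bool:
        s = self.sites
        prev = None
        for chrom, pos in zip(s["chrom"], s["pos"]):
            if prev is not None and prev[0] == chrom and pos < prev[1]:
                return False
            prev = (chrom, pos)
        return True


@dataclass
class SampleTable:
    """Per-sample metadata: population, life-history class, outgroup flag."""

    table: pd.DataFrame  # columns: sample, population, life_history, outgroup[, callable_sites]

    REQUIRED = ("sample", "population", "life_history")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if "outgroup" not in self.table.columns:
            self.table["outgroup"] = False
        self.table["outgroup"] = self.table["outgroup"].astype(bool)
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate samples in sample table: {dups}")

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def population_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in sample table")
        return str(row["population"].iloc[0])

    def populations(self, include_outgroup: bool = False) -> list[str]:
        t = self.table if include_outgroup else self.table.loc[~self.table["outgroup"]]
        return list(dict.fromkeys(t["population"]))

    def samples_of(self, population: str) -> list[str]:
        return self.table.loc[self.table["population"] == population, "sample"].tolist()

    def non_outgroup_samples(self) -> list[str]:
        return self.table.loc[~self.table["outgroup"], "sample"].tolist()

    def landlocked_populations(self) -> list[str]:
        t = self.table.loc[~self.table["outgroup"]]
        return list(dict.fromkeys(t.loc[t["life_history"] == "landlocked", "population"]))

    def callable_for(self, samples: list[str]) -> np.ndarray | None:
        if "callable_sites" not in self.table.columns:
            return None
        lut = dict(zip(self.table["sample"], self.table["callable_sites"]))
        vals = [lut.get(s) for s in samples]
        if any(v is None or pd.isna(v) for v in vals):
            return None
        return np.asarray(vals, dtype=np.int64)


class ConservationTrack:
    """Per-position conservation (GERP) scores stored as BED-style intervals.

    Intervals are 0-based half-open; queries are 1-based chromosomal
    positions. Overlapping intervals are rejected at construction.
    """

    def __init__(self, frame: pd.DataFrame):
        # frame columns: chrom, start, end, score
        if (frame["start"] >= frame["end"]).any():
            bad = frame.loc[frame["start"] >= frame["end"]].iloc[0]
            raise ValueError(
                f"conservation interval with start >= end: "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping conservation intervals on {chrom}")
            self._by_chrom[str(chrom)] = (starts, ends, sub["score"].to_numpy(dtype=float))

    def score_at(self, chrom: str, pos: int) -> float | None:
        """Score covering 1-based position ``pos``, or None if uncovered."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, scores = entry
        zero = pos - 1  # convert to 0-based
        i = int(np.searchsorted(starts, zero, side="right")) - 1
        if i >= 0 and zero < ends[i]:
            return float(scores[i])
        return None

    def scores_for_sites(self, sites: pd.DataFrame) -> np.ndarray:
        """Vector of scores (NaN where uncovered) for a site table."""
        out = np.full(len(sites), np.nan)
        for k, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
            s = self.score_at(str(chrom), int(pos))
            if s is not None:
                out[k] = s
        return out


@dataclass
class Transcript:
    """A coding transcript: ordered coding intervals in transcription order.

    Intervals are 1-based inclusive genomic coordinates. For minus-strand
    transcripts the intervals are listed in transcription order (descending
    genomic position) and codons are read off the reverse complement.
    """

    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    intervals: list[tuple[int, int]]
    frame: int = 0  # codon phase of the first coding base

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        length = self.coding_length()
        if (length - self.frame) % 3 != 0:
            raise ValueError(
                f"transcript {self.transcript_id}: coding length {length} "
                f"(frame {self.frame}) not divisible by 3"
            )
        # transcription order sanity
        starts = [a for a, _ in self.intervals]
        if self.strand == "+" and starts != sorted(starts):
            raise ValueError(f"transcript {self.transcript_id}: intervals not in transcription order")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ValueError(f"transcript {self.transcript_id}: intervals not in transcription order")

    def coding_length(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)

    def genomic_positions(self) -> np.ndarray:
        """Genomic positions of coding bases in transcript (5'→3') order."""
        chunks = []
        for a, b in self.intervals:
            if self.strand == "+":
                chunks.append(np.arange(a, b + 1, dtype=np.int64))
            else:
                chunks.append(np.arange(b, a - 1, -1, dtype=np.int64))
        return np.concatenate(chunks)


@dataclass
class CodingAnnotation:
    transcripts: list[Transcript]

    def by_chrom(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            out.setdefault(t.chrom, []).append(t)
        return out


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
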