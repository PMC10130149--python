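"""Forward Wright–Fisher simulation of a multi-deme diploid cohort.

The generator produces the complete input bundle the pipeline consumes —
VCF, sample table, coding annotation, conservation track, outgroup alleles,
reference FASTA — together with a per-variant truth record, so every
downstream stage can be verified without external data.

Model: discrete generations, diploid Wright–Fisher with recombination
(Poisson crossovers along one chromosome) and viability selection at
deleterious nonsynonymous sites (relative viabilities 1, 1+hs, 1+2s for
0/1/2 copies of a deleterious allele with s < 0, multiplicative across
sites). After a burn-in of ≥ 8·N_anc generations the population splits into
demes per the demography; one deme may carry a recent bottleneck. Mutations
follow the infinite-sites approximation (colliding positions are skipped);
within coding genes the synonymous/nonsynonymous/LoF class of each new
mutation is determined by the actual codon change against the standard
genetic code. The outgroup is the ancestral sequence plus independent
mutation along the outgroup branch, so the emitted outgroup track carries
realistic polarization error while the truth record keeps the exact
ancestral allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon import GENETIC_CODE, STOP_CODONS, translate_codon
from .model import CodingAnnotation, GenotypeMatrix, SampleTable, Transcript

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in 0..3 codes

# effect-class codes used internally by the simulator
NONCODING_C, SYN_C, NONSYN_C, STOP_GAINED_C, STOP_LOST_C, START_LOST_C = range(6)
_CLASS_NAMES = {
    NONCODING_C: "noncoding",
    SYN_C: "synonymous",
    NONSYN_C: "nonsynonymous",
    STOP_GAINED_C: "stop_gained",
    STOP_LOST_C: "stop_lost",
    START_LOST_C: "start_lost",
}
_SELECTED_CLASSES = (NONSYN_C, STOP_GAINED_C, STOP_LOST_C, START_LOST_C)


@dataclass
class DemeSpec:
    name: str
    size: int  # diploid individuals
    split_time: int  # generations before present; 0 for the trunk deme
    life_history: str = "anadromous"  # or "landlocked"
    n_samples: int = 5


@dataclass
class DemographyModel:
    """Split-plus-bottleneck demography.

    The first deme is the trunk (the direct continuation of the ancestral
    lineage); every other deme branches off the trunk at its split time
    (generations before present). The simulated span after burn-in is the
    largest split time.
    """

    n_anc: int
    demes: list[DemeSpec]
    outgroup_divergence: int = 10_000  # generations on the outgroup branch
    burn_in: int | None = None  # default 8 * n_anc
    bottleneck: bool = True

    def __post_init__(self) -> None:
        if self.n_anc < 2 or any(d.size < 2 for d in self.demes):
            raise ValueError("all population sizes must be >= 2")
        if not self.demes:
            raise ValueError("at least one deme required")
        if self.demes[0].split_time != 0:
            raise ValueError("the first (trunk) deme must have split_time 0")
        times = [d.split_time for d in self.demes[1:]]
        if any(t <= 0 for t in times):
            raise ValueError("split times of non-trunk demes must be positive")
        if self.bottleneck:
            landlocked = [d for d in self.demes if d.life_history == "landlocked"]
            if landlocked and min(d.size for d in landlocked) > max(d.size for d in self.demes):
                raise ValueError("bottleneck scenario requires N_b <= N_s")

    @property
    def burnin_generations(self) -> int:
        return self.burn_in if self.burn_in is not None else 8 * self.n_anc


@dataclass
class MutationModel:
    mu: float = 3.0e-7  # per site per generation (desk-scaled)
    coding_fraction: float = 0.3
    s_deleterious: float = -0.01  # stored negative; viability 1+hs, 1+2s
    h: float = 0.5
    fraction_deleterious: float = 0.8  # of nonsynonymous changes
    gene_length: int = 999  # bp of CDS per gene, multiple of 3

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0 <= self.coding_fraction <= 1):
            raise ValueError("coding fraction must be in [0, 1]")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance h must be in [0, 1]")
        if self.s_deleterious > 0:
            raise ValueError("deleterious selection coefficient must be <= 0")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")


@dataclass
class RecombinationModel:
    rate: float = 2.0e-7  # crossovers per bp per generation
    length: int = 5_000_000  # chromosome length, bp

    def __post_init__(self) -> None:
        if self.rate < 0 or self.length <= 0:
            raise ValueError("recombination rate >= 0 and length > 0 required")


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    samples: SampleTable
    annotation: CodingAnnotation
    conservation: pd.DataFrame  # BED frame: chrom, start, end, score
    outgroup_table: pd.DataFrame  # chrom, pos, base
    outgroup_fasta: dict[str, str]
    reference: dict[str, str]
    truth: pd.DataFrame
    size_history: pd.DataFrame
    seed: int
    chrom: str = "chr1"


# ---------------------------------------------------------------------------
# coding layout and fast codon classification

class _CodingLayout:
    """Evenly spaced single-exon genes (ATG + sense codons + stop) with
    per-position codon lookup tables for fast mutation classification."""

    def __init__(self, length: int, mutation: MutationModel, rng: np.random.Generator):
        self.length = length
        L = length
        gl = mutation.gene_length
        n_genes = int(round(mutation.coding_fraction * L / gl)) if mutation.coding_fraction > 0 else 0
        if n_genes * gl > L:
            n_genes = L // gl
        self.seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        # per-position maps (index 0 unused; positions are 1-based)
        self.first_gpos = np.zeros(L + 2, dtype=np.int64)
        self.step = np.zeros(L + 2, dtype=np.int8)
        self.offset = np.zeros(L + 2, dtype=np.int8)
        self.is_coding = np.zeros(L + 2, dtype=bool)
        self.is_start_codon = np.zeros(L + 2, dtype=bool)
        self.strand_minus = np.zeros(L + 2, dtype=bool)

        sense = [c for c in GENETIC_CODE if c not in STOP_CODONS]
        sense_codes = np.array([[_CODE[ord(x)] for x in c] for c in sense], dtype=np.uint8)
        stops = sorted(STOP_CODONS)
        stop_codes = np.array([[_CODE[ord(x)] for x in c] for c in stops], dtype=np.uint8)
        atg = np.array([_CODE[ord(x)] for x in "ATG"], dtype=np.uint8)

        transcripts = []
        spacing = L / n_genes if n_genes else 0
        for g in range(n_genes):
            start = int(g * spacing + (spacing - gl) / 2) + 1  # 1-based
            start = max(1, min(start, L - gl + 1))
            end = start + gl - 1
            strand = "+" if g % 2 == 0 else "-"
            n_codons = gl // 3
            body = sense_codes[rng.integers(0, len(sense_codes), size=n_codons - 2)]
            codons = np.vstack([atg[None, :], body,
                                stop_codes[rng.integers(0, len(stop_codes))][None, :]])
            tx_seq = codons.reshape(-1)  # transcript orientation, 0..3 codes
            if strand == "+":
                self.seq[start - 1 : end] = tx_seq
                gpos = np.arange(start, end + 1, dtype=np.int64)
            else:
                self.seq[start - 1 : end] = _COMP[tx_seq[::-1]]
                gpos = np.arange(end, start - 1, -1, dtype=np.int64)
            tpos = np.arange(gl)
            codon_idx = tpos // 3
            first = gpos[codon_idx * 3]
            self.first_gpos[gpos] = first
            self.step[gpos] = 1 if strand == "+" else -1
            self.offset[gpos] = (tpos % 3).astype(np.int8)
            self.is_coding[gpos] = True
            self.is_start_codon[gpos] = codon_idx == 0
            self.strand_minus[gpos] = strand == "-"
            transcripts.append(
                Transcript(
                    transcript_id=f"gene{g + 1:04d}",
                    chrom="chr1",
                    strand=strand,
                    intervals=[(start, end)],
                    frame=0,
                )
            )
        self.annotation = CodingAnnotation(transcripts)
        self.n_genes = n_genes

    def classify(self, pos: int, alt_code: int) -> int:
        """Effect-class code for a mutation at 1-based ``pos`` to ``alt_code``."""
        if not self.is_coding[pos]:
            return NONCODING_C
        g0 = self.first_gpos[pos]
        step = int(self.step[pos])
        off = int(self.offset[pos])
        idxs = np.array([g0, g0 + step, g0 + 2 * step], dtype=np.int64) - 1
        codon = self.seq[idxs]
        alt = np.uint8(alt_code)
        if self.strand_minus[pos]:
            codon = _COMP[codon]
            alt = _COMP[alt]
        ref_codon = "".join("ACGT"[c] for c in codon)
        alt_arr = codon.copy()
        alt_arr[off] = alt
        alt_codon = "".join("ACGT"[c] for c in alt_arr)
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        if self.is_start_codon[pos] and ref_codon == "ATG" and alt_codon != "ATG":
            return START_LOST_C
        if aa_ref != "*" and aa_alt == "*":
            return STOP_GAINED_C
        if aa_ref == "*" and aa_alt != "*":
            return STOP_LOST_C
        if aa_ref == aa_alt:
            return SYN_C
        return NONSYN_C


# ---------------------------------------------------------------------------
# simulator core

class _Population:
    """Segregating-site state shared across demes.

    ``H[deme]`` is a (2N_deme, S) uint8 derived-allele indicator matrix over
    a global, position-sorted site registry.
    """

    def __init__(self, layout: _CodingLayout, mutation: MutationModel,
                 recomb: RecombinationModel, rng: np.random.Generator):
        self.layout = layout
        self.mutation = mutation
        self.recomb = recomb
        self.rng = rng
        self.pos = np.zeros(0, dtype=np.int64)
        self.alt = np.zeros(0, dtype=np.uint8)
        self.s = np.zeros(0, dtype=np.float64)
        self.eclass = np.zeros(0, dtype=np.int8)
        self.H: dict[str, np.ndarray] = {}
        self.fixed: list[tuple[int, int, float, int]] = []  # pos, alt, s, class
        self.fixed_pos: set[int] = set()
        self.mu_genome = mutation.mu * recomb.length
        self._log_het = np.log1p(mutation.h * mutation.s_deleterious)
        self._log_hom = np.log1p(2.0 * mutation.s_deleterious)

    # -- one generation of one deme ----------------------------------------
    def step_deme(self, name: str, n_next: int) -> None:
        H = self.H[name]
        new_H = self._reproduce(H, n_next)
        self.H[name] = new_H
        self._mutate(name, n_next)

    def found_deme(self, source: str, name: str, size: int) -> None:
        """Found a new deme by a Wright–Fisher draw from the source pool."""
        self.H[name] = self._reproduce(self.H[source], size)
        self._mutate(name, size)

    def _reproduce(self, H: np.ndarray, n_next: int) -> np.ndarray:
        rng = self.rng
        n_par = H.shape[0] // 2
        S = H.shape[1]
        sel = np.flatnonzero(self.s < 0)
        if sel.size:
            G = H[0::2][:, sel].astype(np.int16) + H[1::2][:, sel]
            logw = (G == 1).sum(axis=1) * self._log_het + (G == 2).sum(axis=1) * self._log_hom
            w = np.exp(logw - logw.max())
            p = w / w.sum()
            parents = rng.choice(n_par, size=(n_next, 2), p=p)
        else:
            parents = rng.integers(0, n_par, size=(n_next, 2))
        new_H = np.empty((2 * n_next, S), dtype=np.uint8)
        lam = self.recomb.rate * self.recomb.length
        pos = self.pos
        starts = rng.integers(2, size=2 * n_next)
        n_cx = rng.poisson(lam, size=2 * n_next)
        for g in range(2 * n_next):
            par = parents[g // 2, g % 2]
            hA = H[2 * par]
            hB = H[2 * par + 1]
            if starts[g]:
                hA, hB = hB, hA
            row = new_H[g]
            row[:] = hA
            ncx = int(n_cx[g])
            if ncx == 0 or S == 0:
                continue
            bps = np.sort(rng.integers(1, self.recomb.length + 1, size=ncx))
            cuts = np.searchsorted(pos, bps, side="right")
            # copy the segments carried by the other haplotype (odd parity)
            for k in range(0, ncx, 2):
                a = cuts[k]
                b = cuts[k + 1] if k + 1 < ncx else S
                row[a:b] = hB[a:b]
        return new_H

    def _mutate(self, name: str, n_ind: int) -> None:
        rng = self.rng
        n_hap = 2 * n_ind
        n_mut = int(rng.poisson(n_hap * self.mu_genome))
        if n_mut == 0:
            return
        raw_pos = rng.integers(1, self.recomb.length + 1, size=n_mut)
        hap_idx = rng.integers(0, n_hap, size=n_mut)
        # infinite sites: skip collisions with active or duplicate positions
        order = np.argsort(raw_pos, kind="stable")
        raw_pos = raw_pos[order]
        hap_idx = hap_idx[order]
        keep = np.ones(n_mut, dtype=bool)
        keep[1:] &= raw_pos[1:] != raw_pos[:-1]
        ins = np.searchsorted(self.pos, raw_pos)
        if self.pos.size:
            exists = (ins < self.pos.size) & (
                self.pos[np.minimum(ins, self.pos.size - 1)] == raw_pos
            )
            keep &= ~exists
        if self.fixed_pos:
            keep &= np.array([int(p) not in self.fixed_pos for p in raw_pos])
        raw_pos = raw_pos[keep]
        hap_idx = hap_idx[keep]
        ins = ins[keep]
        m = raw_pos.size
        if m == 0:
            return
        anc = self.layout.seq[raw_pos - 1]
        shift = rng.integers(1, 4, size=m).astype(np.uint8)
        alt_codes = (anc + shift) % 4
        classes = np.array([self.layout.classify(int(p), int(a))
                            for p, a in zip(raw_pos, alt_codes)], dtype=np.int8)
        s_vals = np.zeros(m)
        selected = np.isin(classes, _SELECTED_CLASSES)
        if selected.any() and self.mutation.s_deleterious < 0:
            hit = rng.random(m) < self.mutation.fraction_deleterious
            s_vals[selected & hit] = self.mutation.s_deleterious
        # splice registry columns
        self.pos = np.insert(self.pos, ins, raw_pos)
        self.alt = np.insert(self.alt, ins, alt_codes)
        self.s = np.insert(self.s, ins, s_vals)
        self.eclass = np.insert(self.eclass, ins, classes)
        for deme, H in self.H.items():
            block = np.zeros((H.shape[0], m), dtype=np.uint8)
            if deme == name:
                block[hap_idx, np.arange(m)] = 1
            self.H[deme] = np.insert(H, ins, block, axis=1)

    def prune(self) -> None:
        if self.pos.size == 0:
            return
        total = np.zeros(self.pos.size, dtype=np.int64)
        n_hap_all = 0
        for H in self.H.values():
            total += H.sum(axis=0, dtype=np.int64)
            n_hap_all += H.shape[0]
        lost = total == 0
        fixed = total == n_hap_all
        if fixed.any():
            for j in np.flatnonzero(fixed):
                self.fixed.append((int(self.pos[j]), int(self.alt[j]),
                                   float(self.s[j]), int(self.eclass[j])))
                self.fixed_pos.add(int(self.pos[j]))
        drop = lost | fixed
        if drop.any():
            keep = ~drop
            self.pos = self.pos[keep]
            self.alt = self.alt[keep]
            self.s = self.s[keep]
            self.eclass = self.eclass[keep]
            for deme in self.H:
                self.H[deme] = self.H[deme][:, keep]


def simulate_cohort(
    demography: DemographyModel,
    mutation: MutationModel,
    recomb: RecombinationModel,
    seed: int,
    p_hit: float = 0.9,
    p_false: float = 0.02,
    chrom: str = "chr1",
) -> SimulatedCohort:
    """Run the forward simulation and assemble the full input bundle."""
    for d in demography.demes:
        if d.n_samples > d.size:
            raise ValueError(
                f"deme {d.name}: {d.n_samples} samples exceed deme size {d.size}"
            )
    rng = np.random.default_rng(seed)
    layout = _CodingLayout(recomb.length, mutation, rng)
    popstate = _Population(layout, mutation, recomb, rng)

    trunk = demography.demes[0]
    sizes: list[dict] = []

    # burn-in at ancestral size
    popstate.H["__anc__"] = np.zeros((2 * demography.n_anc, 0), dtype=np.uint8)
    burnin = demography.burnin_generations
    for g in range(burnin):
        popstate.step_deme("__anc__", demography.n_anc)
        popstate.prune()
    popstate.H[trunk.name] = popstate.H.pop("__anc__")

    size_by_name = {d.name: d.size for d in demography.demes}
    t_max = max((d.split_time for d in demography.demes[1:]), default=0)
    pending = sorted(demography.demes[1:], key=lambda d: -d.split_time)
    for t in range(t_max, 0, -1):
        # demes splitting now are founded from the trunk's pre-step pool;
        # the founding draw is their generation step for this tick
        founded_now: set[str] = set()
        while pending and pending[0].split_time == t:
            d = pending.pop(0)
            popstate.found_deme(trunk.name, d.name, d.size)
            founded_now.add(d.name)
        for name in list(popstate.H):
            if name not in founded_now:
                popstate.step_deme(name, size_by_name[name])
        popstate.prune()
        sizes.append({"generation_bp": t - 1,
                      **{name: size_by_name[name] for name in popstate.H}})
    if t_max == 0:
        sizes.append({"generation_bp": 0, trunk.name: trunk.size})

    return _assemble(demography, mutation, recomb, popstate, layout, rng, seed,
                     p_hit, p_false, chrom, pd.DataFrame(sizes))


def _assemble(demography, mutation, recomb, popstate, layout, rng, seed,
              p_hit, p_false, chrom, size_history) -> SimulatedCohort:
    L = recomb.length
    sample_names: list[str] = []
    rows_geno: list[np.ndarray] = []
    table_rows = []
    for d in demography.demes:
        H = popstate.H[d.name]
        n = H.shape[0] // 2
        chosen = np.sort(rng.choice(n, size=d.n_samples, replace=False))
        for k, ind in enumerate(chosen):
            name = f"{d.name}_{k + 1:02d}"
            sample_names.append(name)
            rows_geno.append(H[2 * ind] + H[2 * ind + 1])
            table_rows.append({"sample": name, "population": d.name,
                               "life_history": d.life_history, "outgroup": False,
                               "callable_sites": L})
    table_rows.append({"sample": "outgroup", "population": "outgroup",
                       "life_history": "outgroup", "outgroup": True,
                       "callable_sites": L})

    geno = (np.stack(rows_geno, axis=0) if rows_geno
            else np.zeros((0, popstate.pos.size), dtype=np.uint8))
    # segregating-in-samples sites plus globally fixed derived sites
    counts = geno.sum(axis=0)
    keep = counts > 0
    pos = popstate.pos[keep]
    alt = popstate.alt[keep]
    s_coef = popstate.s[keep]
    eclass = popstate.eclass[keep]
    geno = geno[:, keep].astype(np.int8)

    if popstate.fixed:
        fpos = np.array([f[0] for f in popstate.fixed], dtype=np.int64)
        falt = np.array([f[1] for f in popstate.fixed], dtype=np.uint8)
        fs = np.array([f[2] for f in popstate.fixed])
        fcl = np.array([f[3] for f in popstate.fixed], dtype=np.int8)
        pos = np.concatenate([pos, fpos])
        alt = np.concatenate([alt, falt])
        s_coef = np.concatenate([s_coef, fs])
        eclass = np.concatenate([eclass, fcl])
        geno = np.concatenate(
            [geno, np.full((geno.shape[0], fpos.size), 2, dtype=np.int8)], axis=1
        )
    order = np.argsort(pos, kind="stable")
    pos, alt, s_coef, eclass = pos[order], alt[order], s_coef[order], eclass[order]
    geno = geno[:, order]

    ref_bases = np.array(["ACGT"[c] for c in layout.seq[pos - 1]]) if pos.size else np.array([], dtype=object)
    alt_bases = np.array(["ACGT"[c] for c in alt]) if pos.size else np.array([], dtype=object)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref_bases, "alt": alt_bases})

    matrix = GenotypeMatrix(
        samples=sample_names,
        sites=sites,
        genotypes=geno,
        callable_sites=np.full(len(sample_names), L, dtype=np.int64),
    )
    samples = SampleTable(pd.DataFrame(table_rows))

    # conservation scores at variant positions (threshold behaviour only)
    deleterious = s_coef < 0
    hit = np.where(deleterious, rng.random(pos.size) < p_hit, rng.random(pos.size) < p_false)
    scores = np.where(hit, rng.uniform(4.01, 6.0, size=pos.size),
                      rng.uniform(-2.0, 4.0, size=pos.size))
    conservation = pd.DataFrame({"chrom": chrom, "start": pos - 1, "end": pos,
                                 "score": np.round(scores, 4)})

    # outgroup: ancestral sequence plus drift along the outgroup branch
    og_seq = layout.seq.copy()
    n_og = int(rng.poisson(mutation.mu * L * demography.outgroup_divergence))
    if n_og:
        og_pos = rng.integers(1, L + 1, size=n_og)
        og_shift = rng.integers(1, 4, size=n_og).astype(np.uint8)
        og_seq[og_pos - 1] = (og_seq[og_pos - 1] + og_shift) % 4
    og_string = "".join("ACGT"[c] for c in og_seq)
    outgroup_table = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "base": ["ACGT"[og_seq[p - 1]] for p in pos],
    })

    truth = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": ref_bases, "alt": alt_bases,
        "effect_class": [_CLASS_NAMES[int(c)] for c in eclass],
        "s": s_coef,
        "ancestral": ref_bases,  # reference is the ancestral sequence
    })

    reference = {chrom: "".join("ACGT"[c] for c in layout.seq)}
    return SimulatedCohort(
        matrix=matrix, samples=samples, annotation=layout.annotation,
        conservation=conservation, outgroup_table=outgroup_table,
        outgroup_fasta={chrom: og_string}, reference=reference, truth=truth,
        size_history=size_history, seed=seed, chrom=chrom,
    )


# ---------------------------------------------------------------------------
# unlinked-loci neutral mode (diffusion calibration)

def simulate_unlinked_loci(n_diploid: int, n_loci: int, theta: float, seed: int,
                           n_generations: int | None = None) -> np.ndarray:
    """Neutral infinite-alleles Wright–Fisher at unlinked loci.

    Each locus mutates at μ = θ/(4N) to a brand-new allele; loci segregate
    independently. Returns the per-individual heterozygosity (fraction of
    loci with two distinct alleles), whose diffusion equilibrium expectation
    is θ/(1+θ).
    """
    rng = np.random.default_rng(seed)
    N, L = n_diploid, n_loci
    gens = n_generations if n_generations is not None else 8 * N
    mu = theta / (4.0 * N)
    A = np.zeros((2 * N, L), dtype=np.int64)
    counter = 1
    cols = np.arange(L)
    for _ in range(gens):
        parent = rng.integers(0, N, size=2 * N)
        which = rng.integers(0, 2, size=(2 * N, L))
        A = A[(2 * parent)[:, None] + which, cols[None, :]]
        mut = rng.random((2 * N, L)) < mu
        k = int(mut.sum())
        if k:
            A[mut] = np.arange(counter, counter + k)
            counter += k
    return (A[0::2] != A[1::2]).mean(axis=1)


# ---------------------------------------------------------------------------
# bundle emission

def emit_bundle(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write the cohort in the exact dialects io_formats reads."""
    from pathlib import Path

    from . import io_formats

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e

    contigs = {cohort.chrom: len(cohort.reference[cohort.chrom])}
    paths = {
        "vcf": str(out / "cohort.vcf"),
        "samples": str(out / "samples.tsv"),
        "annotation": str(out / "annotation.gff3"),
        "conservation": str(out / "conservation.bed"),
        "outgroup": str(out / "outgroup_alleles.tsv"),
        "outgroup_fasta": str(out / "outgroup.fa"),
        "reference": str(out / "reference.fa"),
        "truth": str(out / "truth.tsv"),
        "size_history": str(out / "size_history.tsv"),
    }
    io_formats.write_vcf(cohort.matrix, paths["vcf"], contigs=contigs)
    io_formats.write_sample_table(cohort.samples, paths["samples"])
    io_formats.write_annotation(cohort.annotation, paths["annotation"])
    io_formats.write_conservation(cohort.conservation, paths["conservation"])
    io_formats.write_outgroup_table(cohort.outgroup_table, paths["outgroup"])
    io_formats.write_fasta(cohort.outgroup_fasta, paths["outgroup_fasta"])
    io_formats.write_fasta(cohort.reference, paths["reference"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.size_history.to_csv(paths["size_history"], sep="\t", index=False)
    return paths
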