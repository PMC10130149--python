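"""Functional classification of SNVs, Nei–Gojobori site counts, per-genome
dN/dS diversity ratios, conservation-based deleterious calls, outgroup
polarization, and zygosity partitioning of the carried load.

Effect classes: synonymous, nonsynonymous-missense, LoF (stop_gained,
stop_lost, start_lost, splice_donor, splice_acceptor), noncoding. When a
variant hits multiple transcripts the most severe effect wins
(LoF > nonsynonymous > synonymous). The deleterious category is
conservation score strictly greater than the threshold (default GERP > 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon import START_CODON, complement, synonymous_fraction, translate_codon
from .model import MISSING, CodingAnnotation, GenotypeMatrix, SampleTable, Transcript, warn

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous-missense"
LOF = "LoF"
NONCODING = "noncoding"

LOF_SUBTYPES = ("stop_gained", "stop_lost", "start_lost", "splice_donor", "splice_acceptor")
_SEVERITY = {LOF: 3, NONSYNONYMOUS: 2, SYNONYMOUS: 1, NONCODING: 0}

#: LoF subtypes that are codon changes and therefore enter the dN numerator
_CODING_LOF = {"stop_gained", "stop_lost", "start_lost"}

GERP_DELETERIOUS_THRESHOLD = 4.0  # strict ">"


@dataclass
class SiteCounts:
    syn_sites: float
    nonsyn_sites: float
    n_codons: int
    skipped_codons: int = 0


@dataclass
class EffectRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    lof_subtype: str | None
    transcript: str | None


# ---------------------------------------------------------------------------
# Site counting

def count_sites(annotation: CodingAnnotation, refseqs: dict[str, str]) -> SiteCounts:
    """Genome-wide Nei–Gojobori synonymous/nonsynonymous site counts.

    Per codon each position contributes f/3 synonymous sites (f = number of
    the three single-base changes preserving the amino acid); stop codons
    are excluded and ambiguous codons skipped with a log note.
    """
    syn = 0.0
    nonsyn = 0.0
    n_codons = 0
    skipped = 0
    for t in annotation.transcripts:
        seq = _transcript_sequence(t, refseqs)
        usable = len(seq) - t.frame
        if usable % 3 != 0:
            raise ValueError(
                f"transcript {t.transcript_id}: coding length {usable} not divisible by 3"
            )
        for k in range(t.frame, len(seq), 3):
            codon = seq[k : k + 3]
            aa = translate_codon(codon)
            if aa == "*":
                continue
            if aa == "X":
                skipped += 1
                continue
            s, ns = synonymous_fraction(codon)
            syn += s
            nonsyn += ns
            n_codons += 1
    if skipped:
        log.info("count_sites: skipped %d ambiguous codons", skipped)
    return SiteCounts(syn_sites=syn, nonsyn_sites=nonsyn, n_codons=n_codons,
                      skipped_codons=skipped)


def _transcript_sequence(t: Transcript, refseqs: dict[str, str]) -> str:
    seq = refseqs[t.chrom]
    chunks = []
    for a, b in t.intervals:
        sub = seq[a - 1 : b]
        if t.strand == "-":
            sub = "".join(complement(c) for c in reversed(sub))
        chunks.append(sub)
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Variant classification

class _TranscriptIndex:
    """Per-transcript lookup: genomic position -> transcript coordinate."""

    def __init__(self, t: Transcript):
        self.t = t
        self.positions = t.genomic_positions()
        self.pos_to_tpos = {int(g): k for k, g in enumerate(self.positions)}
        self.splice: dict[int, str] = {}
        iv = t.intervals
        for k in range(len(iv) - 1):
            if t.strand == "+":
                donor_start = iv[k][1] + 1
                acceptor_end = iv[k + 1][0] - 1
                self.splice[donor_start] = "splice_donor"
                self.splice[donor_start + 1] = "splice_donor"
                self.splice[acceptor_end - 1] = "splice_acceptor"
                self.splice[acceptor_end] = "splice_acceptor"
            else:
                donor_start = iv[k][0] - 1
                acceptor_end = iv[k + 1][1] + 1
                self.splice[donor_start] = "splice_donor"
                self.splice[donor_start - 1] = "splice_donor"
                self.splice[acceptor_end + 1] = "splice_acceptor"
                self.splice[acceptor_end] = "splice_acceptor"


class EffectClassifier:
    """Classifies biallelic SNVs against a coding annotation and reference."""

    def __init__(self, annotation: CodingAnnotation, refseqs: dict[str, str]):
        self.refseqs = refseqs
        self.by_chrom: dict[str, list[_TranscriptIndex]] = {}
        for t in annotation.transcripts:
            self.by_chrom.setdefault(t.chrom, []).append(_TranscriptIndex(t))

    def classify(self, chrom: str, pos: int, ref: str, alt: str) -> EffectRecord:
        best: EffectRecord | None = None
        for idx in self.by_chrom.get(chrom, []):
            rec = self._classify_one(idx, chrom, pos, ref, alt)
            if rec is None:
                continue
            if best is None or _SEVERITY[rec.effect] > _SEVERITY[best.effect]:
                best = rec
        if best is None:
            return EffectRecord(chrom, pos, ref, alt, NONCODING, None, None)
        return best

    def _classify_one(self, idx: _TranscriptIndex, chrom, pos, ref, alt) -> EffectRecord | None:
        t = idx.t
        sub = idx.splice.get(pos)
        if sub is not None:
            return EffectRecord(chrom, pos, ref, alt, LOF, sub, t.transcript_id)
        tpos = idx.pos_to_tpos.get(pos)
        if tpos is None:
            return None
        if tpos < t.frame:
            raise ValueError(
                f"variant {chrom}:{pos} in transcript {t.transcript_id} before frame anchor"
            )
        codon_idx = (tpos - t.frame) // 3
        cstart = t.frame + 3 * codon_idx
        codon_pos = tpos - cstart
        seq = self.refseqs[chrom]
        bases = []
        for k in range(3):
            g = int(idx.positions[cstart + k])
            b = seq[g - 1]
            bases.append(complement(b) if t.strand == "-" else b)
        ref_codon = "".join(bases)
        ref_t = complement(ref) if t.strand == "-" else ref
        alt_t = complement(alt) if t.strand == "-" else alt
        if ref_codon[codon_pos] != ref_t:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos} in {t.transcript_id}: "
                f"annotation codon has {ref_codon[codon_pos]}, VCF ref is {ref_t}"
            )
        alt_codon = ref_codon[:codon_pos] + alt_t + ref_codon[codon_pos + 1 :]
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        if codon_idx == 0 and ref_codon == START_CODON and alt_codon != START_CODON:
            return EffectRecord(chrom, pos, ref, alt, LOF, "start_lost", t.transcript_id)
        if aa_ref != "*" and aa_alt == "*":
            return EffectRecord(chrom, pos, ref, alt, LOF, "stop_gained", t.transcript_id)
        if aa_ref == "*" and aa_alt != "*":
            return EffectRecord(chrom, pos, ref, alt, LOF, "stop_lost", t.transcript_id)
        if aa_ref == aa_alt:
            return EffectRecord(chrom, pos, ref, alt, SYNONYMOUS, None, t.transcript_id)
        return EffectRecord(chrom, pos, ref, alt, NONSYNONYMOUS, None, t.transcript_id)


def classify_variant(chrom, pos, ref, alt, annotation: CodingAnnotation,
                     refseqs: dict[str, str]) -> EffectRecord:
    return EffectClassifier(annotation, refseqs).classify(chrom, pos, ref, alt)


def classify_sites(sites: pd.DataFrame, annotation: CodingAnnotation,
                   refseqs: dict[str, str]) -> pd.DataFrame:
    """Effect table for every site: columns effect, lof_subtype, transcript."""
    clf = EffectClassifier(annotation, refseqs)
    recs = [clf.classify(str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"])]
    return pd.DataFrame({
        "effect": [r.effect for r in recs],
        "lof_subtype": [r.lof_subtype for r in recs],
        "transcript": [r.transcript for r in recs],
    })


# ---------------------------------------------------------------------------
# Polarization

def polarize(ref: str, alt: str, outgroup_base: str | None) -> str | None:
    """'alt' if alt is derived, 'ref' if ref is derived, None if unpolarizable."""
    if outgroup_base is None:
        return None
    if outgroup_base == ref:
        return "alt"
    if outgroup_base == alt:
        return "ref"
    return None


def polarize_sites(sites: pd.DataFrame, outgroup) -> pd.Series:
    out = []
    for chrom, pos, ref, alt in zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"]):
        out.append(polarize(str(ref), str(alt), outgroup.base_at(str(chrom), int(pos))))
    return pd.Series(out, index=sites.index, dtype=object)


# ---------------------------------------------------------------------------
# Per-genome load profiles

def _derived_dosage(g: np.ndarray, derived: pd.Series | None) -> np.ndarray:
    """Recode alt-dosage genotypes to derived-allele dosage. Unpolarizable
    sites fall back to alt dosage (the 'hom-alt = homozygous' rule)."""
    dd = g.astype(np.int8).copy()
    if derived is not None:
        flip = (derived == "ref").to_numpy()
        obs = dd != MISSING
        dd[flip & obs] = 2 - dd[flip & obs]
    return dd


def dn_ds_profile(matrix: GenotypeMatrix, effects: pd.DataFrame, site_counts: SiteCounts,
                  sample: str, weighting: str = "presence") -> dict:
    """Per-genome nonsynonymous/synonymous diversity ratio.

    A variant is carried when the genotype is het or hom-alt. With
    weighting='presence' a carried variant counts once; with
    weighting='allele-count' a het counts 1/2 and a hom-alt 1.
    dN = nSNV / nonsynonymous sites, dS = sSNV / synonymous sites; the
    ratio is undefined (NaN, warned) when no synonymous SNVs are carried.
    Coding-codon LoF changes (stop/start) enter the nonsynonymous numerator.
    """
    if site_counts.syn_sites <= 0 or site_counts.nonsyn_sites <= 0:
        raise ValueError("site counts must be positive for both classes")
    i = matrix.sample_index(sample)
    g = matrix.genotypes[i]
    if weighting == "presence":
        weightvec = (g >= 1).astype(float)
    elif weighting == "allele-count":
        weightvec = np.where(g >= 1, g / 2.0, 0.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    eff = effects["effect"].to_numpy()
    sub = effects["lof_subtype"].to_numpy()
    is_nonsyn = (eff == NONSYNONYMOUS) | ((eff == LOF) & np.isin(sub, list(_CODING_LOF)))
    is_syn = eff == SYNONYMOUS
    n_snv = float(weightvec[is_nonsyn].sum())
    s_snv = float(weightvec[is_syn].sum())
    dn = n_snv / site_counts.nonsyn_sites
    ds = s_snv / site_counts.syn_sites
    if s_snv == 0:
        warn(f"sample {sample!r} carries no synonymous SNVs; dN/dS undefined")
        ratio = float("nan")
    else:
        ratio = dn / ds
    return {"sample": sample, "n_snv": n_snv, "s_snv": s_snv, "dn": dn, "ds": ds,
            "dnds": ratio}


def zygosity_partition(matrix: GenotypeMatrix, sample: str, category_mask: np.ndarray,
                       derived: pd.Series | None = None) -> dict:
    """Homozygous/heterozygous partition of the carried variants in a category.

    Where polarizable, 'homozygous' means both copies derived; otherwise
    hom-alt stands in. Fraction = hom / (hom + het); NaN with a warning when
    the category is empty for the sample.
    """
    i = matrix.sample_index(sample)
    dd = _derived_dosage(matrix.genotypes[i], derived)
    m = np.asarray(category_mask, dtype=bool)
    hom = int(((dd == 2) & m).sum())
    het = int(((dd == 1) & m).sum())
    if hom + het == 0:
        warn(f"sample {sample!r}: empty category; homozygous fraction undefined")
        frac = float("nan")
    else:
        frac = hom / (hom + het)
    return {"sample": sample, "hom": hom, "het": het, "fraction": frac}


def category_masks(effects: pd.DataFrame, conservation_scores: np.ndarray | None,
                   gerp_threshold: float = GERP_DELETERIOUS_THRESHOLD) -> dict[str, np.ndarray]:
    """Variant-category masks: nonsynonymous, deleterious (score strictly
    above threshold), LoF. Deleterious is absent when no scores are given."""
    eff = effects["effect"].to_numpy()
    masks = {
        "nonsynonymous": (eff == NONSYNONYMOUS)
        | ((eff == LOF) & np.isin(effects["lof_subtype"].to_numpy(), list(_CODING_LOF))),
        "LoF": eff == LOF,
    }
    if conservation_scores is not None:
        s = np.asarray(conservation_scores, dtype=float)
        masks["deleterious"] = np.where(np.isnan(s), False, s > gerp_threshold)
    return masks


def load_profiles(matrix: GenotypeMatrix, effects: pd.DataFrame, site_counts: SiteCounts,
                  samples: SampleTable, conservation_scores: np.ndarray | None = None,
                  derived: pd.Series | None = None, weighting: str = "presence",
                  gerp_threshold: float = GERP_DELETERIOUS_THRESHOLD) -> pd.DataFrame:
    """Per-sample load table: dN/dS fields plus hom/het partitions per category."""
    masks = category_masks(effects, conservation_scores, gerp_threshold)
    rows = []
    for s in samples.non_outgroup_samples():
        if s not in matrix.samples:
            continue
        row = dn_ds_profile(matrix, effects, site_counts, s, weighting=weighting)
        row["population"] = samples.population_of(s)
        for cat, mask in masks.items():
            part = zygosity_partition(matrix, s, mask, derived=derived)
            row[f"{cat}_hom"] = part["hom"]
            row[f"{cat}_het"] = part["het"]
            row[f"{cat}_hom_fraction"] = part["fraction"]
            row[f"{cat}_carried"] = part["hom"] + part["het"]
        rows.append(row)
    return pd.DataFrame(rows)
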