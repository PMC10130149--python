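"""Mutational load: Nei–Gojobori site counting, effect classification,
polarization, dN/dS profiles, and zygosity partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from driftprint.codon import BASES, GENETIC_CODE, STOP_CODONS, synonymous_fraction
from driftprint.load import (
    EffectClassifier,
    SiteCounts,
    category_masks,
    classify_variant,
    count_sites,
    dn_ds_profile,
    polarize,
    zygosity_partition,
)
from driftprint.model import CodingAnnotation, Transcript

from conftest import make_matrix


def single_gene(seq_body, chrom="chr1", strand="+", start=1, tid="t1"):
    """Annotation + reference for one contiguous CDS embedded in padding."""
    pad = "T" * (start - 1)
    ref = {chrom: pad + seq_body + "TTTT"}
    ann = CodingAnnotation([
        Transcript(tid, chrom, strand,
                   [(start, start + len(seq_body) - 1)], frame=0)
    ])
    return ann, ref


class TestCountSites:
    def test_atg_is_fully_nonsynonymous(self):
        s, ns = synonymous_fraction("ATG")
        assert s == 0 and ns == 3

    def test_ttt_has_one_third_synonymous(self):
        s, ns = synonymous_fraction("TTT")
        assert s == pytest.approx(1 / 3)
        assert ns == pytest.approx(8 / 3)

    def test_all_sense_codons_sum_to_three_and_match_enumeration(self):
        # independent oracle: enumerate the 9 single-base changes per codon
        # with Biopython's translation
        for codon in GENETIC_CODE:
            if codon in STOP_CODONS:
                continue
            aa = str(Seq(codon).translate())
            syn = 0
            for i, b in itertools.product(range(3), BASES):
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1:]
                if alt not in STOP_CODONS and str(Seq(alt).translate()) == aa:
                    syn += 1
            s, ns = synonymous_fraction(codon)
            assert s + ns == pytest.approx(3.0)
            assert s == pytest.approx(syn / 3)

    def test_gene_counts_exclude_stop_codon(self):
        ann, ref = single_gene("ATG" + "TTT" + "TAA")
        out = count_sites(ann, ref)
        assert out.n_codons == 2  # ATG + TTT; TAA excluded
        assert out.syn_sites == pytest.approx(1 / 3)
        assert out.nonsyn_sites == pytest.approx(3 + 8 / 3)

    def test_frame_violation_is_hard_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            Transcript("bad", "chr1", "+", [(1, 5)], frame=0)


class TestClassifyVariant:
    def test_synonymous_third_position(self):
        ann, ref = single_gene("ATG" + "GAA" + "TAA")  # Glu codon at 4-6
        rec = classify_variant("chr1", 6, "A", "G", ann, ref)  # GAA->GAG
        assert rec.effect == "synonymous"

    def test_stop_gained(self):
        ann, ref = single_gene("ATG" + "TAC" + "TAA")  # Tyr codon
        rec = classify_variant("chr1", 6, "C", "A", ann, ref)  # TAC->TAA
        assert rec.effect == "LoF"
        assert rec.lof_subtype == "stop_gained"

    def test_start_lost(self):
        ann, ref = single_gene("ATG" + "GAA" + "TAA")
        rec = classify_variant("chr1", 1, "A", "C", ann, ref)
        assert rec.lof_subtype == "start_lost"

    def test_stop_lost(self):
        ann, ref = single_gene("ATG" + "GAA" + "TAA")
        rec = classify_variant("chr1", 8, "A", "C", ann, ref)  # TAA->TCA (Ser)
        assert rec.lof_subtype == "stop_lost"

    def test_noncoding_outside_features(self):
        ann, ref = single_gene("ATG" + "GAA" + "TAA")
        assert classify_variant("chr1", 12, "T", "A", ann, ref).effect == "noncoding"

    def test_minus_strand_uses_reverse_complement(self):
        # transcript 'ATG GAA TAA' on minus strand: genomic = revcomp
        body = str(Seq("ATGGAATAA").reverse_complement())
        ref = {"chr1": body + "TT"}
        ann = CodingAnnotation([Transcript("t1", "chr1", "-", [(1, 9)], frame=0)])
        # genomic position 4 is codon 2 position 3 (transcript coordinate)
        g_ref = ref["chr1"][3]
        # transcript change GAA->GAG: transcript base A->G at tpos 6 => genomic pos 9-6=3+1
        rec = classify_variant("chr1", 4, g_ref, str(Seq("G").complement()), ann, ref)
        assert rec.effect == "synonymous"

    def test_splice_dinucleotides(self):
        # two exons with a 10 bp intron: positions 1-6 and 17-22
        seq = "ATGGA" + "A" + "GTXXXXXXAG".replace("X", "C") + "GAATAA"
        ref = {"chr1": seq}
        ann = CodingAnnotation([Transcript("t1", "chr1", "+", [(1, 6), (17, 22)], frame=0)])
        assert classify_variant("chr1", 7, "G", "A", ann, ref).lof_subtype == "splice_donor"
        assert classify_variant("chr1", 8, "T", "A", ann, ref).lof_subtype == "splice_donor"
        assert classify_variant("chr1", 15, "A", "T", ann, ref).lof_subtype == "splice_acceptor"
        assert classify_variant("chr1", 16, "G", "T", ann, ref).lof_subtype == "splice_acceptor"

    def test_random_coding_snvs_match_retranslation_oracle(self):
        rng = np.random.default_rng(17)
        sense = [c for c in GENETIC_CODE if c not in STOP_CODONS]
        body = "ATG" + "".join(rng.choice(sense, size=164)) + "TAA"
        ann, ref = single_gene(body, start=11)
        clf = EffectClassifier(ann, ref)
        for _ in range(500):
            tpos = int(rng.integers(0, len(body)))
            gpos = 11 + tpos
            refb = body[tpos]
            altb = rng.choice([b for b in "ACGT" if b != refb])
            rec = clf.classify("chr1", gpos, refb, altb)
            # oracle: translate the whole CDS before and after with Biopython
            mutated = body[:tpos] + altb + body[tpos + 1:]
            aa_ref = str(Seq(body).translate())
            aa_alt = str(Seq(mutated).translate())
            codon_i = tpos // 3
            if codon_i == 0 and mutated[:3] != "ATG":
                assert rec.lof_subtype == "start_lost"
            elif aa_ref[codon_i] != "*" and aa_alt[codon_i] == "*":
                assert rec.lof_subtype == "stop_gained"
            elif aa_ref[codon_i] == "*" and aa_alt[codon_i] != "*":
                assert rec.lof_subtype == "stop_lost"
            elif aa_ref[codon_i] == aa_alt[codon_i]:
                assert rec.effect == "synonymous"
            else:
                assert rec.effect == "nonsynonymous-missense"

    def test_reference_mismatch_is_hard_error(self):
        ann, ref = single_gene("ATGGAATAA")
        with pytest.raises(ValueError, match="mismatch"):
            classify_variant("chr1", 2, "C", "G", ann, ref)


class TestPolarize:
    def test_outgroup_matches_ref(self):
        assert polarize("A", "G", "A") == "alt"

    def test_outgroup_matches_alt(self):
        assert polarize("A", "G", "G") == "ref"

    def test_third_allele_or_unknown_is_unpolarized(self):
        assert polarize("A", "G", "C") is None
        assert polarize("A", "G", None) is None

    def test_agrees_with_simulated_truth_at_most_sites(self, tiny_cohort):
        from driftprint.io_formats import OutgroupAlleles
        from driftprint.load import polarize_sites

        og = OutgroupAlleles(table={
            (str(r.chrom), int(r.pos)): str(r.base)
            for r in tiny_cohort.outgroup_table.itertuples()
        })
        derived = polarize_sites(tiny_cohort.matrix.sites, og)
        polarizable = derived.notna()
        # truth: reference allele is ancestral, so 'alt' is the derived call
        agree = (derived[polarizable] == "alt").mean()
        assert polarizable.any()
        assert agree >= 0.95


class TestProfilesAndZygosity:
    def test_dn_ds_arithmetic(self):
        effects = pd.DataFrame({
            "effect": ["nonsynonymous-missense"] * 10 + ["synonymous"] * 10,
            "lof_subtype": [None] * 20,
        })
        g = np.ones((1, 20), dtype=np.int8)  # carries everything het
        m = make_matrix(g)
        out = dn_ds_profile(m, effects, SiteCounts(500.0, 1000.0, 500), "s0")
        assert out["dn"] == pytest.approx(10 / 1000)
        assert out["ds"] == pytest.approx(10 / 500)
        assert out["dnds"] == pytest.approx(0.5)

    def test_no_carried_coding_variants_gives_missing_ratio(self):
        effects = pd.DataFrame({"effect": ["synonymous"] * 4, "lof_subtype": [None] * 4})
        m = make_matrix(np.zeros((1, 4), dtype=np.int8))
        with pytest.warns(UserWarning, match="dN/dS undefined"):
            out = dn_ds_profile(m, effects, SiteCounts(10.0, 10.0, 10), "s0")
        assert out["dn"] == 0 and out["ds"] == 0
        assert np.isnan(out["dnds"])

    def test_allele_count_weighting_halves_hets(self):
        effects = pd.DataFrame({
            "effect": ["nonsynonymous-missense", "synonymous"],
            "lof_subtype": [None, None],
        })
        m = make_matrix(np.array([[1, 2]], dtype=np.int8))
        out = dn_ds_profile(m, effects, SiteCounts(3.0, 3.0, 2), "s0",
                            weighting="allele-count")
        assert out["n_snv"] == pytest.approx(0.5)
        assert out["s_snv"] == pytest.approx(1.0)

    def test_zygosity_fraction(self):
        m = make_matrix(np.array([[2, 2, 2, 1, 0]], dtype=np.int8))
        out = zygosity_partition(m, "s0", np.ones(5, dtype=bool))
        assert out["hom"] == 3 and out["het"] == 1
        assert out["fraction"] == pytest.approx(0.75)

    def test_polarization_flips_derived_dosage(self):
        # derived allele is the reference at the first site: hom-ref = 2 derived
        m = make_matrix(np.array([[0, 2]], dtype=np.int8))
        derived = pd.Series(["ref", "alt"])
        out = zygosity_partition(m, "s0", np.ones(2, dtype=bool), derived=derived)
        assert out["hom"] == 2 and out["het"] == 0

    def test_gerp_threshold_is_strict(self):
        effects = pd.DataFrame({"effect": ["noncoding"] * 3, "lof_subtype": [None] * 3})
        masks = category_masks(effects, np.array([4.0, 4.01, np.nan]))
        assert list(masks["deleterious"]) == [False, True, False]

    def test_empty_category_warns(self):
        m = make_matrix(np.array([[1]], dtype=np.int8))
        with pytest.warns(UserWarning, match="empty category"):
            out = zygosity_partition(m, "s0", np.zeros(1, dtype=bool))
        assert np.isnan(out["fraction"])


def test_classifier_consistent_with_simulator_truth(tiny_cohort):
    """The analysis-side classifier and the generator's fast path must agree
    (both consume the standard genetic code)."""
    from driftprint.load import classify_sites

    effects = classify_sites(tiny_cohort.matrix.sites, tiny_cohort.annotation,
                             tiny_cohort.reference)
    truth_map = {"synonymous": "synonymous",
                 "nonsynonymous": "nonsynonymous-missense",
                 "stop_gained": "LoF", "stop_lost": "LoF", "start_lost": "LoF",
                 "noncoding": "noncoding"}
    want = tiny_cohort.truth["effect_class"].map(truth_map)
    assert (effects["effect"].to_numpy() == want.to_numpy()).all()
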