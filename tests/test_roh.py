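"""RoH scanner: site filtering, window scan semantics, size classes, and
exact equivalence with the explicit window-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftprint.reference import naive_scan_roh
from driftprint.roh import (
    RohParameters,
    filter_sites,
    scan_roh,
    summarize_roh,
)

from conftest import make_matrix, make_sample_table


def scan_params(**kw):
    defaults = dict(min_length=500_000, min_snvs=25, window_size=20,
                    density_bp_per_snv=100_000)
    defaults.update(kw)
    return RohParameters(**defaults)


class TestFilterSites:
    def test_missingness_above_threshold_drops_site(self):
        # 2 of 29 missing = 6.9% > 1%
        g = np.zeros((29, 2), dtype=np.int8)
        g[0, 0] = -1
        g[1, 0] = -1
        g[:, 1] = [0] * 14 + [1] * 15  # MAF ok, no missing
        m = make_matrix(g)
        out = filter_sites(m, RohParameters(geno=0.01, maf=0.0))
        assert out.n_sites == 1
        assert out.sites["pos"].iloc[0] == 200

    def test_maf_boundary_exact_threshold_is_retained(self):
        # 10 diploids: 1 het -> alt freq 0.05 == maf threshold
        g = np.zeros((10, 1), dtype=np.int8)
        g[0, 0] = 1
        m = make_matrix(g)
        assert filter_sites(m, RohParameters(maf=0.05)).n_sites == 1
        # freq 0.05 fails a 0.06 threshold
        assert filter_sites(m, RohParameters(maf=0.06)).n_sites == 0

    def test_outgroup_excluded_from_frequencies(self):
        g = np.zeros((3, 1), dtype=np.int8)
        g[2, 0] = 2  # only the outgroup carries the alt allele
        m = make_matrix(g, samples=["a", "b", "og"])
        table = make_sample_table(["a", "b", "og"], ["p", "p", "out"])
        table.table.loc[2, "outgroup"] = True
        out = filter_sites(m, RohParameters(maf=0.05), table)
        assert out.n_sites == 0  # monomorphic among study samples

    def test_retained_set_matches_independent_recount(self):
        rng = np.random.default_rng(21)
        g = rng.choice([-1, 0, 1, 2], size=(29, 300), p=[0.02, 0.55, 0.13, 0.3])
        m = make_matrix(g)
        params = RohParameters(geno=0.05, maf=0.1)
        out = filter_sites(m, params)
        kept = set(out.sites["pos"])
        for j in range(300):
            col = g[:, j]
            missing = (col == -1).sum()
            called = 29 - missing
            alt = col[col > -1].sum()
            freq = alt / (2 * called) if called else 0
            maf = min(freq, 1 - freq)
            expect = (missing / 29 <= 0.05) and (maf >= 0.1) and called > 0
            assert ((j + 1) * 100 in kept) == expect


class TestScanRoh:
    def test_ideal_homozygous_run(self):
        # 600 hom SNVs spanning ~0.6 Mb -> one segment
        pos = np.arange(600) * 1000 + 1
        g = np.zeros((1, 600), dtype=np.int8)
        m = make_matrix(g, positions=pos)
        segs = scan_roh(m, "s0", scan_params(min_snvs=100))
        assert len(segs) == 1
        assert segs["length"].iloc[0] == pos[-1] - pos[0] + 1
        assert segs["n_snvs"].iloc[0] == 600

    def test_single_het_at_midpoint_splits_run_below_threshold(self):
        pos = np.arange(600) * 1000 + 1
        g = np.zeros((1, 600), dtype=np.int8)
        g[0, 300] = 1
        m = make_matrix(g, positions=pos)
        # each half spans < 0.5 Mb, so nothing survives the length floor
        segs = scan_roh(m, "s0", scan_params(min_snvs=100, window_het=0))
        assert len(segs) == 0

    def test_short_run_rejected_by_strict_length_floor(self):
        pos = np.arange(400) * 1000 + 1  # spans 0.4 Mb < 0.5 Mb
        m = make_matrix(np.zeros((1, 400), dtype=np.int8), positions=pos)
        assert len(scan_roh(m, "s0", scan_params(min_snvs=50))) == 0

    def test_exactly_500kb_fails_strict_boundary(self):
        pos = np.linspace(1, 500_000, 200).astype(np.int64)
        m = make_matrix(np.zeros((1, 200), dtype=np.int8), positions=pos)
        params = scan_params(min_snvs=50, density_bp_per_snv=10_000)
        assert len(scan_roh(m, "s0", params)) == 0
        lenient = scan_params(min_snvs=50, density_bp_per_snv=10_000, length_strict=False)
        assert len(scan_roh(m, "s0", lenient)) == 1

    def test_unsorted_input_is_hard_error(self):
        m = make_matrix(np.zeros((1, 3), dtype=np.int8), positions=[300, 100, 200])
        with pytest.raises(ValueError, match="sorted"):
            scan_roh(m, "s0", scan_params())

    def test_output_independent_of_chromosome_order(self):
        rng = np.random.default_rng(5)
        frames = []
        for chroms in (["chr1"] * 300 + ["chr2"] * 300, ["chr2"] * 300 + ["chr1"] * 300):
            g = rng.bit_generator.state  # keep same genotypes both times
            pos = np.concatenate([np.arange(300) * 2000 + 1] * 2)
            geno = np.zeros((1, 600), dtype=np.int8)
            sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"})
            from driftprint.model import GenotypeMatrix

            m = GenotypeMatrix(samples=["s0"], sites=sites, genotypes=geno)
            segs = scan_roh(m, "s0", scan_params(min_snvs=50))
            frames.append(segs.sort_values(["chrom", "start"]).reset_index(drop=True))
        pd.testing.assert_frame_equal(frames[0], frames[1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        genos=st.lists(st.sampled_from([0, 0, 0, 2, 1, -1]), min_size=1, max_size=400),
        gap_scale=st.sampled_from([500, 2000, 20_000]),
        window=st.sampled_from([5, 20, 50]),
        whet=st.sampled_from([0, 1]),
        seed=st.integers(0, 10_000),
    )
    def test_matches_window_enumeration_oracle(self, genos, gap_scale, window, whet, seed):
        rng = np.random.default_rng(seed)
        gaps = rng.integers(1, gap_scale, size=len(genos))
        pos = np.cumsum(gaps) + 1
        params = RohParameters(window_size=window, window_het=whet,
                               min_length=20_000, min_snvs=5,
                               max_gap=50_000, density_bp_per_snv=30_000)
        m = make_matrix(np.asarray([genos], dtype=np.int8), positions=pos)
        got = scan_roh(m, "s0", params)
        want = naive_scan_roh(pos, genos, params)
        assert [(r.start, r.end, r.n_snvs) for r in got.itertuples()] == want


class TestSummarize:
    def test_no_segments_gives_zero_counts(self):
        table = make_sample_table(["s0"], ["p"])
        out = summarize_roh(pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                                  "length", "n_snvs"]), table)
        assert out["n_segments"].iloc[0] == 0
        assert out["total_length"].iloc[0] == 0

    def test_size_class_boundaries(self):
        table = make_sample_table(["s0"], ["p"])
        segs = pd.DataFrame({
            "sample": ["s0", "s0"], "chrom": "chr1",
            "start": [1, 1_000_000], "end": [600_000, 3_500_000],
            "length": [600_000, 2_500_000], "n_snvs": [100, 400],
        })
        out = summarize_roh(segs, table)
        assert out["n_segments"].iloc[0] == 2
        assert out["n_medium"].iloc[0] == 1  # 0.6 Mb is in 0.2-1 Mb
        assert out["n_long"].iloc[0] == 1  # 2.5 Mb > 2 Mb
        assert out["total_length"].iloc[0] == 3_100_000
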