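import numpy as np
import pandas as pd
import pytest

from flockdiv.roh import (RohParams, detect_roh, f_roh, genome_length_bp,
                          inbreeding_correlations, size_class)

from oracles import roh_segments_bruteforce
from test_diversity import make_matrix


def planted_tract(n_snps=400, tract=(150, 269), spacing=80_000, het_background=True,
                  seed=0):
    """One chromosome with a fully homozygous tract planted in a
    heterozygous-rich background; returns (matrix, tract_start_bp, tract_end_bp)."""
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_snps) + 1) * spacing
    calls = np.ones((1, n_snps), dtype=np.int8) if het_background else \
        rng.integers(0, 3, (1, n_snps)).astype(np.int8)
    calls[0, tract[0]:tract[1] + 1] = rng.choice([0, 2], tract[1] - tract[0] + 1)
    g = make_matrix(calls, pos=pos)
    return g, pos[tract[0]], pos[tract[1]]


class TestDetection:
    def test_fully_heterozygous_animal(self):
        g = make_matrix(np.ones((1, 300)), pos=(np.arange(300) + 1) * 50_000)
        assert len(detect_roh(g)) == 0

    def test_planted_tract_recovered(self):
        # 120-SNP, ~9.5-Mb homozygous tract in an otherwise heterozygous
        # chromosome -> exactly one segment containing it, class >6-12 Mb
        g, lo, hi = planted_tract()
        segs = detect_roh(g)
        assert len(segs) == 1
        seg = segs.iloc[0]
        # window-proportion eligibility may trim one SNP at each edge
        assert seg["start_bp"] <= lo + 80_000 and seg["end_bp"] >= hi - 80_000
        assert seg["size_class"] == ">6-12Mb"

    def test_gap_splits_tract(self):
        # 300-kb gap inside a homozygous tract -> two segments (gap rule)
        pos = np.concatenate([(np.arange(200) + 1) * 20_000,
                              4_300_000 + (np.arange(200) + 1) * 20_000])
        calls = np.zeros((1, 400), dtype=np.int8)
        g = make_matrix(calls, pos=pos)
        segs = detect_roh(g)
        assert len(segs) == 2
        assert segs["end_bp"].iloc[0] == 4_000_000
        assert segs["start_bp"].iloc[1] == 4_320_000

    def test_unsorted_positions_error(self):
        g = make_matrix(np.zeros((1, 60)), pos=list(range(60, 0, -1)))
        g.snps["pos"] = list(range(60, 0, -1))
        with pytest.raises(ValueError):
            detect_roh(g)

    def test_allele_swap_invariance(self):
        g, _, _ = planted_tract(seed=3)
        swapped = make_matrix(2 - g.calls, pos=g.snps["pos"].to_numpy())
        pd.testing.assert_frame_equal(
            detect_roh(g).drop(columns="animal"),
            detect_roh(swapped).drop(columns="animal"))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_scan(self, seed):
        # random genotypes with long homozygous stretches, <= 500 SNPs
        rng = np.random.default_rng(seed)
        n = 500
        calls = rng.choice([0, 1, 2, -1], size=(1, n),
                           p=[0.44, 0.08, 0.44, 0.04]).astype(np.int8)
        start = rng.integers(0, n - 200)
        calls[0, start:start + 180] = rng.choice([0, 2], 180)
        pos = np.sort(rng.choice(np.arange(1, 40_000_000), n, replace=False))
        g = make_matrix(calls, pos=pos)
        params = RohParams()
        segs = detect_roh(g, params)
        expected = roh_segments_bruteforce(calls[0], pos, params)
        assert [(s, e) for s, e in zip(segs["start_bp"], segs["end_bp"])] == expected

    def test_segments_never_overlap(self):
        g, _, _ = planted_tract(seed=5, het_background=False)
        segs = detect_roh(g)
        for _, sub in segs.groupby(["animal", "chrom"]):
            sub = sub.sort_values("start_bp")
            assert (sub["start_bp"].iloc[1:].to_numpy()
                    > sub["end_bp"].iloc[:-1].to_numpy()).all()


class TestSizeClasses:
    @pytest.mark.parametrize("mb,label", [(1.0, "1-6Mb"), (6.0, "1-6Mb"),
                                          (6.1, ">6-12Mb"), (12.0, ">6-12Mb"),
                                          (24.0, ">12-24Mb"), (47.9, ">24-48Mb"),
                                          (48.1, ">48Mb")])
    def test_half_open_boundaries(self, mb, label):
        assert size_class(int(mb * 1e6)) == label


class TestFroh:
    def test_simple_ratio(self):
        # a 50-Mb segment on a 2,500-Mb genome -> F_ROH = 0.02
        g = make_matrix(np.ones((1, 2)), chrom=["1", "1"],
                        pos=[1, 2_500_000_001])
        segs = pd.DataFrame([{"animal": "a0", "chrom": "1", "start_bp": 1,
                              "end_bp": 50_000_000, "n_snps": 100,
                              "length_bp": 50_000_000, "length_mb": 50.0,
                              "size_class": ">48Mb"}])
        summ = f_roh(segs, g)
        assert summ.per_animal["f_roh"].iloc[0] == pytest.approx(0.02)

    def test_no_segments_zero(self):
        g = make_matrix(np.ones((2, 3)))
        summ = f_roh(pd.DataFrame(), g)
        assert (summ.per_animal["f_roh"] == 0).all()

    def test_per_class_sums_to_total(self):
        g, _, _ = planted_tract(seed=6, het_background=False)
        segs = detect_roh(g)
        summ = f_roh(segs, g)
        class_cols = [c for c in summ.per_animal.columns if c.startswith("f_roh_")]
        total = summ.per_animal[class_cols].sum(axis=1)
        np.testing.assert_allclose(total, summ.per_animal["f_roh"], atol=1e-12)

    def test_genome_length_is_snp_span(self):
        g = make_matrix(np.ones((1, 4)), chrom=["1", "1", "2", "2"],
                        pos=[100, 1100, 50, 250])
        assert genome_length_bp(g) == 1000 + 200

    def test_zero_span_errors(self):
        g = make_matrix(np.ones((1, 1)), pos=[500])
        with pytest.raises(ValueError):
            f_roh(pd.DataFrame(), g)


class TestCorrelations:
    def test_identical_vectors(self):
        v = np.array([0.1, 0.2, 0.3, 0.25])
        corr = inbreeding_correlations(v, v, v)
        np.testing.assert_allclose(corr.to_numpy(), 1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(10)
        a, b, c = rng.random((3, 1000))
        corr = inbreeding_correlations(a, b, c)
        off = corr.to_numpy()[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.1)

    def test_zero_variance_column_is_nan(self):
        rng = np.random.default_rng(11)
        a = rng.random(50)
        b = np.full(50, 0.05)
        corr = inbreeding_correlations(a, b, rng.random(50))
        assert np.isnan(corr.loc["F_wright", "F_pedigree"])
        assert corr.loc["F_pedigree", "F_roh"] == corr.loc["F_roh", "F_pedigree"]
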