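import numpy as np
import pandas as pd
import pytest

from flockdiv.diversity import (apply_qc, build_stages, heterozygosity, ld_decay,
                                maf_filter, maf_spectrum, thin_by_window,
                                thin_random)
from flockdiv.genotypes import (GenotypeMatrix, read_additive, read_plink_text,
                                write_additive, write_plink_text)
from flockdiv.sim import GenomeSimConfig, PedSimConfig, gene_drop, simulate_pedigree


def make_matrix(calls, chrom=None, pos=None, flock=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_a, n_s = calls.shape
    snps = pd.DataFrame({"snp": [f"s{j}" for j in range(n_s)],
                         "chrom": chrom if chrom is not None else ["1"] * n_s,
                         "cm": 0.0,
                         "pos": pos if pos is not None else np.arange(1, n_s + 1) * 1000})
    animals = pd.DataFrame({"animal": [f"a{i}" for i in range(n_a)],
                            "flock": flock if flock is not None else "x",
                            "birth_year": np.nan, "sex": "unknown"})
    return GenotypeMatrix(calls, snps, animals)


class TestQc:
    def test_toy_matrix_counts(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        calls[0, :5] = -1   # bad animal (50% missing)
        calls[1, :6] = -1   # bad animal
        calls[2, 3] = -1    # SNP 3 call rate 7/8 after animal drop -> removed
        calls[3, 7] = -1    # SNP 7 likewise
        g = make_matrix(calls, chrom=["1"] * 6 + ["0"] + ["1"] * 3)  # SNP 6 unmapped
        out, rep = apply_qc(g)
        assert rep.animals_removed_call_rate == 2
        assert rep.snps_removed_unmapped_or_call_rate == 3  # 2 call rate + 1 unmapped
        assert out.calls.shape == (8, 7)

    def test_unmapped_chromosome_removed(self):
        g = make_matrix(np.ones((5, 3)), chrom=["1", "0", "2"])
        out, _ = apply_qc(g)
        assert list(out.snps["chrom"]) == ["1", "2"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = -1
        g = make_matrix(calls)
        once, _ = apply_qc(g)
        twice, rep = apply_qc(once)
        assert twice.calls.shape == once.calls.shape
        assert rep.animals_removed_call_rate == 0
        assert rep.snps_removed_unmapped_or_call_rate == 0

    def test_unknown_parentage_mask(self):
        g = make_matrix(np.ones((4, 5)))
        out, rep = apply_qc(g, unknown_parentage=np.array([True, False, False, False]))
        assert rep.animals_removed_unknown_parentage == 1
        assert out.n_animals == 3

    def test_empty_after_qc_errors(self):
        g = make_matrix(np.full((3, 3), -1))
        with pytest.raises(ValueError):
            apply_qc(g)


class TestThinning:
    def test_one_per_window(self):
        g = make_matrix(np.ones((2, 3)), pos=[1000, 2000, 3000])
        out = thin_by_window(g, window_bp=30_000, seed=0)
        assert out.n_snps == 1

    def test_sparse_snps_all_kept(self):
        g = make_matrix(np.ones((2, 4)), pos=[1, 50_001, 100_001, 150_001])
        out = thin_by_window(g, window_bp=30_000, seed=0)
        assert out.n_snps == 4

    def test_at_most_one_per_window_exhaustive_and_deterministic(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 200, replace=False))
        g = make_matrix(np.ones((2, 200)), pos=pos)
        out1 = thin_by_window(g, 30_000, seed=42)
        out2 = thin_by_window(g, 30_000, seed=42)
        assert list(out1.snps["snp"]) == list(out2.snps["snp"])
        windows = out1.snps["pos"] // 30_000
        assert windows.is_unique

    def test_random_thinning_fraction(self):
        g = make_matrix(np.ones((2, 2000)))
        out = thin_random(g, 0.5, seed=3)
        assert 0.4 < out.n_snps / 2000 < 0.6


class TestMafSpectrum:
    def test_bin_assignment(self):
        # one animal's codes (0,0,1) across 3 animals at one SNP:
        # allele count 1 of 6 -> MAF 1/6 in [0.15, 0.20)
        g = make_matrix([[0], [0], [1]])
        spec = maf_spectrum(g)
        tab = spec["bins"].set_index("bin")["count"]
        assert tab["[0.15,0.20)"] == 1

    def test_monomorphic_fixed_tally(self):
        g = make_matrix([[0, 2], [0, 2]])
        spec = maf_spectrum(g)
        assert spec["n_fixed"] == 2

    def test_uniform_frequencies_fill_bins(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.02, 0.98, 2000)
        calls = (rng.random((300, 2000)) < p) + (rng.random((300, 2000)) < p)
        spec = maf_spectrum(make_matrix(calls.astype(np.int8)))
        counts = spec["bins"]["count"].to_numpy()
        assert counts.sum() == 2000
        assert counts.min() > 0

    def test_maf_filter_keeps_boundary(self):
        # 100 animals: one heterozygote -> MAF exactly 0.005 (dropped),
        # two heterozygotes -> 0.01 (kept at the default cutoff)
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[0, 0] = 1
        calls[:2, 1] = 1
        out = maf_filter(make_matrix(calls), 0.01)
        assert list(out.snps["snp"]) == ["s1"]


class TestHeterozygosity:
    def test_all_het_snp(self):
        g = make_matrix(np.ones((50, 1)))
        het = heterozygosity(g)
        assert het["ho"] == 1.0
        assert het["he"] == pytest.approx(0.5)
        assert het["wright_f_mean_per_snp"] == pytest.approx(-1.0)

    def test_hardy_weinberg_f_near_zero(self):
        rng = np.random.default_rng(5)
        p = 0.3
        calls = ((rng.random((10_000, 20)) < p).astype(np.int8)
                 + (rng.random((10_000, 20)) < p).astype(np.int8))
        het = heterozygosity(make_matrix(calls))
        assert abs(het["wright_f"]) < 0.02

    def test_population_mean_formula(self):
        # the deficit F from population means follows (He-Ho)/He exactly
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, (200, 50)).astype(np.int8)
        het = heterozygosity(make_matrix(calls))
        assert het["wright_f"] == pytest.approx((het["he"] - het["ho"]) / het["he"])

    def test_monomorphic_only_errors(self):
        with pytest.raises(ValueError):
            heterozygosity(make_matrix(np.zeros((5, 3))))


class TestLdDecay:
    def test_duplicated_snp_r2_one(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, 100).astype(np.int8)
        g = make_matrix(np.column_stack([col, col]), pos=[1000, 2000])
        res = ld_decay(g)
        assert res["adjacent_mean_r2"] == pytest.approx(1.0)
        assert res["adjacent_mean_dist_bp"] == pytest.approx(1000)

    def test_independent_snps_low_r2(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, (500, 40)).astype(np.int8)
        res = ld_decay(make_matrix(calls))
        mean_r2 = res["decay"]["mean_r2"].dropna().mean()
        assert mean_r2 < 0.05

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, (200, 10)).astype(np.int8)
        g1 = make_matrix(calls)
        g2 = make_matrix(2 - calls)
        r1 = ld_decay(g1)["decay"]["mean_r2"]
        r2 = ld_decay(g2)["decay"]["mean_r2"]
        pd.testing.assert_series_equal(r1, r2)

    def test_gene_drop_decay_monotone(self):
        ped = simulate_pedigree(PedSimConfig(n_flocks=2, n_years=10,
                                             ewes_per_flock=10, seed=10))
        res = gene_drop(ped, GenomeSimConfig(n_chromosomes=1,
                                             snps_per_chromosome=300, seed=11))
        dec = ld_decay(res.genotypes, max_dist_bp=50_000_000,
                       bin_edges=np.linspace(0, 50_000_000, 11))
        vals = dec["decay"]["mean_r2"].dropna().to_numpy()
        inversions = int((np.diff(vals) > 0).sum())
        assert inversions <= len(vals) // 10 + 1


class TestIo:
    def _example(self):
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 3, (8, 10)).astype(np.int8)
        calls[0, 0] = -1
        return make_matrix(calls, chrom=["1"] * 5 + ["2"] * 5)

    def test_plink_round_trip(self, tmp_path):
        g = self._example()
        write_plink_text(g, tmp_path / "x")
        back = read_plink_text(tmp_path / "x")
        np.testing.assert_array_equal(back.calls, g.calls)
        assert list(back.snps["snp"]) == list(g.snps["snp"])

    def test_additive_round_trip(self, tmp_path):
        g = self._example()
        write_additive(g, tmp_path / "m.tsv", tmp_path / "map.tsv")
        back = read_additive(tmp_path / "m.tsv", tmp_path / "map.tsv")
        np.testing.assert_array_equal(back.calls, g.calls)

    def test_metadata_merge(self, tmp_path):
        g = self._example()
        write_plink_text(g, tmp_path / "x")
        meta = pd.DataFrame({"animal": ["a0"], "flock": ["FZ"], "birth_year": [2015]})
        back = read_plink_text(tmp_path / "x", metadata=meta)
        row = back.animals.set_index("animal").loc["a0"]
        assert row["flock"] == "FZ" and row["birth_year"] == 2015


class TestStages:
    def test_lineage_counts(self):
        ped = simulate_pedigree(PedSimConfig(n_flocks=2, n_years=6,
                                             ewes_per_flock=10, seed=13))
        res = gene_drop(ped, GenomeSimConfig(n_chromosomes=2,
                                             snps_per_chromosome=400, seed=14))
        st = build_stages(res.genotypes, seed=15)
        assert st.full.n_snps >= st.reduced.n_snps >= st.thinned.n_snps
        # 50% thinning within binomial tolerance
        frac = st.thinned.n_snps / st.reduced.n_snps
        assert 0.4 < frac < 0.6
        assert st.report.snps_after_thinning == st.full.n_snps
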