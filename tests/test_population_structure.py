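import numpy as np
import pandas as pd
import pytest

from _oracles import make_dataset
from popgenkit.population_structure import (
    compare_groups_f,
    decade_means,
    ibd_matrix,
    inbreeding_f,
    pca,
    tabulate_haplotypes,
)
from popgenkit.synthetic_data import SimConfig, simulate_dataset


class TestIbd:
    def test_duplicate_pair(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 500), size=(10, 500)).astype(np.int8)
        g[1] = g[0]
        kin = ibd_matrix(make_dataset(g))
        assert kin.pi_hat[0, 1] >= 0.95

    def test_symmetry_and_self(self, rng):
        g = rng.integers(0, 3, size=(8, 200)).astype(np.int8)
        kin = ibd_matrix(make_dataset(g))
        assert np.allclose(kin.pi_hat, kin.pi_hat.T)
        assert np.allclose(np.diag(kin.pi_hat), 1.0)
        assert ((kin.pi_hat >= 0) & (kin.pi_hat <= 1)).all()
        z_sum = kin.z0 + kin.z1 + kin.z2
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(z_sum[off], 1.0)

    def test_parent_offspring_and_unrelated(self):
        cfg = SimConfig(
            n_pops=1, n_per_pop=30, n_chromosomes=2, chrom_length_bp=8_000_000,
            snp_spacing_mean_bp=2_000, divergence_F=0.0, seed=31,
        )
        ds, truth = simulate_dataset(cfg)
        kin = ibd_matrix(ds)
        dup = truth.relationship_pairs[0]
        po = truth.relationship_pairs[1]
        assert kin.pair(dup[0], dup[1]) >= 0.95
        assert kin.pair(po[0], po[1]) == pytest.approx(0.5, abs=0.05)
        # samples 10..29 are unrelated to each other
        sub = kin.pi_hat[10:, 10:][~np.eye(20, dtype=bool)]
        assert abs(kin.pi_hat[10, 11]) <= 0.05
        assert np.abs(sub).mean() < 0.02

    def test_unreliable_flag(self, rng):
        g = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        kin = ibd_matrix(make_dataset(g))
        assert kin.unreliable[0, 1]


class TestInbreedingF:
    def test_fully_homozygous_sample(self, rng):
        g = rng.integers(0, 3, size=(20, 300)).astype(np.int8)
        g[0] = np.where(g[0] == 1, 2, g[0])
        table = inbreeding_f(make_dataset(g))
        assert table.loc[0, "f"] == pytest.approx(1.0)

    def test_hwe_mean_near_zero(self):
        cfg = SimConfig(
            n_pops=1, n_per_pop=200, n_chromosomes=2, chrom_length_bp=9_000_000,
            divergence_F=0.0, seed=32, relationship_constructions=False,
        )
        ds, _ = simulate_dataset(cfg)
        table = inbreeding_f(ds)
        assert abs(table["f"].mean()) < 0.01

    def test_fis_recovery(self):
        cfg = SimConfig(
            n_pops=1, n_per_pop=100, n_chromosomes=2, chrom_length_bp=9_000_000,
            divergence_F=0.0, within_inbreeding_Fis=0.2, seed=33,
            relationship_constructions=False,
        )
        ds, _ = simulate_dataset(cfg)
        table = inbreeding_f(ds)
        assert table["f"].mean() == pytest.approx(0.2, abs=0.02)

    def test_allele_swap_invariance(self, rng):
        g = rng.integers(0, 3, size=(15, 200)).astype(np.int8)
        t1 = inbreeding_f(make_dataset(g))
        t2 = inbreeding_f(make_dataset(2 - g))
        assert np.allclose(t1["f"], t2["f"])

    def test_monomorphic_only_rejected(self):
        g = np.zeros((5, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            inbreeding_f(make_dataset(g))


class TestDecadeAndTtest:
    def _table(self, f_values, years, pops=None):
        n = len(f_values)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "f": f_values,
                "observed_hom": 0.0,
                "expected_hom": 0.0,
                "n_used": 100,
                "population": pops or ["P"] * n,
                "birth_year": years,
            }
        )

    def test_single_decade_equals_group_mean(self):
        t = self._table([0.1, 0.2, 0.3], [1994, 1991, 1998])
        out = decade_means(t)
        assert len(out) == 1
        assert out["decade"].iloc[0] == 1990
        assert out["mean_f"].iloc[0] == pytest.approx(0.2)

    def test_missing_years_excluded_and_tallied(self):
        t = self._table([0.1, 0.2, 0.3, 0.4], [1994, None, 1998, None])
        out = decade_means(t)
        assert out["n"].sum() == 2
        assert out.attrs["n_missing_year"] == 2

    def test_drifting_f_monotone(self, rng):
        years = np.repeat([1960, 1970, 1980, 1990], 10)
        f = (years - 1960) / 300 + rng.normal(0, 1e-4, size=len(years))
        out = decade_means(self._table(f, years)).sort_values("decade")
        assert (np.diff(out["mean_f"]) > 0).all()

    def test_identical_groups_p1(self):
        t = self._table([0.1, 0.2, 0.3] * 2, [2000] * 6, ["A"] * 3 + ["B"] * 3)
        tstat, p, means = compare_groups_f(t, "A", "B")
        assert tstat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert means["A"] == means["B"]

    def test_zero_variance_equal_means(self):
        t = self._table([0.5] * 6, [2000] * 6, ["A"] * 3 + ["B"] * 3)
        tstat, p, _ = compare_groups_f(t, "A", "B")
        assert p == 1.0

    def test_small_group_rejected(self):
        t = self._table([0.1, 0.2], [2000, 2000], ["A", "B"])
        with pytest.raises(ValueError):
            compare_groups_f(t, "A", "B")


class TestPca:
    def test_matches_eigh_oracle(self, rng):
        g = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        while (g.mean(axis=0) % 2 == 0).any():  # keep all markers polymorphic
            g = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
        ds = make_dataset(g)
        res = pca(ds, n_components=4)
        # independent brute-force normalization + eigendecomposition
        p = g.mean(axis=0) / 2
        z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        cov = z @ z.T / g.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:4]
        assert np.allclose(res.eigenvalues, np.maximum(evals[order], 0), atol=1e-10)
        for k in range(4):
            v, w = res.scores[:, k], evecs[:, order[k]]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_two_population_separation(self):
        cfg = SimConfig(
            n_pops=2, n_per_pop=50, n_chromosomes=2, chrom_length_bp=18_000_000,
            divergence_F=0.1, seed=34, relationship_constructions=False,
        )
        ds, _ = simulate_dataset(cfg)
        res = pca(ds)
        pc1 = res.scores[:, 0]
        a, b = pc1[:50], pc1[50:]
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_homogeneous_population_bulk_edge(self):
        cfg = SimConfig(
            n_pops=1, n_per_pop=60, n_chromosomes=2, chrom_length_bp=18_000_000,
            divergence_F=0.0, seed=35, relationship_constructions=False,
        )
        ds, _ = simulate_dataset(cfg)
        res = pca(ds, 3)
        edge = (1 + np.sqrt(60 / ds.n_markers)) ** 2
        assert res.eigenvalues[0] < edge * 1.05

    def test_marker_permutation_invariance(self, rng):
        g = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        ds = make_dataset(g)
        res1 = pca(ds, 3)
        perm = rng.permutation(60)
        # keep the map sorted: reuse original positions for permuted genotypes
        ds2 = make_dataset(g[:, perm])
        res2 = pca(ds2, 3)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
        for k in range(3):
            v, w = res1.scores[:, k], res2.scores[:, k]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_eigenvalue_conservation(self, rng):
        g = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        ds = make_dataset(g)
        res = pca(ds, n_components=10)
        p = ds.alt_allele_freq()
        var = 2 * p * (1 - p)
        keep = var > 0
        z = (g[:, keep] - 2 * p[keep]) / np.sqrt(var[keep])
        total = np.trace(z @ z.T / keep.sum())
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_component_clipping_warns(self, rng):
        g = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
        with pytest.warns(UserWarning):
            res = pca(make_dataset(g), n_components=10)
        assert res.scores.shape[1] == 3


class TestHaplotypes:
    def _calls(self, rows, ids=None):
        arr = np.asarray(rows)
        ids = ids or [f"m{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=ids)

    def test_all_identical(self):
        calls = self._calls([[0, 2, 0]] * 4)
        counts, dist, excluded = tabulate_haplotypes(calls)
        assert counts.tolist() == [4]
        assert excluded == []

    def test_single_marker_difference(self):
        calls = self._calls([[0, 2, 0], [0, 2, 2]])
        counts, dist, _ = tabulate_haplotypes(calls)
        assert len(counts) == 2
        assert dist.iloc[0, 1] == 1

    def test_three_haplotypes_manual_tally(self):
        calls = self._calls([[0, 0], [0, 0], [2, 0], [2, 2], [2, 2], [2, 2]])
        counts, _, _ = tabulate_haplotypes(calls)
        assert sorted(counts.tolist()) == [1, 2, 3]

    def test_het_call_excluded(self):
        calls = self._calls([[0, 1, 0], [0, 2, 0]])
        counts, _, excluded = tabulate_haplotypes(calls)
        assert excluded == ["m0"]
        assert counts.sum() == 1

    def test_missing_grouped_separately(self):
        calls = self._calls([[0, -1, 0], [0, 2, 0]])
        counts, dist, _ = tabulate_haplotypes(calls)
        assert any("?" in h for h in counts.index)
        assert all("?" not in h for h in dist.index)
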