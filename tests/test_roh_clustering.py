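import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from _oracles import make_dataset
from popgenkit.roh_clustering import (
    call_incidence_regions,
    find_clusters,
    homozygosity_association,
    membership_matrix,
)
from popgenkit.roh_detection import ROHParams, ROHRecord, ROHSet
from popgenkit.selection_fst import sigma_threshold_regions


def grid_markers(n=300, spacing=100_000, chrom="1"):
    pos = (np.arange(n) + 1) * spacing
    return make_dataset(np.zeros((1, n), np.int8), chrom=[chrom] * n, pos=pos).markers


def rohset(recs, samples):
    return ROHSet(list(recs), ROHParams(), 10**9, list(samples))


class TestFindClusters:
    def test_identical_members(self):
        recs = [
            ROHRecord(f"s{i}", "1", 10_000_000, 20_000_000, 100, 0, 0) for i in range(5)
        ]
        cl = find_clusters(rohset(recs, [f"s{i}" for i in range(5)]), grid_markers())
        assert len(cl) == 1
        assert (cl[0].consensus_start_bp, cl[0].consensus_end_bp) == (10_000_000, 20_000_000)
        assert len(cl[0].member_samples) == 5

    def test_staggered_members(self):
        recs = [
            ROHRecord(f"s{i}", "1", (1 + i) * 1_000_000, (11 + i) * 1_000_000, 100, 0, 0)
            for i in range(5)
        ]
        cl = find_clusters(rohset(recs, [f"s{i}" for i in range(5)]), grid_markers())
        assert len(cl) == 1
        # consensus = [max(starts), min(ends)]
        assert (cl[0].consensus_start_bp, cl[0].consensus_end_bp) == (5_000_000, 11_000_000)

    def test_below_min_members(self):
        recs = [
            ROHRecord(f"s{i}", "1", 1_000_000, 9_000_000, 100, 0, 0) for i in range(4)
        ]
        assert find_clusters(rohset(recs, [f"s{i}" for i in range(4)]), grid_markers()) == []

    def test_first_snp_anchor(self):
        recs = [
            ROHRecord(f"s{i}", "1", 1_050_000, 2_050_000, 10, 0, 0) for i in range(5)
        ]
        markers = grid_markers()
        cl = find_clusters(rohset(recs, [f"s{i}" for i in range(5)]), markers)
        # first marker at or after 1,050,000 on the 100kb grid is 1,100,000
        assert cl[0].first_snp_bp == 1_100_000
        assert cl[0].first_snp_id == markers.loc[
            markers["position_bp"] == 1_100_000, "marker_id"
        ].iloc[0]

    def test_consensus_contained_in_members(self, rng):
        samples = [f"s{i}" for i in range(12)]
        recs = []
        for i, s in enumerate(samples * 3):
            start = int(rng.integers(1, 25_000_000))
            recs.append(
                ROHRecord(s, "1", start, start + int(rng.integers(2, 8) * 1e6), 10, 0, 0)
            )
        clusters = find_clusters(rohset(recs, samples), grid_markers(400), min_members=4)
        by_sample = {}
        for r in recs:
            by_sample.setdefault(r.sample_id, []).append(r)
        for cl in clusters:
            assert cl.consensus_start_bp <= cl.consensus_end_bp
            for s in cl.member_samples:
                assert any(
                    r.start_bp <= cl.consensus_start_bp
                    and r.end_bp >= cl.consensus_end_bp
                    for r in by_sample[s]
                )

    def test_two_disjoint_clusters(self):
        recs = [
            ROHRecord(f"s{i}", "1", 1_000_000, 4_000_000, 10, 0, 0) for i in range(5)
        ] + [
            ROHRecord(f"s{i}", "1", 20_000_000, 24_000_000, 10, 0, 0) for i in range(5, 11)
        ]
        cl = find_clusters(rohset(recs, [f"s{i}" for i in range(11)]), grid_markers())
        assert len(cl) == 2
        assert cl[0].consensus_start_bp == 1_000_000
        assert cl[1].consensus_start_bp == 20_000_000


class TestMembership:
    def test_members_flagged(self):
        samples = [f"s{i}" for i in range(6)]
        recs = [ROHRecord(s, "1", 1_000_000, 4_000_000, 10, 0, 0) for s in samples[:5]]
        rs = rohset(recs, samples)
        clusters = find_clusters(rs, grid_markers())
        mm = membership_matrix(rs, clusters)
        assert mm.iloc[:5, 0].tolist() == [1] * 5
        assert mm.iloc[5, 0] == 0  # sample without ROH: zero row

    def test_oracle_agreement(self, rng):
        samples = [f"s{i}" for i in range(10)]
        recs = []
        for s in samples:
            for _ in range(3):
                start = int(rng.integers(1, 25_000_000))
                recs.append(
                    ROHRecord(s, "1", start, start + 3_000_000, 10, 0, 0)
                )
        rs = rohset(recs, samples)
        clusters = find_clusters(rs, grid_markers(400), min_members=3)
        mm = membership_matrix(rs, clusters)
        for j, cl in enumerate(clusters):
            for i, s in enumerate(samples):
                expect = any(
                    r.sample_id == s and r.start_bp <= cl.first_snp_bp <= r.end_bp
                    for r in recs
                )
                assert mm.iloc[i, j] == int(expect)


class TestAssociation:
    def test_balanced_all_carriers_p1(self):
        ids = [f"s{i}" for i in range(20)]
        mm = pd.DataFrame({"cluster_0": [1] * 20}, index=ids)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=ids)
        res = homozygosity_association(mm, labels)
        assert res.table["p_value"].iloc[0] == 1.0

    def test_perfect_split_exact_p(self):
        # all of group A carries, none of B: two-sided Fisher p = 2 / C(40,20)
        ids = [f"s{i}" for i in range(40)]
        mm = pd.DataFrame({"cluster_0": [1] * 20 + [0] * 20}, index=ids)
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=ids)
        res = homozygosity_association(mm, labels)
        expected = 2.0 / comb(40, 20, exact=True)
        assert res.table["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res.table["enriched_group"].iloc[0] == "A"

    def test_bonferroni_and_bh(self, rng):
        ids = [f"s{i}" for i in range(30)]
        mm = pd.DataFrame(
            (rng.random((30, 8)) < 0.4).astype(int),
            index=ids,
            columns=[f"cluster_{j}" for j in range(8)],
        )
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=ids)
        res = homozygosity_association(mm, labels)
        t = res.table
        assert res.test_count == 8
        assert np.allclose(t["bonferroni_p"], np.minimum(1.0, t["p_value"] * 8))
        ranked = t.sort_values("p_value")
        assert (np.diff(ranked["bh_fdr_q"]) >= -1e-12).all()

    def test_group_errors(self):
        ids = ["a", "b"]
        mm = pd.DataFrame({"cluster_0": [1, 0]}, index=ids)
        with pytest.raises(ValueError):
            homozygosity_association(mm, pd.Series(["A", "A"], index=ids))

    def test_fisher_chi2_rank_agreement(self, rng):
        ids = [f"s{i}" for i in range(60)]
        labels = pd.Series(["A"] * 30 + ["B"] * 30, index=ids)
        cols = {}
        for j in range(60):
            pa, pb = rng.uniform(0.15, 0.85, size=2)
            cols[f"cluster_{j}"] = np.concatenate(
                [rng.random(30) < pa, rng.random(30) < pb]
            ).astype(int)
        mm = pd.DataFrame(cols, index=ids)
        res = homozygosity_association(mm, labels)
        t = res.table[(res.table["p_value"] < 1.0) & (res.table["chi2_p"] < 1.0)]
        rho = stats.spearmanr(t["p_value"], t["chi2_p"]).statistic
        assert rho > 0.99

    def test_pvalues_valid_under_null(self, rng):
        # Fisher p-values on discrete tables are super-uniform (conservative):
        # P(p <= t) <= t for every t.  Checked empirically over label
        # permutations of a null dataset.
        n = 40
        ids = [f"s{i}" for i in range(n)]
        member = (rng.random(n) < 0.4).astype(int)
        base = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        pvals = []
        for _ in range(400):
            labels = pd.Series(rng.permutation(base), index=ids)
            mm = pd.DataFrame({"cluster_0": member}, index=ids)
            pvals.append(
                homozygosity_association(mm, labels).table["p_value"].iloc[0]
            )
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        # 3-sigma binomial slack on the empirical CDF
        slack = 3 * np.sqrt(ecdf * (1 - ecdf) / len(pvals)) + 1e-9
        assert (ecdf <= pvals + slack + 0.05).all()


class TestIncidenceRegions:
    def test_flat_incidence_empty(self):
        markers = grid_markers(100)
        assert call_incidence_regions(np.full(100, 3.0), markers) == []

    def test_single_spike(self):
        markers = grid_markers(500)
        counts = np.zeros(500)
        counts[250:253] = 30  # spike small enough not to swamp sigma itself
        mu, sigma = counts.mean(), counts.std(ddof=1)
        assert mu + 7 * sigma < 30  # spike really is a seed
        regions = call_incidence_regions(counts, markers)
        assert len(regions) == 1
        r = regions[0]
        assert r.start_bp <= markers["position_bp"].iloc[250]
        assert r.end_bp >= markers["position_bp"].iloc[252]

    def test_matches_shared_threshold_logic(self, rng):
        markers = grid_markers(300)
        counts = rng.poisson(3, size=300).astype(float)
        counts[150] = 60
        mu, sigma = counts.mean(), counts.std(ddof=1)
        ours = call_incidence_regions(counts, markers)
        ref = sigma_threshold_regions(
            counts, markers, mu=mu, sigma=sigma, seed_mult=7.0, ext_mult=5.0, pad_bp=0
        )
        assert [(r.chromosome, r.start_bp, r.end_bp) for r in ours] == [
            (r.chromosome, r.start_bp, r.end_bp) for r in ref
        ]
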