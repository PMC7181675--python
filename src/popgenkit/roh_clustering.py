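"""ROH clusters shared across individuals and the homozygosity association
test between two labeled groups.

A cluster is seeded at a local maximum of per-position ROH coverage (leftmost
on ties) reached by at least ``min_members`` distinct samples; its members are
the runs overlapping the seed point and its consensus interval spans from the
maximum of member starts to the minimum of member ends (nonempty because all
members contain the seed).  Member runs are consumed, so clusters never share
a seed.

The association test builds, per cluster, a 2x2 group-by-membership table
where membership means "has an ROH containing the cluster's first SNP".  The
primary p-value is a two-sided Fisher exact test; a chi-square statistic
(without continuity correction) is reported alongside, with Bonferroni and
Benjamini-Hochberg corrections over the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .roh_detection import ROHSet
from .selection_fst import SelectionRegion, sigma_threshold_regions

__all__ = [
    "ROHCluster",
    "AssociationResult",
    "find_clusters",
    "membership_matrix",
    "homozygosity_association",
    "call_incidence_regions",
]


@dataclass
class ROHCluster:
    chromosome: str
    consensus_start_bp: int
    consensus_end_bp: int
    first_snp_id: str
    first_snp_bp: int
    member_samples: list[str] = field(default_factory=list)
    n_snps_in_cluster: int = 0

    @property
    def length_bp(self) -> int:
        return self.consensus_end_bp - self.consensus_start_bp


@dataclass
class AssociationResult:
    table: pd.DataFrame  # one row per cluster
    test_count: int
    group_names: tuple[str, str]
    group_sizes: tuple[int, int]


def find_clusters(
    rohset: ROHSet, markers: pd.DataFrame, min_members: int = 5
) -> list[ROHCluster]:
    """Consensus ROH clusters carried by at least *min_members* samples."""
    chrom_arr = markers["chromosome"].astype(str).to_numpy()
    pos_by_chrom = {}
    ids_by_chrom = {}
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        pos_by_chrom[str(chrom)] = markers["position_bp"].to_numpy(np.int64)[cols]
        ids_by_chrom[str(chrom)] = markers["marker_id"].to_numpy()[cols]

    by_chrom: dict[str, list] = {}
    for rec in rohset.records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    clusters: list[ROHCluster] = []
    for chrom, recs in sorted(by_chrom.items()):
        pool = list(recs)
        while True:
            seed = _leftmost_coverage_peak(pool, min_members)
            if seed is None:
                break
            members = [r for r in pool if r.start_bp <= seed <= r.end_bp]
            if len({r.sample_id for r in members}) < min_members:
                break  # defensive; peak guarantees coverage >= min_members
            cons_start = max(r.start_bp for r in members)
            cons_end = min(r.end_bp for r in members)
            pos = pos_by_chrom.get(chrom)
            if pos is not None and len(pos):
                lo = int(np.searchsorted(pos, cons_start, side="left"))
                hi = int(np.searchsorted(pos, cons_end, side="right"))
                first_id = str(ids_by_chrom[chrom][lo]) if lo < len(pos) else ""
                first_bp = int(pos[lo]) if lo < len(pos) else cons_start
                n_snps = hi - lo
            else:
                first_id, first_bp, n_snps = "", cons_start, 0
            clusters.append(
                ROHCluster(
                    chromosome=chrom,
                    consensus_start_bp=int(cons_start),
                    consensus_end_bp=int(cons_end),
                    first_snp_id=first_id,
                    first_snp_bp=first_bp,
                    member_samples=sorted({r.sample_id for r in members}),
                    n_snps_in_cluster=int(n_snps),
                )
            )
            consumed = set(id(r) for r in members)
            pool = [r for r in pool if id(r) not in consumed]
    return clusters


def _leftmost_coverage_peak(records, min_members: int):
    """Leftmost position where ROH coverage is a local maximum >= min_members.

    Coverage is the number of records (distinct samples, since per-sample runs
    do not overlap) containing a position; the step function changes only at
    record starts/ends, so the scan walks sorted breakpoints.
    """
    if not records:
        return None
    events = []
    for r in records:
        events.append((r.start_bp, +1))
        events.append((r.end_bp + 1, -1))
    events.sort()
    # build plateau list: (start, coverage)
    plateaus = []
    cov = 0
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            cov += events[i][1]
            i += 1
        plateaus.append((pos, cov))
    best = None
    for k, (pos, cov) in enumerate(plateaus):
        prev_cov = plateaus[k - 1][1] if k > 0 else 0
        next_cov = plateaus[k + 1][1] if k + 1 < len(plateaus) else 0
        if cov >= min_members and cov > prev_cov and cov > next_cov:
            best = pos
            break
    return best


def membership_matrix(rohset: ROHSet, clusters: list[ROHCluster]) -> pd.DataFrame:
    """Binary sample x cluster matrix: 1 iff the sample has an ROH containing
    the cluster's first-SNP position."""
    sample_ids = list(rohset.sample_ids)
    out = np.zeros((len(sample_ids), len(clusters)), dtype=np.int8)
    index = {sid: i for i, sid in enumerate(sample_ids)}
    for j, cl in enumerate(clusters):
        for rec in rohset.records:
            if (
                rec.chromosome == cl.chromosome
                and rec.start_bp <= cl.first_snp_bp <= rec.end_bp
            ):
                out[index[rec.sample_id], j] = 1
    cols = [f"cluster_{j}" for j in range(len(clusters))]
    return pd.DataFrame(out, index=pd.Index(sample_ids, name="sample_id"), columns=cols)


@lru_cache(maxsize=100_000)
def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _chi2_no_correction(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    exp = np.outer(rows, cols) / n
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, 1))


def homozygosity_association(membership: pd.DataFrame, group_labels) -> AssociationResult:
    """Per-cluster two-group association of ROH membership.

    *group_labels* is a Series/dict keyed by sample_id (or positional array)
    with exactly two levels.  Degenerate tables (everyone or no one a member)
    give p = 1.
    """
    labels = pd.Series(group_labels)
    if not isinstance(labels.index, pd.RangeIndex) or len(labels) != len(membership):
        labels = labels.reindex(membership.index)
    values = labels.to_numpy()
    groups = pd.unique(values[~pd.isna(values)])
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    in_a = values == groups[0]
    in_b = values == groups[1]
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")

    mem = membership.to_numpy()
    k = mem.shape[1]
    rows = []
    for j in range(k):
        a = int(mem[in_a, j].sum())  # group A carriers
        b = n_a - a
        c = int(mem[in_b, j].sum())
        d = n_b - c
        if (a + c == 0) or (b + d == 0):  # all or none carry: degenerate
            p = 1.0
            chi2_stat, chi2_p = 0.0, 1.0
        else:
            p = _fisher_two_sided(a, b, c, d)
            chi2_stat, chi2_p = _chi2_no_correction(a, b, c, d)
        fa, fb = a / n_a, c / n_b
        direction = (
            str(groups[0]) if fa > fb else (str(groups[1]) if fb > fa else "equal")
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "cluster": membership.columns[j],
                "carriers_a": a,
                "carriers_b": c,
                "n_a": n_a,
                "n_b": n_b,
                "odds_ratio": odds,
                "p_value": p,
                "chi2_stat": chi2_stat,
                "chi2_p": chi2_p,
                "enriched_group": direction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "carriers_a",
            "carriers_b",
            "n_a",
            "n_b",
            "odds_ratio",
            "p_value",
            "chi2_stat",
            "chi2_p",
            "enriched_group",
        ],
    )
    if k:
        table["bonferroni_p"] = np.minimum(1.0, table["p_value"] * k)
        table["bh_fdr_q"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["bonferroni_p"] = []
        table["bh_fdr_q"] = []
    return AssociationResult(
        table=table,
        test_count=k,
        group_names=(str(groups[0]), str(groups[1])),
        group_sizes=(n_a, n_b),
    )


def call_incidence_regions(
    incidence: np.ndarray,
    markers: pd.DataFrame,
    seed_mult: float = 7.0,
    ext_mult: float = 5.0,
    pad_bp: int = 0,
    chrom_lengths: dict | None = None,
) -> list[SelectionRegion]:
    """Commonly-homozygous regions from per-SNP ROH incidence counts.

    Applies the same sigma-threshold logic as the F_ST region caller: seed at
    count > mu + seed_mult*sigma, extend through consecutive SNPs with count
    > mu + ext_mult*sigma.  Zero-variance incidence yields no regions.  By
    default no padding is added (pad_bp = 0).
    """
    incidence = np.asarray(incidence, dtype=float)
    if len(incidence) != len(markers):
        raise ValueError("incidence is not aligned to the marker map")
    mu = float(incidence.mean()) if len(incidence) else 0.0
    sigma = float(incidence.std(ddof=1)) if len(incidence) > 1 else 0.0
    return sigma_threshold_regions(
        incidence,
        markers,
        mu=mu,
        sigma=sigma,
        seed_mult=seed_mult,
        ext_mult=ext_mult,
        pad_bp=pad_bp,
        chrom_lengths=chrom_lengths,
    )
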