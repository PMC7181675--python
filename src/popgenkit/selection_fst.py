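"""Marker-based F_ST, the sigma-threshold region caller, and multilocus
pairwise population divergence.

Per-marker theta follows the Weir & Cockerham (1984) variance-components
estimator computed from genotype counts (observed heterozygosity enters the
within-individual component; sample sizes weight every moment).  Negative
per-marker estimates are clamped to 0 so profiles live on [0, 1]; multilocus
estimates are ratio-of-sums over the unclamped components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset

__all__ = [
    "FstProfile",
    "SelectionRegion",
    "marker_fst",
    "call_regions",
    "sigma_threshold_regions",
    "pairwise_population_fst",
    "wc_components",
    "manhattan_plot",
]


@dataclass
class FstProfile:
    theta: np.ndarray  # per-marker, clamped to [0, 1]
    mu_hat: float
    sigma_hat: float
    n_zero_variance: int

    def threshold(self, k: float) -> float:
        return self.mu_hat + k * self.sigma_hat

    def to_frame(self, markers: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": markers["marker_id"].to_numpy(),
                "chromosome": markers["chromosome"].to_numpy(),
                "position_bp": markers["position_bp"].to_numpy(),
                "theta": self.theta,
            }
        )


@dataclass
class SelectionRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    seed_snp_ids: list[str] = field(default_factory=list)
    n_consecutive_extreme: int = 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def align_group_labels(dataset: GenotypeDataset, group_labels) -> np.ndarray:
    """Resolve *group_labels* (positional array, or Series/dict keyed by
    sample_id) to an array aligned with ``dataset.samples``."""
    labels = pd.Series(group_labels)
    sample_ids = dataset.samples["sample_id"]
    if len(labels) == dataset.n_samples and isinstance(
        labels.index, pd.RangeIndex
    ):
        return labels.to_numpy()
    return labels.reindex(sample_ids).to_numpy()


def _group_matrices(dataset: GenotypeDataset, group_labels):
    values = align_group_labels(dataset, group_labels)
    groups = pd.unique(values[~pd.isna(values)])
    return [dataset.genotypes[values == grp] for grp in groups], list(groups)


def wc_components(g_groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components (a, b, c) per marker.

    *g_groups* is a list of genotype matrices (samples x markers, -1 missing),
    one per subpopulation.  Markers where any group has < 1 non-missing call
    or overall zero variance yield a = b = c = 0.
    """
    r = len(g_groups)
    if r < 2:
        raise ValueError("need at least two groups")
    m = g_groups[0].shape[1]
    n_i = np.zeros((r, m))
    p_i = np.zeros((r, m))
    h_i = np.zeros((r, m))
    for k, g in enumerate(g_groups):
        ok = g >= 0
        n = ok.sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(ok, g, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h_i[k] = np.where(ok & (g == 1), 1, 0).sum(axis=0) / np.maximum(n, 1)

    n_sum = n_i.sum(axis=0)
    n_bar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    valid = (n_i >= 1).all(axis=0) & (n_bar > 1) & (n_c > 0)
    poly = (p_bar > 0) & (p_bar < 1)
    keep = valid & poly
    a = np.where(keep, a, 0.0)
    b = np.where(keep, b, 0.0)
    c = np.where(keep, c, 0.0)
    return np.nan_to_num(a), np.nan_to_num(b), np.nan_to_num(c)


def marker_fst(dataset: GenotypeDataset, group_labels) -> FstProfile:
    """Per-marker Weir–Cockerham theta between exactly two groups.

    Zero-variance markers get theta = 0 and are tallied; negative estimates
    are clamped to 0.  mu_hat and sigma_hat summarize all markers after
    clamping (invariant markers included).
    """
    (g_groups, names) = _group_matrices(dataset, group_labels)
    if len(g_groups) != 2:
        raise ValueError(f"marker_fst needs exactly two groups, got {names}")
    for g, name in zip(g_groups, names):
        if g.shape[0] < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    a, b, c = wc_components(g_groups)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, a / denom, 0.0)
    n_zero = int((denom <= 0).sum())
    theta = np.clip(np.nan_to_num(theta), 0.0, 1.0)
    mu = float(theta.mean()) if len(theta) else 0.0
    sigma = float(theta.std(ddof=1)) if len(theta) > 1 else 0.0
    return FstProfile(theta=theta, mu_hat=mu, sigma_hat=sigma, n_zero_variance=n_zero)


def pairwise_population_fst(dataset: GenotypeDataset, group_labels) -> pd.DataFrame:
    """Multilocus theta for every pair of groups (ratio of summed components).

    Returns a symmetric DataFrame with zero diagonal, entries clamped to
    [0, 1].
    """
    labels = align_group_labels(dataset, group_labels)
    groups = list(pd.unique(labels[~pd.isna(labels)]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    mats = {grp: dataset.genotypes[labels == grp] for grp in groups}
    for grp, g in mats.items():
        if g.shape[0] < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            a, b, c = wc_components([mats[gi], mats[gj]])
            denom = (a + b + c).sum()
            theta = a.sum() / denom if denom > 0 else 0.0
            theta = float(np.clip(theta, 0.0, 1.0))
            out.loc[gi, gj] = out.loc[gj, gi] = theta
    return out


# ---------------------------------------------------------------------------
# sigma-threshold region caller (shared with the ROH incidence scan)
# ---------------------------------------------------------------------------

def sigma_threshold_regions(
    values: np.ndarray,
    markers: pd.DataFrame,
    mu: float,
    sigma: float,
    seed_mult: float = 7.0,
    ext_mult: float = 5.0,
    pad_bp: int = 500_000,
    strict_padding: bool = False,
    chrom_lengths: dict | None = None,
) -> list[SelectionRegion]:
    """Call regions around SNPs exceeding ``mu + seed_mult * sigma``.

    For each seed SNP: if both map-adjacent flanking SNPs are at or below the
    extension threshold ``mu + ext_mult * sigma``, the region is the window of
    ``2 * pad_bp`` centered on the seed.  Otherwise the contiguous segment of
    SNPs above the extension threshold containing the seed is taken and
    padded by *pad_bp* at each end (``2 * pad_bp`` per end when
    *strict_padding*).  Overlapping regions are merged; regions are clipped
    to position >= 1 and, when *chrom_lengths* is given, to the chromosome
    length.
    """
    if sigma <= 0:
        return []
    values = np.asarray(values, dtype=float)
    seed_thr = mu + seed_mult * sigma
    ext_thr = mu + ext_mult * sigma
    chrom_arr = markers["chromosome"].astype(str).to_numpy()
    pos_arr = markers["position_bp"].to_numpy(np.int64)
    ids = markers["marker_id"].to_numpy()

    regions: list[SelectionRegion] = []
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        v = values[cols]
        pos = pos_arr[cols]
        seeds = np.flatnonzero(v > seed_thr)
        if len(seeds) == 0:
            continue
        ext = v > ext_thr
        raw: list[tuple[int, int, list[int], int]] = []
        for s in seeds:
            left_ok = s == 0 or v[s - 1] <= ext_thr
            right_ok = s == len(v) - 1 or v[s + 1] <= ext_thr
            if left_ok and right_ok:
                raw.append((int(pos[s] - pad_bp), int(pos[s] + pad_bp), [s], 1))
            else:
                lo = s
                while lo > 0 and ext[lo - 1]:
                    lo -= 1
                hi = s
                while hi < len(v) - 1 and ext[hi + 1]:
                    hi += 1
                end_pad = 2 * pad_bp if strict_padding else pad_bp
                raw.append(
                    (int(pos[lo] - end_pad), int(pos[hi] + end_pad), [s], hi - lo + 1)
                )
        raw.sort(key=lambda t: t[0])
        merged: list[list] = []
        for start, end, seed_idx, n_ext in raw:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2].extend(seed_idx)
                merged[-1][3] = max(merged[-1][3], n_ext)
            else:
                merged.append([start, end, list(seed_idx), n_ext])
        limit = None
        if chrom_lengths is not None:
            limit = chrom_lengths.get(chrom) or chrom_lengths.get(str(chrom))
        for start, end, seed_idx, n_ext in merged:
            start = max(1, start)
            if limit is not None:
                end = min(int(limit), end)
            regions.append(
                SelectionRegion(
                    chromosome=str(chrom),
                    start_bp=int(start),
                    end_bp=int(end),
                    seed_snp_ids=[str(ids[cols[s]]) for s in sorted(set(seed_idx))],
                    n_consecutive_extreme=int(n_ext),
                )
            )
    return regions


def call_regions(
    profile: FstProfile,
    markers: pd.DataFrame,
    seed_mult: float = 7.0,
    ext_mult: float = 5.0,
    pad_bp: int = 500_000,
    strict_padding: bool = False,
    chrom_lengths: dict | None = None,
) -> list[SelectionRegion]:
    """Sigma-threshold selection regions from a per-marker theta profile."""
    if len(profile.theta) != len(markers):
        raise ValueError("profile is not aligned to the marker map")
    return sigma_threshold_regions(
        profile.theta,
        markers,
        mu=profile.mu_hat,
        sigma=profile.sigma_hat,
        seed_mult=seed_mult,
        ext_mult=ext_mult,
        pad_bp=pad_bp,
        strict_padding=strict_padding,
        chrom_lengths=chrom_lengths,
    )


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "n_seed_snps": len(r.seed_snp_ids),
                "n_consecutive_extreme": r.n_consecutive_extreme,
                "seed_snp_ids": ",".join(r.seed_snp_ids),
            }
            for r in regions
        ],
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_seed_snps",
            "n_consecutive_extreme",
            "seed_snp_ids",
        ],
    )


def manhattan_plot(profile: FstProfile, markers: pd.DataFrame, out_path, ext_mult=5.0):
    """Genome-wide theta scatter with the mu + k.sigma line, saved to disk."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .genotype_io import chromosome_sort_key

    chrom_arr = markers["chromosome"].astype(str).to_numpy()
    pos_arr = markers["position_bp"].to_numpy(np.int64)
    chroms = sorted(pd.unique(chrom_arr), key=chromosome_sort_key)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    for i, chrom in enumerate(chroms):
        cols = np.flatnonzero(chrom_arr == chrom)
        ax.scatter(
            offset + pos_arr[cols],
            profile.theta[cols],
            s=2,
            color="C0" if i % 2 == 0 else "C1",
            rasterized=True,
        )
        offset += pos_arr[cols].max() + 1_000_000
    ax.axhline(profile.threshold(ext_mult), color="black", lw=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel("per-marker theta")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
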