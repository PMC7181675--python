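"""Per-individual runs of homozygosity, length-bin summaries, and F_ROH.

A run is a maximal stretch of map-consecutive autosomal SNPs that is
homozygous up to a small allowance of heterozygous and missing calls, with
no inter-SNP gap above a cap, and that meets minimum SNP-count and physical
length thresholds.  Run boundaries are always homozygous non-missing SNPs
(allowed het/missing calls may only be interior).

Runs are selected left-to-right: among all qualifying candidate intervals,
the one with the leftmost start (longest end on ties) is emitted and the scan
resumes after it, so the per-sample record set is non-overlapping and is the
leftmost-maximal resolution of overlapping candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset

__all__ = [
    "ROHParams",
    "ROHRecord",
    "ROHSet",
    "detect_roh",
    "summarize_roh_bins",
    "snp_incidence",
    "compute_f_roh",
    "f_roh_table",
    "autosomal_map_length",
    "BOVINE_HD_L_AUTO_KB",
]

#: published mapped-autosome extent for the BovineHD array, in kilobasepairs
BOVINE_HD_L_AUTO_KB = 2_510_611


@dataclass(frozen=True)
class ROHParams:
    min_length_bp: int = 500_000
    min_snps: int = 25
    max_het: int = 1
    max_missing: int = 5
    max_gap_bp: int = 100_000

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"ROHParams.{name} must be >= 0")


@dataclass(frozen=True)
class ROHRecord:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def contains(self, position_bp: int) -> bool:
        return self.start_bp <= position_bp <= self.end_bp


@dataclass
class ROHSet:
    records: list[ROHRecord]
    params: ROHParams
    l_auto_bp: int
    sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "chromosome": r.chromosome,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "length_bp": r.length_bp,
                    "n_snps": r.n_snps,
                    "n_het": r.n_het,
                    "n_missing": r.n_missing,
                }
                for r in self.records
            ],
            columns=[
                "sample_id",
                "chromosome",
                "start_bp",
                "end_bp",
                "length_bp",
                "n_snps",
                "n_het",
                "n_missing",
            ],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def autosomal_map_length(markers: pd.DataFrame) -> int:
    """Sum over autosomes of (last - first) SNP position, in bp."""
    from .genotype_io import is_autosome

    total = 0
    for chrom, grp in markers.groupby("chromosome", sort=False):
        if is_autosome(chrom):
            pos = grp["position_bp"]
            total += int(pos.max() - pos.min())
    return total


def _detect_sample_chrom(
    g: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Runs on one sample/chromosome as (start_idx, end_idx, n_het, n_missing).

    Two-pointer scan over segments delimited by gaps > max_gap_bp.  For each
    candidate homozygous start, the maximal feasible end under the het and
    missing budgets is found; the end is trimmed back to the last homozygous
    SNP and the run is emitted if it meets the SNP-count and length minima.
    """
    het = g == 1
    miss = g < 0
    hom = ~het & ~miss
    m = len(g)
    out: list[tuple[int, int, int, int]] = []
    if m == 0:
        return out

    het_cum = np.concatenate([[0], np.cumsum(het)])
    miss_cum = np.concatenate([[0], np.cumsum(miss)])

    # hard breaks where consecutive-SNP gap exceeds the cap
    breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
    seg_starts = np.concatenate([[0], breaks + 1])
    seg_ends = np.concatenate([breaks, [m - 1]])

    for lo, hi in zip(seg_starts, seg_ends):
        i = lo
        j = lo - 1  # inclusive right pointer of feasible window
        n_het = n_miss = 0
        while i <= hi:
            if not hom[i]:
                if i > j:
                    j = i
                    n_het = int(het[i])
                    n_miss = int(miss[i])
                i += 1
                n_het -= int(het[i - 1])
                n_miss -= int(miss[i - 1])
                continue
            if j < i:
                j = i
                n_het = int(het[i])
                n_miss = int(miss[i])
            while j + 1 <= hi:
                nh = n_het + int(het[j + 1])
                nm = n_miss + int(miss[j + 1])
                if nh > params.max_het or nm > params.max_missing:
                    break
                j += 1
                n_het, n_miss = nh, nm
            # trim end back to last homozygous SNP in [i, j]
            jt = j
            while jt >= i and not hom[jt]:
                jt -= 1
            if jt >= i:
                n_snps = jt - i + 1
                length = int(pos[jt] - pos[i])
                if n_snps >= params.min_snps and length >= params.min_length_bp:
                    rh = int(het_cum[jt + 1] - het_cum[i])
                    rm = int(miss_cum[jt + 1] - miss_cum[i])
                    out.append((i, jt, rh, rm))
                    # resume after the emitted run (non-overlapping records)
                    i = jt + 1
                    if j < i:
                        j = i - 1
                        n_het = n_miss = 0
                    else:
                        n_het = int(het_cum[j + 1] - het_cum[i])
                        n_miss = int(miss_cum[j + 1] - miss_cum[i])
                    continue
            # no qualifying run starting at i: advance the start
            i += 1
            if i <= j:
                n_het = int(het_cum[j + 1] - het_cum[i])
                n_miss = int(miss_cum[j + 1] - miss_cum[i])
    return out


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Detect runs of homozygosity on the autosomal markers of *dataset*."""
    params = params or ROHParams()
    if not dataset.is_map_sorted():
        raise ValueError("detect_roh requires markers sorted by (chromosome, position)")
    auto_idx = dataset.autosomal_marker_index()
    markers = dataset.markers.iloc[auto_idx]
    g_auto = dataset.genotypes[:, auto_idx]

    records: list[ROHRecord] = []
    sample_ids = [str(s) for s in dataset.samples["sample_id"]]
    chrom_arr = markers["chromosome"].astype(str).to_numpy()
    pos_arr = markers["position_bp"].to_numpy(np.int64)

    chrom_slices = []
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        chrom_slices.append((str(chrom), cols, pos_arr[cols]))

    for si, sid in enumerate(sample_ids):
        row = g_auto[si]
        for chrom, cols, pos in chrom_slices:
            for i, j, nh, nm in _detect_sample_chrom(row[cols], pos, params):
                records.append(
                    ROHRecord(
                        sample_id=sid,
                        chromosome=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        n_snps=j - i + 1,
                        n_het=nh,
                        n_missing=nm,
                    )
                )
    return ROHSet(
        records=records,
        params=params,
        l_auto_bp=autosomal_map_length(dataset.markers),
        sample_ids=sample_ids,
    )


def summarize_roh_bins(
    rohset: ROHSet,
    group_labels: pd.Series | dict,
    bins_mb: list[float] = (0.5, 2, 4, 8, 16),
) -> pd.DataFrame:
    """Per-group mean ROH count and mean total length (Mb) in cumulative bins.

    Bins are open lower bounds: a 3-Mb run counts in the >0.5 and >2 Mb bins
    (length >= bin threshold, with length = end - start).  Means are over all
    individuals in the group, including those with no runs.
    """
    import warnings

    labels = pd.Series(group_labels)
    frame = rohset.to_frame()
    rows = []
    for group in labels.unique():
        members = labels.index[labels == group]
        n = len(members)
        if n == 0:
            warnings.warn(f"empty group {group!r}: means reported as 0", stacklevel=2)
        sub = frame[frame["sample_id"].isin(members)]
        for b in bins_mb:
            in_bin = sub[sub["length_bp"] >= b * 1e6]
            rows.append(
                {
                    "group": group,
                    "bin_mb": b,
                    "mean_count": len(in_bin) / n if n else 0.0,
                    "mean_total_mb": in_bin["length_bp"].sum() / 1e6 / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def snp_incidence(rohset: ROHSet, markers: pd.DataFrame) -> np.ndarray:
    """Per-SNP count of ROH records covering it (0 for non-autosomal SNPs)."""
    from .genotype_io import is_autosome

    chrom_arr = markers["chromosome"].astype(str).to_numpy()
    pos_arr = markers["position_bp"].to_numpy(np.int64)
    counts = np.zeros(len(markers), dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in pd.unique(chrom_arr):
        if is_autosome(chrom):
            by_chrom[str(chrom)] = np.flatnonzero(chrom_arr == chrom)
    for rec in rohset.records:
        cols = by_chrom.get(rec.chromosome)
        if cols is None:
            continue
        pos = pos_arr[cols]
        lo = np.searchsorted(pos, rec.start_bp, side="left")
        hi = np.searchsorted(pos, rec.end_bp, side="right")
        counts[cols[lo:hi]] += 1
    return counts


def compute_f_roh(rohset: ROHSet, min_length_mb: float) -> pd.Series:
    """Per-sample F_ROH = sum of run lengths >= min_length_mb Mb / L_AUTO."""
    if rohset.l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    thr = min_length_mb * 1e6
    totals = {sid: 0.0 for sid in rohset.sample_ids}
    for rec in rohset.records:
        if rec.length_bp >= thr:
            totals[rec.sample_id] = totals.get(rec.sample_id, 0.0) + rec.length_bp
    out = pd.Series(totals, name=f"f_roh_{min_length_mb:g}") / rohset.l_auto_bp
    return out


def f_roh_table(
    rohset: ROHSet, thresholds_mb: tuple[float, ...] = (0.5, 10.0)
) -> pd.DataFrame:
    """F_ROH at the default 0.5-Mb and 10-Mb length thresholds, per sample."""
    cols = {f"f_roh_{t:g}": compute_f_roh(rohset, t) for t in thresholds_mb}
    out = pd.DataFrame(cols)
    out.index.name = "sample_id"
    return out
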