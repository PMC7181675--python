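"""Reading, writing, filtering, and LD-pruning of SNP-array genotype datasets.

Genotypes are held in memory as an ``int8`` sample x marker matrix of
alternate-allele counts (0, 1, 2) with ``-1`` marking missing calls.  A value
of 1 is always the heterozygote, so homozygosity tests are independent of
allele labels.  On disk the dataset uses the de-facto standard binary trio:
a variant-major 2-bit ``.bed`` matrix plus text ``.bim``/``.fam`` tables.

Coordinates are 1-based physical bp.  Intervals elsewhere in this package are
reported as (start_bp, end_bp) inclusive of the terminal SNP positions with
length = end_bp - start_bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "FilesetError",
    "FormatError",
    "GenotypeDataset",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "apply_qc",
    "ld_prune",
    "is_autosome",
    "is_sex_chromosome",
    "chromosome_sort_key",
]

MISSING: int = -1

#: chromosome labels treated as sex-linked / non-autosomal
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "M"})

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "population", "sex", "birth_year"]


class FilesetError(Exception):
    """A companion file of the binary genotype fileset is missing or unusable."""


class FormatError(FilesetError):
    """The fileset is present but internally inconsistent (e.g. truncated)."""


def is_autosome(label: str) -> bool:
    s = str(label)
    return s.isdigit() and s != "0"


def is_sex_chromosome(label: str) -> bool:
    return str(label).upper() in SEX_CHROMOSOMES


def chromosome_sort_key(label: str):
    """Sort numeric chromosomes first (numerically), then X, Y, MT, then unmapped."""
    s = str(label)
    if is_autosome(s):
        return (0, int(s), s)
    order = {"X": 1, "XY": 2, "Y": 3, "MT": 4, "M": 4}
    if s.upper() in order:
        return (order[s.upper()], 0, s)
    return (9, 0, s)  # "0" / unmapped last


@dataclass
class GenotypeDataset:
    """Sample x marker matrix of alternate-allele counts plus its two maps.

    Attributes
    ----------
    genotypes
        ``int8`` array of shape ``(n_samples, n_markers)``; entries in
        ``{0, 1, 2}`` with ``-1`` for missing.
    markers
        DataFrame with columns ``marker_id, chromosome, position_bp,
        allele1, allele2``, sorted by (chromosome, position_bp).
    samples
        DataFrame with columns ``sample_id, population, sex, birth_year``.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise FormatError("genotype matrix must be 2-D (samples x markers)")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise FormatError(
                f"matrix is {n}x{m} but tables have {len(self.samples)} samples "
                f"and {len(self.markers)} markers"
            )
        g = self.genotypes
        bad = (g < -1) | (g > 2)
        if bad.any():
            raise FormatError("genotype entries must be in {0,1,2} or -1 (missing)")
        if self.markers["marker_id"].duplicated().any():
            raise FormatError("marker_id values must be unique")
        if self.samples["sample_id"].duplicated().any():
            raise FormatError("sample_id values must be unique")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeDataset":
        g = self.genotypes
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx, :]
            samples = samples.iloc[sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            g = g[:, marker_idx]
            markers = markers.iloc[marker_idx]
        return GenotypeDataset(g.copy(), markers.copy(), samples.copy())

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.genotypes >= 0).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.genotypes >= 0).mean(axis=1)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls (NaN if none)."""
        g = self.genotypes
        ok = g >= 0
        n_ok = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, g, 0).sum(axis=0) / np.maximum(2 * n_ok, 1)
        return np.where(n_ok > 0, p, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def autosomal_marker_index(self) -> np.ndarray:
        auto = self.markers["chromosome"].map(is_autosome).to_numpy(bool)
        return np.flatnonzero(auto)

    def is_map_sorted(self) -> bool:
        keys = [chromosome_sort_key(c) for c in self.markers["chromosome"]]
        pos = self.markers["position_bp"].to_numpy()
        prev = None
        for k, p in zip(keys, pos):
            cur = (k, int(p))
            if prev is not None and cur < prev:
                return False
            prev = cur
        return True

    def sort_by_map(self) -> "GenotypeDataset":
        order = sorted(
            range(self.n_markers),
            key=lambda i: (
                chromosome_sort_key(self.markers["chromosome"].iat[i]),
                int(self.markers["position_bp"].iat[i]),
            ),
        )
        return self.subset(marker_idx=np.asarray(order, dtype=int))


@dataclass
class QCReport:
    """Ledger of marker and sample removals; counts reconcile by construction."""

    n_markers_input: int = 0
    n_fail_callrate_or_maf: int = 0
    n_unmapped_removed: int = 0
    n_sex_removed: int = 0
    n_markers_retained: int = 0
    n_samples_input: int = 0
    n_samples_removed_callrate: int = 0
    n_samples_removed_dup: int = 0
    n_samples_retained: int = 0
    parameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        got = (
            self.n_markers_input
            - self.n_fail_callrate_or_maf
            - self.n_unmapped_removed
            - self.n_sex_removed
        )
        if got != self.n_markers_retained:
            raise ValueError("QCReport marker counts do not reconcile")
        if (
            self.n_samples_input
            - self.n_samples_removed_callrate
            - self.n_samples_removed_dup
            != self.n_samples_retained
        ):
            raise ValueError("QCReport sample counts do not reconcile")
        for k, v in self.__dict__.items():
            if k.startswith("n_") and v < 0:
                raise ValueError(f"QCReport count {k} is negative")

    def to_text(self) -> str:
        lines = []
        for k, v in self.__dict__.items():
            if k == "parameters":
                continue
            lines.append(f"{k}\t{v}")
        for k, v in self.parameters.items():
            lines.append(f"param.{k}\t{v}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())


# ---------------------------------------------------------------------------
# binary fileset (bed/bim/fam dialect)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # variant-major

# 2-bit code per genotype value: value -> code, code -> value.
# 00 = hom allele1 (0 alt copies), 10 = het, 11 = hom allele2, 01 = missing.
_VALUE_TO_CODE = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
_CODE_TO_VALUE = np.array([0, MISSING, 1, 2], dtype=np.int8)

_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}
_FAM_TO_SEX = {"1": "male", "2": "female"}


def write_genotypes(dataset: GenotypeDataset, fileset_path) -> None:
    """Write *dataset* as ``<fileset_path>.bed/.bim/.fam``."""
    base = Path(fileset_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.genotypes.shape

    # .bim
    bim = dataset.markers.copy()
    bim_out = pd.DataFrame(
        {
            "chromosome": bim["chromosome"].astype(str),
            "marker_id": bim["marker_id"],
            "cm": 0,
            "position_bp": bim["position_bp"].astype(int),
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )
    bim_out.to_csv(base.with_suffix(".bim"), sep="\t", header=False, index=False)

    # .fam: FID=population, IID=sample_id, PID=MID=0, SEX coded, PHENO=birth_year
    fam = dataset.samples.copy()
    years = fam["birth_year"]
    pheno = ["-9" if pd.isna(y) else str(int(y)) for y in years]
    fam_out = pd.DataFrame(
        {
            "fid": fam["population"].astype(str),
            "iid": fam["sample_id"].astype(str),
            "pid": 0,
            "mid": 0,
            "sex": [_SEX_TO_FAM.get(str(s), "0") for s in fam["sex"]],
            "pheno": pheno,
        }
    )
    fam_out.to_csv(base.with_suffix(".fam"), sep="\t", header=False, index=False)

    # .bed, variant-major
    g = dataset.genotypes  # (n, m)
    codes = np.where(g >= 0, _VALUE_TO_CODE[np.clip(g, 0, 2)], 0b01).astype(np.uint8)
    codes = codes.T  # (m, n) variant-major
    n_pad = (-n) % 4
    if n_pad:
        codes = np.concatenate(
            [codes, np.zeros((m, n_pad), dtype=np.uint8)], axis=1
        )
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    try:
        with open(base.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
    except OSError as exc:  # pragma: no cover - environment dependent
        raise FilesetError(f"cannot write {base.with_suffix('.bed')}: {exc}") from exc


def read_genotypes(fileset_path) -> GenotypeDataset:
    """Read a ``.bed/.bim/.fam`` fileset written by :func:`write_genotypes`
    (or any variant-major PLINK-1 style trio)."""
    base = Path(fileset_path)
    paths = {ext: base.with_suffix(ext) for ext in (".bed", ".bim", ".fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise FilesetError(f"missing companion file: {p}")

    bim = pd.read_csv(
        paths[".bim"],
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"chromosome": str, "marker_id": str, "allele1": str, "allele2": str},
    )
    if bim.empty and paths[".bim"].stat().st_size == 0:
        bim = pd.DataFrame(
            columns=["chromosome", "marker_id", "cm", "position_bp", "allele1", "allele2"]
        )
    markers = pd.DataFrame(
        {
            "marker_id": bim["marker_id"],
            "chromosome": bim["chromosome"].astype(str),
            "position_bp": bim["position_bp"].astype(int) if len(bim) else bim["position_bp"],
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )

    fam = pd.read_csv(
        paths[".fam"],
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype=str,
    )
    if fam.empty and paths[".fam"].stat().st_size == 0:
        fam = pd.DataFrame(columns=["fid", "iid", "pid", "mid", "sex", "pheno"])
    birth_year = pd.array(
        [pd.NA if y in ("-9", "NA", None) else int(float(y)) for y in fam["pheno"]],
        dtype="Int64",
    )
    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "population": fam["fid"],
            "sex": [_FAM_TO_SEX.get(str(s), "unknown") for s in fam["sex"]],
            "birth_year": birth_year,
        }
    )

    n, m = len(samples), len(markers)
    raw = paths[".bed"].read_bytes()
    if len(raw) < 3 or raw[:3] != _BED_MAGIC:
        raise FormatError(f"{paths['.bed']} lacks the variant-major magic header")
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise FormatError(
            f"{paths['.bed']} has {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} markers"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    genotypes = _CODE_TO_VALUE[codes[:, :n]].T.copy()  # (n, m)
    return GenotypeDataset(genotypes, markers, samples)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    dataset: GenotypeDataset,
    marker_call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    sample_call_rate_min: float = 0.95,
    ibd_dup_threshold: float = 0.75,
    drop_unmapped: bool = True,
    drop_sex: bool = True,
) -> tuple[GenotypeDataset, QCReport]:
    """Filter samples and markers, returning the retained dataset and a ledger.

    Order of operations (recorded in the report): sample call-rate filter
    first, then marker call-rate/MAF on the retained samples, then removal of
    unmapped and sex-chromosome markers, and finally IBD-based sample
    de-duplication (pi-hat >= *ibd_dup_threshold* drops the lower-call-rate
    member of each offending pair).  Call-rate and MAF filters are strict
    (``>``), matching ">95%" / ">5%" style thresholds.
    """
    if dataset.n_samples == 0 or dataset.n_markers == 0:
        raise ValueError("apply_qc requires a nonempty dataset")

    report = QCReport(
        n_markers_input=dataset.n_markers,
        n_samples_input=dataset.n_samples,
        parameters={
            "marker_call_rate_min": marker_call_rate_min,
            "maf_min": maf_min,
            "sample_call_rate_min": sample_call_rate_min,
            "ibd_dup_threshold": ibd_dup_threshold,
            "drop_unmapped": drop_unmapped,
            "drop_sex": drop_sex,
            "order": "samples_callrate,markers,ibd_dedup",
        },
    )

    # 1. sample call rate (on the full input marker set)
    scr = dataset.sample_call_rate()
    keep_samples = scr > sample_call_rate_min
    report.n_samples_removed_callrate = int((~keep_samples).sum())
    ds = dataset.subset(sample_idx=np.flatnonzero(keep_samples))

    # 2. marker call rate and MAF on the post-sample-filter set
    mcr = ds.marker_call_rate()
    maf = ds.minor_allele_freq()
    pass_cr_maf = (mcr > marker_call_rate_min) & (np.nan_to_num(maf, nan=0.0) > maf_min)
    report.n_fail_callrate_or_maf = int((~pass_cr_maf).sum())

    chrom = ds.markers["chromosome"].astype(str)
    pos = ds.markers["position_bp"].to_numpy()
    unmapped = (chrom == "0") | (chrom == "") | (pos <= 0)
    sexlinked = chrom.map(is_sex_chromosome).to_numpy(bool)

    keep = pass_cr_maf.copy()
    if drop_unmapped:
        report.n_unmapped_removed = int((keep & unmapped).sum())
        keep &= ~unmapped
    if drop_sex:
        report.n_sex_removed = int((keep & sexlinked).sum())
        keep &= ~sexlinked
    report.n_markers_retained = int(keep.sum())
    ds = ds.subset(marker_idx=np.flatnonzero(keep))

    if ds.n_markers == 0:
        warnings.warn("apply_qc removed every marker", stacklevel=2)

    # 3. IBD de-duplication on the filtered markers
    n_dup = 0
    if ds.n_samples >= 2 and ds.n_markers > 0 and ibd_dup_threshold is not None:
        from .population_structure import ibd_matrix  # deferred: avoids cycle

        kin = ibd_matrix(ds)
        pi = kin.pi_hat.copy()
        np.fill_diagonal(pi, 0.0)
        call = ds.sample_call_rate()
        alive = np.ones(ds.n_samples, dtype=bool)
        while True:
            masked = np.where(np.outer(alive, alive), pi, 0.0)
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            if masked[i, j] < ibd_dup_threshold:
                break
            drop = i if call[i] <= call[j] else j
            alive[drop] = False
            n_dup += 1
        ds = ds.subset(sample_idx=np.flatnonzero(alive))
    report.n_samples_removed_dup = n_dup
    report.n_samples_retained = ds.n_samples
    report.validate()
    return ds, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns, pairwise-complete over
    non-missing entries.  Monomorphic (zero-variance) pairs give r2 = 0."""
    g = g.astype(np.float64)
    mask = g >= 0
    x = np.where(mask, g, 0.0)
    m = mask.astype(np.float64)
    n = m.T @ m  # joint non-missing counts
    sx = x.T @ m
    sy = m.T @ x
    sxy = x.T @ x
    sxx = (x * x).T @ m
    syy = m.T @ (x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2 = np.where((n >= 2) & (vx > 0) & (vy > 0), r2, 0.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(
    dataset: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> list[int]:
    """Greedy windowed LD pruning; returns retained marker indices.

    Windows of *window_snps* markers slide in *step_snps* increments within
    each chromosome.  Inside a window every retained pair must have
    r2 < *r2_max*; of an offending pair the later-positioned marker is
    removed.  Monomorphic markers are never pruned (their r2 is taken as 0).
    """
    if not dataset.is_map_sorted():
        raise ValueError("ld_prune requires the dataset sorted by map order")
    removed = np.zeros(dataset.n_markers, dtype=bool)
    chroms = dataset.markers["chromosome"].astype(str).to_numpy()
    g_all = dataset.genotypes

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        mc = len(idx)
        start = 0
        while start < mc:
            win = idx[start : start + window_snps]
            alive = win[~removed[win]]
            if len(alive) >= 2:
                r2 = _pairwise_r2(g_all[:, alive])
                k = len(alive)
                local_alive = np.ones(k, dtype=bool)
                for a in range(k):
                    if not local_alive[a]:
                        continue
                    for b in range(a + 1, k):
                        if local_alive[b] and r2[a, b] >= r2_max:
                            local_alive[b] = False
                            removed[alive[b]] = True
            if start + window_snps >= mc:
                break
            start += step_snps
    return [int(i) for i in np.flatnonzero(~removed)]
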