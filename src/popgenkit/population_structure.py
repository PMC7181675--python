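"""Pairwise IBD (pi-hat), individual inbreeding f, PCA with HWE
normalization, decade trends, group comparison, and Y-haplotype tabulation.

IBD follows the method-of-moments route: observed identity-by-state sharing
counts per pair are compared with their expectations under IBD states
Z in {0,1,2}, where the expectations are unbiased frequency-moment estimates
from the pooled sample (the small-sample correction).  pi-hat =
P(Z=1)/2 + P(Z=2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset

__all__ = [
    "KinshipEstimate",
    "PCAResult",
    "ibd_matrix",
    "inbreeding_f",
    "decade_means",
    "compare_groups_f",
    "pca",
    "tabulate_haplotypes",
]

MIN_JOINT_MARKERS = 50


@dataclass
class KinshipEstimate:
    """Pairwise IBD-state probabilities and pi-hat (symmetric n x n arrays)."""

    sample_ids: list[str]
    z0: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    pi_hat: np.ndarray
    n_joint: np.ndarray
    unreliable: np.ndarray  # pairs with < MIN_JOINT_MARKERS joint markers

    def pair(self, id_a: str, id_b: str) -> float:
        i = self.sample_ids.index(id_a)
        j = self.sample_ids.index(id_b)
        return float(self.pi_hat[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pi_hat, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components), unit-norm eigenvectors
    eigenvalues: np.ndarray  # nonincreasing

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def _ibs_expectations(dataset: GenotypeDataset):
    """Per-marker E[IBS class | IBD state] from unbiased frequency moments.

    With X alt alleles out of T observed, products like p^2 q^2 are estimated
    by falling-factorial ratios, e.g. X(X-1)Y(Y-1) / T(T-1)(T-2)(T-3).
    """
    g = dataset.genotypes
    ok = g >= 0
    X = np.where(ok, g, 0).sum(axis=0).astype(float)
    T = (2 * ok.sum(axis=0)).astype(float)
    Y = T - X
    with np.errstate(invalid="ignore", divide="ignore"):
        d4 = T * (T - 1) * (T - 2) * (T - 3)
        d3 = T * (T - 1) * (T - 2)
        e00 = 2.0 * X * (X - 1) * Y * (Y - 1) / d4
        e10 = 4.0 * (X * (X - 1) * (X - 2) * Y + Y * (Y - 1) * (Y - 2) * X) / d4
        e11 = 2.0 * (X * (X - 1) * Y + Y * (Y - 1) * X) / d3
    usable = T >= 4
    e00 = np.where(usable, np.nan_to_num(e00), 0.0)
    e10 = np.where(usable, np.nan_to_num(e10), 0.0)
    e11 = np.where(usable, np.nan_to_num(e11), 0.0)
    e20 = np.where(usable, 1.0 - e00 - e10, 0.0)
    e21 = np.where(usable, 1.0 - e11, 0.0)
    return e00, e10, e20, e11, e21, usable


def ibd_matrix(dataset: GenotypeDataset) -> KinshipEstimate:
    """Method-of-moments IBD estimation for every sample pair.

    Estimates are bounded into [0, 1] and renormalized; pairs with fewer than
    50 jointly non-missing markers are flagged unreliable.  The caller should
    supply an LD-pruned marker set.
    """
    n, m = dataset.genotypes.shape
    e00, e10, e20, e11, e21, usable = _ibs_expectations(dataset)
    g = dataset.genotypes
    ok = (g >= 0) & usable[None, :]

    z0 = np.zeros((n, n))
    z1 = np.zeros((n, n))
    z2 = np.zeros((n, n))
    n_joint = np.zeros((n, n), dtype=np.int64)

    for i in range(n):
        gi = g[i]
        oki = ok[i]
        for j in range(i + 1, n):
            joint = oki & ok[j]
            nj = int(joint.sum())
            n_joint[i, j] = n_joint[j, i] = nj
            if nj == 0:
                continue
            d = np.abs(gi[joint] - g[j][joint])
            n0 = int((d == 2).sum())
            n1 = int((d == 1).sum())
            n2 = nj - n0 - n1
            s00 = e00[joint].sum()
            s10 = e10[joint].sum()
            s20 = e20[joint].sum()
            s11 = e11[joint].sum()
            s21 = e21[joint].sum()
            p0 = n0 / s00 if s00 > 0 else 0.0
            p1 = (n1 - p0 * s10) / s11 if s11 > 0 else 0.0
            p2 = (n2 - p0 * s20 - p1 * s21) / nj
            z = np.array([p0, p1, p2])
            # bound impossible values, then renormalize
            z = np.clip(z, 0.0, 1.0)
            total = z.sum()
            z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
            z0[i, j] = z0[j, i] = z[0]
            z1[i, j] = z1[j, i] = z[1]
            z2[i, j] = z2[j, i] = z[2]
    np.fill_diagonal(z2, 1.0)
    np.fill_diagonal(n_joint, (g >= 0).sum(axis=1))
    pi = np.clip(z1 / 2.0 + z2, 0.0, 1.0)
    return KinshipEstimate(
        sample_ids=[str(s) for s in dataset.samples["sample_id"]],
        z0=z0,
        z1=z1,
        z2=z2,
        pi_hat=pi,
        n_joint=n_joint,
        unreliable=n_joint < MIN_JOINT_MARKERS,
    )


def inbreeding_f(dataset: GenotypeDataset, freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-sample f = (O_hom - E_hom) / (L - E_hom) over non-missing markers.

    E_hom uses the unbiased expected heterozygosity 2 p q 2n/(2n-1) with
    allele frequencies from the pooled analyzed samples (or *freqs* if
    supplied; the 2n correction then still uses the per-marker call counts).
    """
    g = dataset.genotypes
    ok = g >= 0
    n_calls = ok.sum(axis=0)
    if freqs is None:
        p = dataset.alt_allele_freq()
    else:
        p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    alleles = 2.0 * n_calls
    with np.errstate(invalid="ignore", divide="ignore"):
        het_exp = 2.0 * p * q * alleles / np.maximum(alleles - 1.0, 1.0)
    het_exp = np.nan_to_num(het_exp)
    poly = np.nan_to_num(p * q) > 0
    if not poly.any():
        raise ValueError("inbreeding_f undefined: all markers monomorphic")

    hom = ((g == 0) | (g == 2)) & ok
    o_hom = hom.sum(axis=1).astype(float)
    e_hom = (ok * (1.0 - het_exp)[None, :]).sum(axis=1)
    L = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / (L - e_hom)
    out = pd.DataFrame(
        {
            "sample_id": dataset.samples["sample_id"].to_numpy(),
            "f": f,
            "observed_hom": o_hom,
            "expected_hom": e_hom,
            "n_used": L.astype(int),
            "population": dataset.samples["population"].to_numpy(),
            "birth_year": dataset.samples["birth_year"].to_numpy(),
        }
    )
    return out


def decade_means(table: pd.DataFrame, group_column: str = "population") -> pd.DataFrame:
    """Mean f per (group, decade); samples without birth_year are excluded
    and tallied in the ``n_missing_year`` attribute column of the result."""
    t = table.copy()
    known = t["birth_year"].notna()
    t = t[known]
    t["decade"] = (t["birth_year"].astype(float) // 10 * 10).astype(int)
    out = (
        t.groupby([group_column, "decade"], observed=True)["f"]
        .agg(mean_f="mean", n="size")
        .reset_index()
    )
    out.attrs["n_missing_year"] = int((~known).sum())
    return out


def compare_groups_f(
    table: pd.DataFrame, group_a: str, group_b: str, group_column: str = "population"
) -> tuple[float, float, dict]:
    """Welch's two-sided t-test on per-sample f between two groups."""
    fa = table.loc[table[group_column] == group_a, "f"].to_numpy(float)
    fb = table.loc[table[group_column] == group_b, "f"].to_numpy(float)
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("both groups need at least 2 samples")
    means = {group_a: float(fa.mean()), group_b: float(fb.mean())}
    if fa.std() == 0 and fb.std() == 0:
        if fa.mean() == fb.mean():
            return 0.0, 1.0, means
    t, p = stats.ttest_ind(fa, fb, equal_var=False)
    return float(t), float(p), means


def pca(dataset: GenotypeDataset, n_components: int = 10) -> PCAResult:
    """PCA of HWE-normalized genotypes.

    Each marker column is centered by 2 p-hat and scaled by its theoretical
    HWE standard deviation sqrt(2 p-hat q-hat); missing entries are
    mean-imputed (zero after centering).  Scores are the unit-norm
    eigenvectors of the sample-by-sample covariance ``Z Z' / m``; eigenvalues
    are nonincreasing.
    """
    g = dataset.genotypes.astype(float)
    ok = dataset.genotypes >= 0
    p = dataset.alt_allele_freq()
    var = 2.0 * p * (1.0 - p)
    poly = np.nan_to_num(var) > 0
    if poly.sum() == 0:
        raise ValueError("no polymorphic markers for PCA")
    g = g[:, poly]
    ok = ok[:, poly]
    p = p[poly]
    sd = np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(ok, (g - 2.0 * p[None, :]) / sd[None, :], 0.0)

    n, m = z.shape
    max_comp = min(n, m)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clipped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    cov = z @ z.T / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    return PCAResult(
        sample_ids=[str(s) for s in dataset.samples["sample_id"]],
        scores=evecs[:, order],
        eigenvalues=np.maximum(evals[order], 0.0),
    )


def tabulate_haplotypes(
    calls: pd.DataFrame, missing_token: str = "?"
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Haplotype strings over hemizygous markers, their counts, and Hamming
    distances between distinct complete haplotypes.

    *calls* is a sample x marker frame with entries in {0, 2} (hemizygous
    calls coded like homozygotes) or -1/NaN for missing.  Samples with any
    heterozygous call (1) are flagged as genotyping anomalies and excluded;
    samples with missing calls are grouped separately under haplotypes
    containing the missing token.

    Returns (counts, hamming_distance_frame, excluded_sample_ids).
    """
    arr = calls.to_numpy()
    excluded: list[str] = []
    haplotypes: dict[str, str] = {}
    for i, sid in enumerate(calls.index):
        row = arr[i]
        if (row == 1).any():
            excluded.append(str(sid))
            continue
        symbols = []
        for v in row:
            if pd.isna(v) or v < 0:
                symbols.append(missing_token)
            else:
                symbols.append("A" if v == 0 else "B")
        haplotypes[str(sid)] = "".join(symbols)
    counts = pd.Series(haplotypes, dtype=object).value_counts()
    complete = [h for h in counts.index if missing_token not in h]
    dist = pd.DataFrame(0, index=complete, columns=complete, dtype=int)
    for a in complete:
        for b in complete:
            dist.loc[a, b] = sum(x != y for x, y in zip(a, b))
    return counts, dist, excluded
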