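"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths: the ROH enumerator is an
O(m^2) sub-interval filter, the theta oracle is a scalar transcription of the
variance-components formulas, and the kinship moments oracle works from raw
IBS sharing.  They exist so the fast implementations can be checked against
slow-but-obvious ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popgenkit.genotype_io import GenotypeDataset


def make_dataset(g, chrom=None, pos=None, populations=None, birth_years=None):
    """Small-dataset builder for tests."""
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = (np.arange(m) + 1) * 10_000
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{i}" for i in range(m)],
            "chromosome": [str(c) for c in chrom],
            "position_bp": np.asarray(pos, dtype=np.int64),
            "allele1": "A",
            "allele2": "B",
        }
    )
    if populations is None:
        populations = ["P"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations,
            "sex": "male",
            "birth_year": birth_years if birth_years is not None else 2000,
        }
    )
    return GenotypeDataset(g, markers, samples)


# ---------------------------------------------------------------------------
# ROH brute force
# ---------------------------------------------------------------------------

def roh_brute_force(g, pos, params):
    """All qualifying homozygous sub-intervals, resolved to the
    leftmost-start / longest-end non-overlapping set.

    Returns a list of (start_idx, end_idx) marker-index pairs.
    """
    g = np.asarray(g)
    pos = np.asarray(pos)
    m = len(g)
    het = g == 1
    miss = g < 0
    hom = ~het & ~miss
    hc = np.concatenate([[0], np.cumsum(het)])
    mc = np.concatenate([[0], np.cumsum(miss)])
    block = np.concatenate([[0], np.cumsum(np.diff(pos) > params.max_gap_bp)])

    cands = []
    for i in range(m):
        if not hom[i]:
            continue
        for j in range(i, m):
            if block[j] != block[i]:
                break
            if hc[j + 1] - hc[i] > params.max_het:
                break
            if mc[j + 1] - mc[i] > params.max_missing:
                continue
            if not hom[j]:
                continue
            if j - i + 1 >= params.min_snps and pos[j] - pos[i] >= params.min_length_bp:
                cands.append((i, j))
    cands.sort(key=lambda t: (t[0], -t[1]))
    out, last_end = [], -1
    for i, j in cands:
        if i > last_end:
            out.append((i, j))
            last_end = j
    return out


def roh_candidate_union_bp(g, pos, params):
    """Total bp covered by the union of ALL qualifying sub-intervals.

    Unlike the greedy non-overlapping selection, this union is monotone under
    relaxation of any single constraint (the candidate set only grows).
    """
    g = np.asarray(g)
    pos = np.asarray(pos)
    m = len(g)
    het = g == 1
    miss = g < 0
    hom = ~het & ~miss
    hc = np.concatenate([[0], np.cumsum(het)])
    mc = np.concatenate([[0], np.cumsum(miss)])
    block = np.concatenate([[0], np.cumsum(np.diff(pos) > params.max_gap_bp)])
    intervals = []
    for i in range(m):
        if not hom[i]:
            continue
        for j in range(i, m):
            if block[j] != block[i] or hc[j + 1] - hc[i] > params.max_het:
                break
            if mc[j + 1] - mc[i] > params.max_missing or not hom[j]:
                continue
            if j - i + 1 >= params.min_snps and pos[j] - pos[i] >= params.min_length_bp:
                intervals.append((int(pos[i]), int(pos[j])))
    intervals.sort()
    total, cur_start, cur_end = 0, None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


# ---------------------------------------------------------------------------
# Weir & Cockerham theta, scalar transcription (two or more groups)
# ---------------------------------------------------------------------------

def wc_theta_oracle(genotype_counts):
    """Theta from per-group genotype counts [(n0, n1, n2), ...] at one marker.

    n0/n1/n2 are counts of 0-, 1-, 2-alt genotypes.  Returns the unclamped
    ratio a / (a + b + c).
    """
    r = len(genotype_counts)
    n = [c0 + c1 + c2 for (c0, c1, c2) in genotype_counts]
    p = [(c1 + 2 * c2) / (2 * ni) for (c0, c1, c2), ni in zip(genotype_counts, n)]
    h = [c1 / ni for (c0, c1, c2), ni in zip(genotype_counts, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else 0.0


def genotype_counts_to_matrix(counts):
    """Expand (n0, n1, n2) genotype counts into a genotype row vector."""
    n0, n1, n2 = counts
    return np.array([0] * n0 + [1] * n1 + [2] * n2, dtype=np.int8)
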