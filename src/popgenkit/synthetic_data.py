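"""Synthetic genotype datasets with known ground truth.

Populations diverge from a common ancestral allele-frequency spectrum under
the Balding–Nichols Beta model; within-individual inbreeding deflates
heterozygosity; autozygous (ROH) tracts are planted at known coordinates; and
two fixed relationship constructions (a duplicate pair and a parent–offspring
pair) provide kinship anchors.  Sites are simulated independently — no
background LD — so every downstream expectation has a closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, write_genotypes

__all__ = [
    "PlantedROH",
    "SimConfig",
    "SimTruth",
    "balding_nichols_freqs",
    "simulate_dataset",
    "write_truth",
]


@dataclass(frozen=True)
class PlantedROH:
    """An autozygous tract to impose on carriers.

    ``selector`` is a population label (tract planted in a carrier_fraction
    of that population) or a single sample_id.
    """

    selector: str
    chromosome: str
    start_bp: int
    end_bp: int
    carrier_fraction: float = 1.0


@dataclass
class SimConfig:
    n_pops: int = 2
    n_per_pop: int | list[int] = 25
    n_chromosomes: int = 2
    chrom_length_bp: int = 20_000_000
    snp_spacing_mean_bp: int = 3_500
    divergence_F: float | list[float] = 0.1
    within_inbreeding_Fis: float | list[float] = 0.0
    missing_rate: float = 0.0
    planted_roh: list[PlantedROH] = field(default_factory=list)
    decade_range: tuple[int, int] = (1960, 2009)
    seed: int = 0
    pop_labels: list[str] | None = None
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    relationship_constructions: bool = True

    def counts(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop list must have n_pops entries")
        return list(self.n_per_pop)

    def labels(self) -> list[str]:
        if self.pop_labels is not None:
            if len(self.pop_labels) != self.n_pops:
                raise ValueError("pop_labels must have n_pops entries")
            return list(self.pop_labels)
        return [f"POP{i + 1}" for i in range(self.n_pops)]

    def per_pop(self, value) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * self.n_pops
        if len(value) != self.n_pops:
            raise ValueError("per-population parameter has wrong length")
        return [float(v) for v in value]

    def validate(self) -> None:
        chrom_names = {str(c + 1) for c in range(self.n_chromosomes)}
        for tract in self.planted_roh:
            if not (0.0 <= tract.carrier_fraction <= 1.0):
                raise ValueError("carrier_fraction must be in [0,1]")
            if str(tract.chromosome) not in chrom_names:
                raise ValueError(f"planted ROH on unknown chromosome {tract.chromosome}")
            if not (1 <= tract.start_bp < tract.end_bp <= self.chrom_length_bp):
                raise ValueError(
                    f"planted interval {tract.start_bp}-{tract.end_bp} outside "
                    f"chromosome bounds (1..{self.chrom_length_bp})"
                )
        for F in self.per_pop(self.divergence_F):
            if not (0.0 <= F < 1.0):
                raise ValueError("divergence_F must be in [0,1)")
        for fis in self.per_pop(self.within_inbreeding_Fis):
            if not (0.0 <= fis < 1.0):
                raise ValueError("within_inbreeding_Fis must be in [0,1)")


@dataclass
class SimTruth:
    ancestral_freqs: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    true_roh: list[tuple[str, str, int, int]]  # sample_id, chrom, start, end
    relationship_pairs: list[tuple[str, str, float]]  # id, id, expected pi-hat
    divergence_F: list[float]
    config: SimConfig


def balding_nichols_freqs(
    ancestral_p: float, F: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies under the Balding–Nichols model.

    Frequencies are drawn Beta(p(1-F)/F, (1-p)(1-F)/F), with mean
    *ancestral_p* and variance F.p(1-p).  F = 0 degenerates to the ancestral
    frequency for every population.
    """
    if not (0.0 < ancestral_p < 1.0):
        raise ValueError("ancestral_p must be strictly inside (0,1)")
    if F == 0.0:
        return np.full(n_pops, ancestral_p)
    if not (0.0 < F < 1.0):
        raise ValueError("F must be in [0,1)")
    scale = (1.0 - F) / F
    return rng.beta(ancestral_p * scale, (1.0 - ancestral_p) * scale, size=n_pops)


def _draw_genotypes(
    p: np.ndarray, n: int, fis: float, rng: np.random.Generator
) -> np.ndarray:
    """n individuals at len(p) sites with P(het) = 2p(1-p)(1-Fis)."""
    m = len(p)
    auto = rng.random((n, m)) < fis  # autozygous indicator
    hom = 2 * (rng.random((n, m)) < p).astype(np.int8)
    a1 = (rng.random((n, m)) < p).astype(np.int8)
    a2 = (rng.random((n, m)) < p).astype(np.int8)
    return np.where(auto, hom, a1 + a2).astype(np.int8)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Generate a :class:`GenotypeDataset` plus its :class:`SimTruth`.

    Identical configs (including seed) reproduce identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    labels = config.labels()
    Fs = config.per_pop(config.divergence_F)
    fis = config.per_pop(config.within_inbreeding_Fis)

    # marker map: exponential spacing per chromosome
    chrom_col, pos_col = [], []
    for c in range(config.n_chromosomes):
        pos = []
        cur = 1 + rng.integers(0, config.snp_spacing_mean_bp)
        while cur <= config.chrom_length_bp:
            pos.append(int(cur))
            cur += 1 + int(rng.exponential(config.snp_spacing_mean_bp))
        chrom_col.extend([str(c + 1)] * len(pos))
        pos_col.extend(pos)
    m = len(pos_col)
    markers = pd.DataFrame(
        {
            "marker_id": [f"SNP{c}_{i:07d}" for i, c in enumerate(chrom_col)],
            "chromosome": chrom_col,
            "position_bp": pos_col,
            "allele1": "A",
            "allele2": "B",
        }
    )
    chrom_arr = np.asarray(chrom_col)
    pos_arr = np.asarray(pos_col, dtype=np.int64)

    lo, hi = config.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=m)
    pop_freqs: dict[str, np.ndarray] = {}
    for k, label in enumerate(labels):
        if Fs[k] == 0.0:
            pop_freqs[label] = ancestral.copy()
        else:
            scale = (1.0 - Fs[k]) / Fs[k]
            pop_freqs[label] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)

    blocks, sample_ids, sample_pops = [], [], []
    for k, label in enumerate(labels):
        blocks.append(_draw_genotypes(pop_freqs[label], counts[k], fis[k], rng))
        sample_ids.extend(f"{label}_S{i + 1:03d}" for i in range(counts[k]))
        sample_pops.extend([label] * counts[k])
    g = np.concatenate(blocks, axis=0) if blocks else np.empty((0, m), np.int8)
    sample_ids = np.asarray(sample_ids, dtype=object)

    # fixed relationship constructions in the first population
    relationship_pairs: list[tuple[str, str, float]] = []
    if config.relationship_constructions and counts and counts[0] >= 3:
        p0 = pop_freqs[labels[0]]
        g[1] = g[0]  # duplicate
        transmitted = (rng.random(m) < g[0] / 2.0).astype(np.int8)
        other = (rng.random(m) < p0).astype(np.int8)
        g[2] = transmitted + other  # parent -> offspring
        relationship_pairs.append((str(sample_ids[0]), str(sample_ids[1]), 1.0))
        relationship_pairs.append((str(sample_ids[0]), str(sample_ids[2]), 0.5))

    # planted autozygous tracts: copy one haplotype across the interval
    true_roh: list[tuple[str, str, int, int]] = []
    pop_of = np.asarray(sample_pops, dtype=object)
    for tract in config.planted_roh:
        in_interval = (
            (chrom_arr == str(tract.chromosome))
            & (pos_arr >= tract.start_bp)
            & (pos_arr <= tract.end_bp)
        )
        cols = np.flatnonzero(in_interval)
        if tract.selector in labels:
            pool = np.flatnonzero(pop_of == tract.selector)
            n_carriers = int(round(tract.carrier_fraction * len(pool)))
            carriers = rng.choice(pool, size=n_carriers, replace=False) if n_carriers else []
        else:
            hits = np.flatnonzero(sample_ids == tract.selector)
            if len(hits) == 0:
                raise ValueError(f"planted ROH selector {tract.selector!r} not found")
            carriers = hits
        for s in np.sort(np.asarray(carriers, dtype=int)):
            row = g[s, cols]
            hets = row == 1
            row[hets] = 2 * (rng.random(hets.sum()) < 0.5).astype(np.int8)
            g[s, cols] = row
            true_roh.append(
                (str(sample_ids[s]), str(tract.chromosome), tract.start_bp, tract.end_bp)
            )

    # missingness after truth recording
    if config.missing_rate > 0:
        mask = rng.random(g.shape) < config.missing_rate
        g[mask] = MISSING

    y0, y1 = config.decade_range
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": sample_pops,
            "sex": "male",
            "birth_year": rng.integers(y0, y1 + 1, size=len(sample_ids)),
        }
    )
    dataset = GenotypeDataset(g, markers, samples)
    truth = SimTruth(
        ancestral_freqs=ancestral,
        pop_freqs=pop_freqs,
        true_roh=true_roh,
        relationship_pairs=relationship_pairs,
        divergence_F=Fs,
        config=config,
    )
    return dataset, truth


def write_truth(truth: SimTruth, out_prefix) -> None:
    """Write the planted-tract table (TSV) and a JSON truth summary."""
    base = Path(out_prefix)
    base.parent.mkdir(parents=True, exist_ok=True)
    roh = pd.DataFrame(
        truth.true_roh, columns=["sample_id", "chromosome", "start_bp", "end_bp"]
    )
    roh.to_csv(base.with_suffix(".true_roh.tsv"), sep="\t", index=False)
    summary = {
        "divergence_F": truth.divergence_F,
        "n_markers": int(len(truth.ancestral_freqs)),
        "populations": {k: int(len(v)) for k, v in truth.pop_freqs.items()},
        "relationship_pairs": [list(p) for p in truth.relationship_pairs],
        "n_planted_roh": len(truth.true_roh),
        "seed": truth.config.seed,
    }
    base.with_suffix(".truth.json").write_text(json.dumps(summary, indent=2) + "\n")


def write_fileset(dataset: GenotypeDataset, truth: SimTruth, out_prefix) -> None:
    """Emit the binary genotype fileset together with the truth tables."""
    write_genotypes(dataset, out_prefix)
    write_truth(truth, out_prefix)
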