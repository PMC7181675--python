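"""End-to-end orchestration: QC -> prune -> structure -> ROH -> clusters ->
association -> F_ST scan -> reports, from a single seeded config.

Every stage writes its numeric outputs to the output directory; downstream
stage entry points reload those artifacts, so a stage can be re-run in
isolation with identical results.  A manifest records all parameter values
and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import (
    GenotypeDataset,
    QCReport,
    apply_qc,
    ld_prune,
    read_genotypes,
    write_genotypes,
)
from .population_structure import (
    compare_groups_f,
    decade_means,
    ibd_matrix,
    inbreeding_f,
    pca,
)
from .roh_clustering import (
    call_incidence_regions,
    find_clusters,
    homozygosity_association,
    membership_matrix,
)
from .roh_detection import (
    ROHParams,
    detect_roh,
    f_roh_table,
    snp_incidence,
    summarize_roh_bins,
)
from .selection_fst import (
    call_regions,
    manhattan_plot,
    marker_fst,
    pairwise_population_fst,
    regions_to_frame,
)
from .synthetic_data import PlantedROH, SimConfig, simulate_dataset, write_truth

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "generate_report"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message

    def record(self) -> dict:
        return {"stage": self.stage, "error": self.message}


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline.

    Exactly one of ``fileset`` (path prefix of a bed/bim/fam trio) or
    ``simulation`` (a :class:`SimConfig` or its mapping) must be given.
    """

    fileset: str | None = None
    simulation: SimConfig | dict | None = None
    out_dir: str = "popgenkit_out"
    seed: int = 1

    group_column: str = "population"
    group_a: str | None = None  # defaults: first two labels encountered
    group_b: str | None = None

    # module parameter blocks (defaults follow the published analysis)
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    cluster_min_members: int = 5
    seed_mult: float = 7.0
    ext_mult: float = 5.0
    pad_bp: int = 500_000
    strict_padding: bool = False
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5
    pca_components: int = 10
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.get("simulation")
        if isinstance(sim, dict):
            sim = dict(sim)
            planted = [
                PlantedROH(**t) if isinstance(t, dict) else PlantedROH(*t)
                for t in sim.pop("planted_roh", [])
            ]
            raw["simulation"] = SimConfig(planted_roh=planted, **sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.fileset is None) == (self.simulation is None):
            raise ValueError("exactly one of fileset/simulation must be set")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.simulation, SimConfig):
            d["simulation"] = dataclasses.asdict(self.simulation)
        d["version"] = __version__
        return d


def _load_dataset(config: PipelineConfig, out: Path) -> GenotypeDataset:
    if config.fileset is not None:
        return read_genotypes(config.fileset)
    sim = config.simulation
    if isinstance(sim, dict):
        sim = SimConfig(**sim)
    sim = dataclasses.replace(sim, seed=sim.seed if sim.seed else config.seed)
    dataset, truth = simulate_dataset(sim)
    write_genotypes(dataset, out / "simulated")
    write_truth(truth, out / "simulated")
    return dataset

def _resolve_groups(config: PipelineConfig, dataset: GenotypeDataset):
    labels = dataset.samples[config.group_column]
    present = list(pd.unique(labels.dropna()))
    a = config.group_a if config.group_a is not None else (present[0] if present else None)
    b = config.group_b if config.group_b is not None else (present[1] if len(present) > 1 else None)
    for g in (a, b):
        if g is not None and g not in present:
            raise PipelineError("config", f"group label {g!r} not found in column "
                                          f"{config.group_column!r} (have {present})")
    return a, b


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2) + "\n")

    # ---- load / simulate
    try:
        dataset = _load_dataset(config, out)
        dataset = dataset.sort_by_map()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    group_a, group_b = _resolve_groups(config, dataset)

    # ---- QC
    try:
        qcd, qc_report = apply_qc(dataset, **config.qc)
        qc_report.write(out / "qc_report.txt")
        bundle["qc_report"] = qc_report
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    labels = qcd.samples[config.group_column]
    two_group = pd.Series(
        np.where(labels == group_a, group_a, np.where(labels == group_b, group_b, None)),
        index=qcd.samples["sample_id"],
    ) if group_a is not None and group_b is not None else None

    # ---- LD prune + structure
    try:
        pruned_idx = ld_prune(
            qcd, config.ld_window_snps, config.ld_step_snps, config.ld_r2_max
        )
        pd.Series(pruned_idx, name="marker_index").to_csv(
            out / "ld_pruned_indices.tsv", sep="\t", index=False
        )
        pruned = qcd.subset(marker_idx=pruned_idx)

        pca_res = pca(qcd, config.pca_components)
        pca_res.to_frame().to_csv(out / "pca_scores.tsv", sep="\t")
        pd.Series(pca_res.eigenvalues, name="eigenvalue").to_csv(
            out / "pca_eigenvalues.tsv", sep="\t", index=False
        )
        kin = ibd_matrix(pruned)
        kin.to_frame().to_csv(out / "pi_hat.tsv", sep="\t")
        f_table = inbreeding_f(pruned)
        f_table.to_csv(out / "inbreeding_f.tsv", sep="\t", index=False)
        decades = decade_means(f_table, config.group_column)
        decades.to_csv(out / "f_by_decade.tsv", sep="\t", index=False)
        bundle.update(
            pca=pca_res, kinship=kin, f_table=f_table, decade_means=decades,
            n_pruned=len(pruned_idx),
        )
        if group_a is not None and group_b is not None:
            t, p, means = compare_groups_f(f_table, group_a, group_b, config.group_column)
            bundle["f_comparison"] = {"t": t, "p": p, "means": means}
        if len(pd.unique(labels.dropna())) >= 2:
            fst_matrix = pairwise_population_fst(qcd, labels)
            fst_matrix.to_csv(out / "pairwise_fst.tsv", sep="\t")
            bundle["pairwise_fst"] = fst_matrix
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("structure", str(exc)) from exc

    # ---- ROH
    try:
        roh_params = ROHParams(**config.roh)
        rohset = detect_roh(qcd, roh_params)
        rohset.write(out / "roh.tsv")
        froh = f_roh_table(rohset)
        froh.to_csv(out / "f_roh.tsv", sep="\t")
        groups_series = pd.Series(
            labels.to_numpy(), index=qcd.samples["sample_id"].to_numpy()
        )
        bins = summarize_roh_bins(rohset, groups_series)
        bins.to_csv(out / "roh_bins.tsv", sep="\t", index=False)
        incidence = snp_incidence(rohset, qcd.markers)
        bundle.update(rohset=rohset, f_roh=froh, roh_bins=bins, incidence=incidence)
    except Exception as exc:
        raise PipelineError("roh", str(exc)) from exc

    # ---- clusters + association
    try:
        clusters = find_clusters(rohset, qcd.markers, config.cluster_min_members)
        bundle["clusters"] = clusters
        membership = membership_matrix(rohset, clusters)
        membership.to_csv(out / "cluster_membership.tsv", sep="\t")
        if two_group is not None and clusters:
            assoc = homozygosity_association(membership, two_group)
            assoc.table.to_csv(out / "association.tsv", sep="\t", index=False)
            bundle["association"] = assoc
        incidence_regions = call_incidence_regions(
            incidence, qcd.markers, config.seed_mult, config.ext_mult
        )
        regions_to_frame(incidence_regions).to_csv(
            out / "incidence_regions.tsv", sep="\t", index=False
        )
        bundle["incidence_regions"] = incidence_regions
    except Exception as exc:
        raise PipelineError("clusters", str(exc)) from exc

    # ---- F_ST scan
    try:
        if two_group is not None:
            profile = marker_fst(qcd, two_group)
            profile.to_frame(qcd.markers).to_csv(
                out / "fst_profile.tsv", sep="\t", index=False
            )
            regions = call_regions(
                profile,
                qcd.markers,
                config.seed_mult,
                config.ext_mult,
                config.pad_bp,
                config.strict_padding,
            )
            regions_to_frame(regions).to_csv(out / "fst_regions.tsv", sep="\t", index=False)
            bundle["fst_profile"] = profile
            bundle["fst_regions"] = regions
            if config.make_figures:
                manhattan_plot(profile, qcd.markers, out / "fst_manhattan.png",
                               config.ext_mult)
    except Exception as exc:
        raise PipelineError("fst", str(exc)) from exc

    # ---- report
    report = generate_report(bundle)
    (out / "report.txt").write_text(report)
    bundle["report"] = report
    return bundle


def _cluster_listing(bundle: dict) -> str:
    clusters = bundle.get("clusters") or []
    header = (
        "Chr\tStart SNP\tPosition Start\tEnd Position\tLength\t# SNPs\t"
        "P-value\tPopulation"
    )
    if not clusters:
        return header + "\n(no clusters)\n"
    assoc = bundle.get("association")
    pvals = {}
    enriched = {}
    if assoc is not None:
        for _, row in assoc.table.iterrows():
            pvals[row["cluster"]] = row["p_value"]
            enriched[row["cluster"]] = row["enriched_group"]
    lines = [header]
    for j, cl in enumerate(clusters):
        key = f"cluster_{j}"
        p = pvals.get(key, float("nan"))
        pop = enriched.get(key, "NA")
        lines.append(
            f"{cl.chromosome}\t{cl.first_snp_id}\t{cl.consensus_start_bp}\t"
            f"{cl.consensus_end_bp}\t{cl.length_bp}\t{cl.n_snps_in_cluster}\t"
            f"{p:.6g}\t{pop}"
        )
    return "\n".join(lines) + "\n"


def generate_report(bundle: dict) -> str:
    """Human-readable summary with the four standard sections; missing
    pieces are flagged rather than fatal."""
    parts = [f"popgenkit {__version__} pipeline report", "=" * 40, ""]

    parts.append("## ROH cluster association listing")
    parts.append(_cluster_listing(bundle))

    parts.append("## ROH length-bin means (per group)")
    bins = bundle.get("roh_bins")
    parts.append(bins.to_string(index=False) + "\n" if bins is not None else "(missing)\n")

    parts.append("## Pairwise fixation index")
    fst = bundle.get("pairwise_fst")
    parts.append(fst.round(4).to_string() + "\n" if fst is not None else "(missing)\n")

    parts.append("## Inbreeding summary (mean f and F_ROH per group)")
    f_table = bundle.get("f_table")
    froh = bundle.get("f_roh")
    if f_table is not None:
        summary = f_table.groupby("population")["f"].agg(["mean", "count"])
        if froh is not None:
            merged = froh.join(
                f_table.set_index("sample_id")["population"], how="left"
            )
            summary = summary.join(merged.groupby("population").mean(numeric_only=True))
        parts.append(summary.round(4).to_string() + "\n")
        comp = bundle.get("f_comparison")
        if comp:
            parts.append(
                f"Welch t = {comp['t']:.4g}, p = {comp['p']:.4g}, "
                f"means = {comp['means']}\n"
            )
    else:
        parts.append("(missing)\n")
    return "\n".join(parts)
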