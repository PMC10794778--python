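"""End-to-end pipeline: bin -> aggregate -> classify -> call domains -> dynamics.

A run is described by a plain YAML config (see ``RunConfig``); every stage
writes TSV/BED outputs into the run directory and a manifest records
parameters, usable-bin counts and filter casualty counts. Identical config
and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binning import autosome_names, genome_from_fasta, mean_autosomal_gc, tile_genome, write_bin_table
from .classify import profile_methylome, profiles_table
from .domains import call_domains, total_domain_size, write_domains_bed
from .dynamics import assign_gc_groups, classify_susceptibility, overlap_fraction, stage_delta
from .intervals import read_bed
from .io import (
    CpGMethylome,
    aggregate_cells,
    bin_methylation,
    filter_bins,
    global_methylation,
    read_coverage,
    read_cytosine_report,
    read_site_table,
    write_bin_methylome,
)

log = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    sample_id: str
    path: str
    format: str = "cytosine_report"  # cytosine_report | coverage | site_table
    coord_base: int = 1


@dataclass
class RunConfig:
    genome_fasta: str
    output_dir: str
    samples: list[SampleSpec]
    autosomes: list[str] | None = None
    bin_width: int = 500_000
    small_bin_width: int = 10_000
    k_extreme: int = 1_000
    n_gc_groups: int = 12
    tertile_size: int | None = None
    global_depth_min: int = 5
    site_depth_min: int = 5
    min_cpgs_informative: int = 1
    bridge_max_bins: int = 5
    min_domain_size: int = 100_000
    min_covered_cpgs: int = 10
    max_n_fraction: float = 0.5
    exclude_partial: bool = True
    lad_bed: str | None = None
    dynamics: dict | None = None  # {"hypo_sample": id, "remeth_sample": id}
    seed: int = 0

    def __post_init__(self):
        if not self.samples:
            raise ValueError("sample manifest is empty")
        for name in ("bin_width", "small_bin_width", "k_extreme", "n_gc_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for spec in self.samples:
            if not Path(spec.path).exists():
                raise FileNotFoundError(f"sample {spec.sample_id}: file not found: {spec.path}")
        if not Path(self.genome_fasta).exists():
            raise FileNotFoundError(f"genome FASTA not found: {self.genome_fasta}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        return cls(samples=samples, **raw)


def load_sample(spec: SampleSpec) -> CpGMethylome:
    if spec.format == "cytosine_report":
        return read_cytosine_report(spec.path, spec.sample_id)
    if spec.format == "coverage":
        return read_coverage(spec.path, spec.coord_base, spec.sample_id)
    if spec.format == "site_table":
        return read_site_table(spec.path, spec.sample_id)
    raise ValueError(f"unknown sample format {spec.format!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "parameters": {
        k: v for k, v in vars(config).items() if k != "samples"
    }, "samples": {}, "warnings": []}

    genome = genome_from_fasta(config.genome_fasta)
    autosomes = config.autosomes or autosome_names(genome)
    manifest["autosomes"] = list(autosomes)
    bins = tile_genome(genome, config.bin_width, autosomes)
    small_bins = tile_genome(genome, config.small_bin_width, autosomes)
    write_bin_table(bins, outdir / "bins.tsv")
    manifest["mean_autosomal_gc"] = round(mean_autosomal_gc(bins), 6)

    profiles = []
    binmeths: dict[str, pd.DataFrame] = {}
    for spec in config.samples:
        try:
            meth = load_sample(spec)
            glob = global_methylation(meth, config.global_depth_min)
            bm = bin_methylation(meth, bins, config.site_depth_min)
            bm, filter_log = filter_bins(
                bm,
                config.min_covered_cpgs,
                config.max_n_fraction,
                config.exclude_partial,
                min_usable=2 * config.k_extreme,
            )
            prof = profile_methylome(spec.sample_id, bm, glob.level, config.k_extreme)
            profiles.append(prof)
            binmeths[spec.sample_id] = bm
            write_bin_methylome(bm, outdir / f"{spec.sample_id}.bins.tsv")

            if glob.level < 0.2:
                manifest["warnings"].append(
                    f"{spec.sample_id}: global level {glob.level:.3f} < 0.2 "
                    "(oocyte-lineage-like); PMD calls unreliable"
                )
            bm_small = bin_methylation(meth, small_bins, config.site_depth_min)
            domains = call_domains(
                bm_small,
                glob.level,
                config.min_cpgs_informative,
                config.bridge_max_bins,
                config.min_domain_size,
            )
            write_domains_bed(domains, outdir / f"{spec.sample_id}.pmd.bed", "PMD")
            write_domains_bed(domains, outdir / f"{spec.sample_id}.hmd.bed", "HMD")
            manifest["samples"][spec.sample_id] = {
                "global_level": round(glob.level, 6),
                "global_sites": glob.n_sites,
                "class": prof.class_label,
                "score": round(prof.score, 6),
                "usable_bins": filter_log["n_usable"],
                "bin_filter": filter_log,
                "pmd_total_bp": total_domain_size(domains, "PMD"),
                "hmd_total_bp": total_domain_size(domains, "HMD"),
            }
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for sample {spec.sample_id!r}: {exc}"
            ) from exc

    profiles_table(profiles).to_csv(
        outdir / "profiles.tsv", sep="\t", index=False, float_format="%.6g"
    )

    if config.dynamics:
        hypo_id = config.dynamics["hypo_sample"]
        remeth_id = config.dynamics["remeth_sample"]
        bm_h, bm_r = binmeths[hypo_id], binmeths[remeth_id]
        shared_usable = bm_h["usable"] & bm_r["usable"] & bm_h["level"].notna() & bm_r["level"].notna()
        bm_h = bm_h.assign(usable=shared_usable)
        bm_r = bm_r.assign(usable=shared_usable)
        grouped = assign_gc_groups(bm_h, config.n_gc_groups)
        delta, test = stage_delta(bm_h, bm_r, grouped)
        delta.to_csv(outdir / "gc_group_deltas.tsv", sep="\t", index=False, float_format="%.6g")
        annotations = None
        if config.lad_bed:
            lad = overlap_fraction(bm_h, read_bed(config.lad_bed), name="clad")
            annotations = {"clad_overlap": lad["clad_fraction"].to_numpy()}
        labels, summary = classify_susceptibility(
            bm_h, bm_r, config.tertile_size, annotations
        )
        labels.to_csv(outdir / "nine_group_bins.tsv", sep="\t", index=False, float_format="%.6g")
        summary.to_csv(outdir / "nine_group_summary.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["dynamics"] = {
            "hypo_sample": hypo_id,
            "remeth_sample": remeth_id,
            "delta_test_p": test.p_value,
            "delta_test_method": test.method,
            "n_classified": int(len(labels)),
        }

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
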