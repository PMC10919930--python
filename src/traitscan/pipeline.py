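"""End-to-end pipeline runs from a single structured config.

Two pipelines are provided: the association-scan pipeline
(simulate/load -> scan -> permutation FDR -> classify -> report) and the
population-genomics pipeline (simulate/load -> depth filter -> windowed
heterozygosity -> ROH -> pseudodiploid -> psmcfa).  Each writes a
self-contained artifact directory with reproducibility metadata (verbatim
config, derived stage seeds, input checksums); rerunning with the same
config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignio, classify, popgen, scan, synthetic
from .errors import ConfigError, TraitscanError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single config for both pipelines.

    Stage seeds are derived deterministically from ``seed`` (one spawned
    stream per stage), so e.g. changing the number of permutations never
    changes the simulated data.
    """

    seed: int = 0
    outdir: str = "traitscan_out"
    # inputs: either paths, or "simulate"
    alignment: str = "simulate"
    alignment_format: str = "fasta"
    traits: str = "simulate"
    track: str = "simulate"
    track_b: str | None = None  # second genome for the pseudodiploid stage
    # simulation
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    n_plant_type1: int = 7
    n_plant_type2: int = 5
    # scan / FDR
    models: tuple = ("allele", "allele+habitat")
    thresholds: tuple = (1e-3, 1e-4, 1e-5)
    n_perm: int = 1000
    n_runs: int = 2
    stratified_for_habitat_model: bool = True
    hit_threshold: float = 1e-4  # p-value cutoff defining reported hits
    # coordinate mapping
    ref_row: str | None = None  # default: first alignment row
    anchor: int = 1
    orientation: str = "forward"
    chrom: str = "ref"
    features_bed: str | None = None
    # popgen
    window_size: int = 1_000_000
    roh_window_size: int = 20_000
    roh_min_windows: int = 25
    roh_het_threshold: float = 0.025
    #: per-window score: "fraction" (n_het / n_called) or "per_kb" (n_het per
    #: kb of window span).  The pipeline defaults to per_kb because a
    #: fraction threshold of 0.025 cannot separate ROH from a background
    #: heterozygosity of ~1e-3 per site (every window would qualify).
    roh_score: str = "per_kb"
    froh_min_length: int = 500_000
    psmcfa_bin_size: int = 100
    psmcfa_min_called_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "thresholds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        names = ["simulate", "fdr", "pseudodiploid"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {
            n: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            for n, c in zip(names, children)
        }


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_meta(outdir: Path, config: RunConfig, extra: dict) -> None:
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(extra, fh, indent=2, default=str)
        fh.write("\n")


def _coerce_sim_overrides(sim: dict) -> dict:
    """Allow YAML configs to express the structured sim fields as mappings."""
    sim = dict(sim)
    if "roh_segments" in sim:
        sim["roh_segments"] = [
            s if isinstance(s, synthetic.RohSegment) else synthetic.RohSegment(**s)
            for s in sim["roh_segments"]
        ]
    if "low_complexity_blocks" in sim:
        sim["low_complexity_blocks"] = [
            b
            if isinstance(b, synthetic.LowComplexityBlock)
            else synthetic.LowComplexityBlock(**b)
            for b in sim["low_complexity_blocks"]
        ]
    if "plants" in sim:
        sim["plants"] = [
            p if isinstance(p, synthetic.PlantSpec) else synthetic.PlantSpec(**p)
            for p in sim["plants"]
        ]
    return sim


def _sim_config(config: RunConfig, seed: int) -> synthetic.SimConfig:
    cfg = synthetic.default_config(seed=seed, **_coerce_sim_overrides(config.sim))
    if not cfg.plants and (config.n_plant_type1 or config.n_plant_type2):
        cfg.plants = synthetic.default_plants(
            cfg, n_type1=config.n_plant_type1, n_type2=config.n_plant_type2
        )
    return cfg


def run_scan_pipeline(config: RunConfig) -> Path:
    """simulate/load -> scan -> FDR -> classify -> typed-site report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    log: dict = {"stage_seeds": seeds, "stages": {}}
    try:
        # --- inputs ---
        sim_cfg = None
        if config.alignment == "simulate" or config.traits == "simulate":
            sim_cfg = _sim_config(config, seeds["simulate"])
        if config.traits == "simulate":
            traits = synthetic.simulate_trait_table(sim_cfg)
            alignio.write_trait_table(traits, outdir / "traits.tsv")
        else:
            traits = alignio.read_trait_table(config.traits)
            log["stages"]["traits_checksum"] = _checksum(Path(config.traits))
        if config.alignment == "simulate":
            aln, truth = synthetic.simulate_alignment(traits, sim_cfg)
            aln.write_fasta(outdir / "alignment.fasta")
            truth.planted_sites.to_csv(
                outdir / "truth_sites.tsv", sep="\t", index=False
            )
            patterns = sim_cfg.patterns
        else:
            aln = alignio.read_alignment(config.alignment, config.alignment_format)
            log["stages"]["alignment_checksum"] = _checksum(Path(config.alignment))
            patterns = (
                sim_cfg.patterns
                if sim_cfg is not None
                else synthetic.default_config().patterns
            )
        # --- scan ---
        results = scan.scan_alignment(aln, traits, models=config.models)
        results.to_csv(outdir / "scan.tsv", sep="\t", index=False, na_rep="NA")
        # --- FDR ---
        estimates = []
        for model in config.models:
            stratified = (
                model == "allele+habitat" and config.stratified_for_habitat_model
            )
            estimates.extend(
                scan.estimate_fdr(
                    aln,
                    traits,
                    thresholds=config.thresholds,
                    n_perm=config.n_perm,
                    n_runs=config.n_runs,
                    stratified=stratified,
                    seed=seeds["fdr"],
                    model=model,
                )
            )
        scan.fdr_table(estimates).to_csv(outdir / "fdr.tsv", sep="\t", index=False)
        # --- classify hits ---
        hit_cols = sorted(
            set(
                results.loc[
                    results["p_value"].notna()
                    & (results["p_value"] <= config.hit_threshold),
                    "column",
                ]
            )
        )
        sites = classify.classify_columns(aln, hit_cols, patterns)
        ref_row = config.ref_row if config.ref_row is not None else aln.ids[0]
        cmap = alignio.build_column_map(
            aln, ref_row, config.anchor, config.orientation
        )
        for s in sites:
            s.coordinate = cmap.coord_of_column(s.column)
            s.chrom = config.chrom
        if config.features_bed:
            features = alignio.read_bed(config.features_bed)
            classify.annotate_features(sites, features, chrom=config.chrom)
        typed = [s for s in sites if s.type_label]
        alignio.write_site_report(typed, outdir / "typed_sites.tsv")
        alignio.write_sites_bed(
            typed, cmap, outdir / "typed_sites.bed", chrom=config.chrom
        )
        log["stages"]["n_columns"] = int(aln.n_columns)
        log["stages"]["n_hit_columns"] = len(hit_cols)
        log["stages"]["n_typed_sites"] = len(typed)
    except TraitscanError as exc:
        log["error"] = f"scan pipeline aborted: {exc}"
        _write_meta(outdir, config, log)
        raise
    _write_meta(outdir, config, log)
    return outdir


def run_popgen_pipeline(config: RunConfig) -> Path:
    """simulate/load -> depth filter -> windows -> ROH -> pseudodiploid."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    log: dict = {"stage_seeds": seeds, "stages": {}}
    try:
        sim_cfg = _sim_config(config, seeds["simulate"])
        if config.track == "simulate":
            track, truth = synthetic.simulate_genotype_track(sim_cfg)
            truth.planted_roh.to_csv(outdir / "truth_roh.tsv", sep="\t", index=False)
        else:
            p = Path(config.track)
            if not p.exists():
                raise ConfigError(f"track input not found: {p}")
            track = (
                popgen.GenotypeTrack.from_vcf(p)
                if p.suffix == ".vcf"
                else popgen.GenotypeTrack.from_tsv(p)
            )
            log["stages"]["track_checksum"] = _checksum(p)
        filtered = popgen.filter_by_depth(track)
        log["stages"]["n_sites"] = int(track.n_sites)
        log["stages"]["n_sites_after_depth_filter"] = int(filtered.n_sites)
        windows = popgen.window_heterozygosity(filtered, config.window_size)
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False, na_rep="NA")
        runs = popgen.call_roh(
            filtered,
            window_size=config.roh_window_size,
            min_windows=config.roh_min_windows,
            het_threshold=config.roh_het_threshold,
            score=config.roh_score,
        )
        assessed = sum(filtered.scaffold_lengths.values())
        summary = popgen.summarize_roh(
            runs, assessed_length=assessed, min_length=config.froh_min_length
        )
        popgen.write_roh_bed(runs, outdir / "roh.bed")
        popgen.write_roh_summary(summary, outdir / "roh_summary.json")
        # pseudodiploid: either a supplied second track or an independent
        # re-simulation (different seed) standing in for the second genome
        if config.track_b is not None:
            p = Path(config.track_b)
            if not p.exists():
                raise ConfigError(f"track_b input not found: {p}")
            track_b = (
                popgen.GenotypeTrack.from_vcf(p)
                if p.suffix == ".vcf"
                else popgen.GenotypeTrack.from_tsv(p)
            )
        else:
            cfg_b = dataclasses.replace(
                sim_cfg, seed=sim_cfg.seed + 1, roh_segments=[]
            )
            track_b, _ = synthetic.simulate_genotype_track(cfg_b)
        pseudo = popgen.make_pseudodiploid(
            filtered, popgen.filter_by_depth(track_b), seed=seeds["pseudodiploid"]
        )
        pseudo.to_tsv(outdir / "pseudodiploid.tsv")
        popgen.write_psmcfa(
            pseudo,
            outdir / "pseudodiploid.psmcfa",
            bin_size=config.psmcfa_bin_size,
            min_called_fraction=config.psmcfa_min_called_fraction,
        )
        log["stages"]["n_roh_runs"] = len(runs)
        log["stages"]["froh"] = summary.froh
        log["stages"]["n_pseudodiploid_sites"] = int(pseudo.n_sites)
    except TraitscanError as exc:
        log["error"] = f"popgen pipeline aborted: {exc}"
        _write_meta(outdir, config, log)
        raise
    _write_meta(outdir, config, log)
    return outdir
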