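"""End-to-end orchestration: simulate -> filter -> call -> landscape -> report.

Each run is driven by a validated :class:`~meioxo.config.RunConfig`; all
randomness descends from the single root seed via hierarchical child
streams, so reruns with identical config and seed produce byte-identical
outputs.  A JSON manifest (tool version, config hash, per-stage tallies,
output checksums) is written atomically at the end of the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__, io
from .caller import (
    FilterConfig,
    call_crossovers,
    call_genotypes,
    count_per_individual,
    filter_markers,
    segment_track,
)
from .config import RunConfig, config_hash, validate_config
from .landscape import bin_crossovers, group_recombination, snp_density_grouping
from .simulate import build_intensity_profiles, simulate_f2_population, simulate_gbs

__all__ = ["run_pipeline"]

log = logging.getLogger("meioxo")


def run_pipeline(config, out_dir=None, markers_path=None) -> dict:
    """Run the full workflow; returns the manifest dict.

    With ``markers_path`` the simulation stage is replaced by ingesting an
    existing marker TSV (the deposited-data route); otherwise an F2
    population is simulated and its ground truth written alongside the
    marker table.  A stage failure aborts with the stage name while earlier
    stages' outputs remain on disk.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    chash = config_hash(cfg)
    seed = cfg.seed
    out = Path(out_dir or cfg.raw["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "meioxo",
        "version": __version__,
        "config_hash": chash,
        "seed": seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    root = np.random.default_rng(seed)
    model = cfg.genome_model()
    stage = "simulate"
    try:
        if markers_path is None:
            params = cfg.pathway_params()
            profiles = build_intensity_profiles(model, params)
            sim = cfg.section("simulator")
            population = simulate_f2_population(
                model, params, int(sim["n_individuals"]), root, profiles=profiles
            )
            table = simulate_gbs(
                population,
                model,
                mean_coverage=float(sim["mean_coverage"]),
                error_rate=float(sim["error_rate"]),
                sites_per_Mb=float(sim["sites_per_mb"]),
                rng=root,
                quality_fail_fraction=float(sim["quality_fail_fraction"]),
                base_library_reads=int(sim["base_library_reads"]),
            )
            io.write_truth_bed(population, out / "truth.bed", seed, chash)
            io.write_marker_table(table, out / "markers.tsv", seed, chash)
            manifest["outputs"]["truth.bed"] = io.sha256_of(out / "truth.bed")
            manifest["stages"]["simulate"] = {
                "n_individuals": len(population),
                "true_crossovers": int(sum(ind.n_crossovers for ind in population)),
                "marker_rows": len(table.df),
            }
        else:
            stage = "ingest"
            table = io.read_marker_table(markers_path)
            manifest["inputs"]["markers"] = io.sha256_of(markers_path)
            manifest["stages"]["ingest"] = {
                "n_individuals": len(table.library_reads),
                "marker_rows": len(table.df),
            }
        log.info("%s: %d marker rows", stage, len(table.df))

        stage = "filter"
        cal = cfg.section("caller")
        fcfg = FilterConfig(
            min_site_quality=float(cal["min_site_quality"]),
            min_mean_coverage=float(cal["min_mean_coverage"]),
            min_library_reads=int(cal["min_library_reads"]),
        )
        table, report = filter_markers(table, fcfg)
        manifest["stages"]["filter"] = report.as_dict()
        log.info("filter: %s", report.as_dict())

        stage = "call"
        genotypes = call_genotypes(table, hom_fraction=float(cal["hom_fraction"]))
        segments = segment_track(
            genotypes,
            smoothing_window=int(cal["smoothing_window"]),
            min_support=int(cal["min_support"]),
        )
        calls = call_crossovers(segments)
        counts = count_per_individual(calls, individuals=table.individuals)
        io.write_calls(calls, out / "crossovers.bed", out / "crossovers.tsv", seed, chash)
        io.write_table(counts, out / "crossover_counts.tsv", seed=seed, config_hash=chash)
        manifest["stages"]["call"] = {
            "n_segments": len(segments),
            "n_calls": len(calls),
            "skipped_tracks": len(segments.attrs.get("skipped", [])),
        }

        stage = "landscape"
        land = cfg.section("landscape")
        lengths = dict(model.chromosomes)
        n_ind = len(table.individuals)
        snp_positions = table.df[["chrom", "pos"]].drop_duplicates()
        windows = bin_crossovers(
            calls,
            lengths,
            int(land["window_bp"]),
            n_ind,
            snp_positions=snp_positions,
            drop_partial=bool(land["drop_partial"]),
        )
        io.write_table(windows, out / "windows.tsv", seed=seed, config_hash=chash)
        density_windows = bin_crossovers(
            calls, lengths, int(land["density_window_bp"]), n_ind, snp_positions=snp_positions
        )
        n_groups = len(density_windows) // int(land["group_size"])
        if n_groups >= 1:
            grouped, excluded = snp_density_grouping(density_windows, int(land["group_size"]))
            groups = group_recombination(
                grouped, calls, n_ind, window_bp=int(land["density_window_bp"])
            )
            io.write_table(groups, out / "density_groups.tsv", seed=seed, config_hash=chash)
            manifest["stages"]["landscape"] = {
                "n_windows": len(windows),
                "n_density_groups": len(groups),
                "n_windows_excluded": len(excluded),
            }
        else:
            manifest["stages"]["landscape"] = {"n_windows": len(windows), "n_density_groups": 0}

        for name in ("markers.tsv", "crossovers.bed", "crossovers.tsv",
                     "crossover_counts.tsv", "windows.tsv", "density_groups.tsv"):
            p = out / name
            if p.exists():
                manifest["outputs"][name] = io.sha256_of(p)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(out / "manifest.json")
    return manifest
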