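"""Config-driven orchestration of the full analysis sweep.

One declarative config (YAML or dict) lists the input files, the target
tracks with their overlap modes, and the analysis constants; ``run_all``
validates everything up front (no partial outputs on a bad config), then
executes: gap-joining -> size/distance summaries -> gene context ->
enrichment sweep -> AT test (if a FASTA is given) -> qPCR validation (if a
table is given).  Each panel is written as TSV next to a consolidated JSON
bundle and a run manifest (config snapshot, input checksums, seed, stage
timings, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_model import (
    FeatureTrack,
    PipelineConfig,
    RegionSet,
    read_bed,
    read_genes,
    write_bed,
    write_results,
)
from .sar_postprocess import (
    distance_histogram,
    inter_interval_distances,
    length_histogram,
    merge_by_gap,
    size_summary,
)
from .enrichment_engine import (
    OverlapStatistic,
    class_overlap_test,
    enrichment_test,
    track_seed,
)
from .gene_context import derive_point_track, genic_breakdown, nearest_distance_profile
from .sequence_features import at_enrichment_test
from .qpcr_validation import analyze_qpcr, read_qpcr_table

logger = logging.getLogger("sarenrich")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


class PipelineValidationError(ValueError):
    """Raised before any computation when the configuration is unusable."""


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineValidationError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def validate_config(config: dict) -> PipelineConfig:
    """Validate-first contract: every referenced file must exist up front."""
    for key in ("calls", "regions"):
        if key not in config:
            raise PipelineValidationError(f"config is missing required key {key!r}")
    params = config.get("params", {})
    try:
        pcfg = PipelineConfig(
            merge_gap_bp=int(params.get("merge_gap_bp", 2501)),
            n_randomizations=int(params.get("n_randomizations", 9999)),
            proximity_bp=int(params.get("proximity_bp", 5000)),
            z_threshold=float(params.get("z_threshold", 8.0)),
            rng_seed=int(params.get("rng_seed", 42)),
        )
    except (TypeError, ValueError) as exc:
        raise PipelineValidationError(f"bad params block: {exc}") from exc
    paths = [config["calls"], config["regions"]]
    for opt in ("genes", "fasta", "qpcr"):
        if config.get(opt):
            paths.append(config[opt])
    for tr in config.get("tracks", []):
        if "name" not in tr or "path" not in tr:
            raise PipelineValidationError(f"track entry {tr!r} needs name and path")
        if tr.get("mode", "count") not in ("count", "within_distance", "containment", "bp"):
            raise PipelineValidationError(f"track {tr['name']}: bad mode {tr.get('mode')!r}")
        paths.append(tr["path"])
    for ct in config.get("class_tracks", []):
        if "name" not in ct or "path" not in ct:
            raise PipelineValidationError(f"class track entry {ct!r} needs name and path")
        paths.append(ct["path"])
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineValidationError(f"missing input file(s): {missing}")
    return pcfg


def run_all(config: dict, outdir: str | Path) -> dict:
    """Execute every enabled stage; returns the consolidated bundle dict."""
    pcfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    bundle: dict = {"params": dataclasses.asdict(pcfg)}

    def stage(name):
        logger.info("stage %s: start (seed=%d)", name, pcfg.rng_seed)
        return time.perf_counter()

    def done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, timings[name])

    # -- postprocess -------------------------------------------------------
    t0 = stage("postprocess")
    regions = RegionSet(read_bed(config["regions"]))
    calls = read_bed(config["calls"])
    sars = merge_by_gap(calls, pcfg.merge_gap_bp)
    write_bed(sars, outdir / "sars.bed")
    sizes = size_summary(sars, regions)
    distances = inter_interval_distances(sars, regions)
    write_results([sizes], outdir / "size_summary.tsv")
    write_results([distances], outdir / "distance_summary.tsv")
    length_histogram(sars).to_csv(outdir / "size_hist.tsv", sep="\t", index=False)
    distance_histogram(distances.distances).to_csv(
        outdir / "distance_hist.tsv", sep="\t", index=False
    )
    logger.info(
        "postprocess: %d calls -> %d joined intervals; %d inter-site distances",
        len(calls), len(sars), len(distances.distances),
    )
    bundle["n_calls"] = len(calls)
    bundle["n_sars"] = len(sars)
    bundle["size_summary"] = dataclasses.asdict(sizes)
    dsum = dataclasses.asdict(distances)
    dsum.pop("distances")
    bundle["distance_summary"] = dsum
    done("postprocess", t0)

    # -- gene context ------------------------------------------------------
    if config.get("genes"):
        t0 = stage("gene_context")
        genes = read_genes(config["genes"])
        report = genic_breakdown(
            sars, genes, regions,
            upstream_bp=pcfg.proximity_bp, proximity_bp=pcfg.proximity_bp,
        )
        write_results([report], outdir / "gene_context.tsv")
        bins = np.arange(-50_000, 50_001, 2_000)
        for which in ("tss", "tes"):
            points = derive_point_track(genes, which)
            nearest_distance_profile(sars, points, regions, bins).to_csv(
                outdir / f"{which}_profile.tsv", sep="\t", index=False
            )
        bundle["gene_context"] = dataclasses.asdict(report)
        done("gene_context", t0)

    # -- enrichment sweep --------------------------------------------------
    if config.get("tracks") or config.get("class_tracks"):
        t0 = stage("enrichment")
        results = []
        for tr in config.get("tracks", []):
            track = FeatureTrack(
                tr["name"],
                read_bed(tr["path"]),
                overlap_mode=tr.get("mode", "count"),
                distance_bp=int(tr.get("distance_bp", 0)),
            )
            res = enrichment_test(
                sars, track, regions,
                n_randomizations=pcfg.n_randomizations,
                rng_seed=track_seed(pcfg.rng_seed, track.track_name),
            )
            results.append(res)
            logger.info(
                "enrichment %s (%s): observed=%.1f null_mean=%.2f p_enrich=%.4g",
                res.track_name, res.mode, res.observed, res.null_mean, res.p_enrich,
            )
        class_defs = config.get("class_tracks", [])
        if class_defs:
            class_tracks = [
                FeatureTrack(ct["name"], read_bed(ct["path"]), overlap_mode="bp")
                for ct in class_defs
            ]
            results.extend(
                class_overlap_test(
                    sars, class_tracks, regions,
                    n_randomizations=pcfg.n_randomizations,
                    rng_seed=track_seed(pcfg.rng_seed, "class_tracks"),
                )
            )
        write_results(results, outdir / "enrichment.tsv")
        bundle["enrichment"] = [
            {
                k: v
                for k, v in dataclasses.asdict(r).items()
                if not isinstance(v, np.ndarray)
            }
            for r in results
        ]
        bundle["n_enrichment_tests"] = len(results)
        done("enrichment", t0)

    # -- AT content --------------------------------------------------------
    if config.get("fasta"):
        t0 = stage("at_test")
        import pyfaidx

        fasta = pyfaidx.Fasta(config["fasta"])
        at = at_enrichment_test(
            sars, regions, fasta,
            n_randomizations=pcfg.n_randomizations,
            rng_seed=track_seed(pcfg.rng_seed, "at_content"),
        )
        row = {
            "observed_median_at_pct": at.observed_median_at_pct,
            "observed_mean_at_pct": at.observed_mean_at_pct,
            "null_median_of_medians": at.null_median_of_medians,
            "p_enrich": at.p_enrich,
            "p_deplete": at.p_deplete,
            "n_randomizations": at.n_randomizations,
        }
        write_results([row], outdir / "at_content.tsv")
        bundle["at_content"] = row
        done("at_test", t0)

    # -- qPCR --------------------------------------------------------------
    if config.get("qpcr"):
        t0 = stage("qpcr")
        table = read_qpcr_table(config["qpcr"])
        records, summary = analyze_qpcr(
            table,
            negative_control=config.get("negative_control", "ApoB_neg"),
            z_threshold=pcfg.z_threshold,
        )
        write_results(records, outdir / "qpcr_validation.tsv")
        bundle["qpcr"] = summary
        done("qpcr", t0)

    # -- bundle + manifest -------------------------------------------------
    with (outdir / "bundle.json").open("w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
        fh.write("\n")
    input_paths = [config["calls"], config["regions"]] + [
        config[k] for k in ("genes", "fasta", "qpcr") if config.get(k)
    ] + [tr["path"] for tr in config.get("tracks", [])] + [
        ct["path"] for ct in config.get("class_tracks", [])
    ]
    manifest = {
        "version": __version__,
        "seed": pcfg.rng_seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "timings_s": timings,
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return bundle
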