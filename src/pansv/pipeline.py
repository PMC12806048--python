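"""Stage orchestration: configuration, validation, logging, manifest.

Runs the stages in dependency order on a synthetic cohort (or on files
already on disk for individual stages), writes per-stage TSV outputs,
and records a run manifest with the seed, a parameter hash, and
per-stage record counts so conservation invariants are auditable from
the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, consensus, enrichment, introgression, io, mechanism, popgen
from . import selection, simulate

logger = logging.getLogger("pansv")

ALL_STAGES = ("simulate", "merge", "mechanism", "popgen", "scan", "abba", "enrich")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds with their published or documented defaults."""

    seed: int = 0
    out_dir: str = "pansv_run"
    stages: tuple[str, ...] = ALL_STAGES
    # consensus
    min_size: int = 50
    max_size: int = 100_000
    merge_dist: int = 50
    min_recurrence: int = 3
    # popgen QC / LD
    min_call_rate: float = 0.3
    min_mac_exclusive: int = 3
    tag_r2: float = 0.2
    molqtl_r2: float = 0.6
    ld_window: int = 100_000
    ibs_maf: float = 0.05
    # selection scan
    window: int = 30_000
    step: int = 10_000
    top_fraction: float = 0.001
    scaling_constant: float = 1.001
    # introgression
    min_sites: int = 20
    # enrichment
    n_permutations: int = 100
    # simulation
    sim: simulate.SimulationConfig = simulate.SimulationConfig()


def validate_config(config: PipelineConfig) -> list[str]:
    """Raise on out-of-domain values; return a report of the values in
    force (published defaults are called out)."""
    errors = []
    if not 0 < config.top_fraction < 1:
        errors.append("top_fraction must be in (0, 1)")
    if config.scaling_constant <= 1:
        errors.append("scaling constant must exceed 1 (scaled score unbounded)")
    if config.min_size < 0 or config.max_size < config.min_size:
        errors.append("size filter bounds must satisfy 0 <= min <= max")
    if not 0 <= config.min_call_rate <= 1:
        errors.append("call rate threshold must be in [0, 1]")
    if config.n_permutations < 1:
        errors.append("need at least one permutation")
    if config.window < config.step:
        errors.append("window must be >= step")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    if errors:
        raise ValueError("; ".join(errors))
    return [
        f"size filter [{config.min_size}, {config.max_size}] bp (published)",
        f"breakpoint recurrence > {config.min_recurrence - 1} (published)",
        f"merge distance {config.merge_dist} bp (published)",
        f"call rate > {config.min_call_rate}, MAC > {config.min_mac_exclusive} (published)",
        f"tagged r2 >= {config.tag_r2}, molQTL r2 >= {config.molqtl_r2} (published)",
        f"windows {config.window} bp step {config.step} bp (published)",
        f"scaled rank S = R/({config.scaling_constant} - R), top {config.top_fraction:.3%} (published)",
        f"{config.n_permutations} permutations (published)",
        f"LD window +-{config.ld_window} bp (documented default)",
        f"ABBA-BABA min sites {config.min_sites} (documented default)",
    ]


def _param_hash(config: PipelineConfig) -> str:
    """Hash of the scientific parameters (output location excluded)."""
    payload = dataclasses.asdict(config)
    payload.pop("out_dir")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": {},
    }
    counts = manifest["stages"]

    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    cohort = simulate.simulate_cohort(sim_cfg)
    layout = io.GenomeLayout.from_sequences(cohort.reference.sequences)

    if "simulate" in config.stages:
        io.write_fasta(out / "reference.fa", cohort.reference.sequences)
        io.write_fasta(out / "te_library.fa", cohort.reference.te_library)
        io.write_tsv(out / "truth_svs.tsv", cohort.truth.svs.drop(columns=["seq"]))
        io.write_tsv(out / "samples.tsv", cohort.genotypes.samples)
        io.write_genotype_vcf(out / "genotypes.vcf", cohort.genotypes, layout)
        io.write_ibd_bed(out / "ibd_segments.bed", cohort.ibd_segments)
        for cls, df in cohort.annotations.items():
            io.write_bed(out / f"annotation_{cls}.bed", df)
        counts["simulate"] = {
            "planted_svs": len(cohort.truth.svs),
            "samples": cohort.genotypes.n_samples,
            "variants": cohort.genotypes.n_variants,
        }
        logger.info("simulate: %s", counts["simulate"])

    records = None
    if "merge" in config.stages:
        records = consensus.merge_cohort(
            cohort.callsets,
            reference=cohort.reference.sequences,
            min_size=config.min_size,
            max_size=config.max_size,
            min_recurrence=config.min_recurrence,
            max_dist=config.merge_dist,
        )
        frame = consensus.records_to_frame(records)
        io.write_sv_vcf(out / "merged_svs.vcf", frame, layout)
        io.write_tsv(out / "cluster_report.tsv", frame.drop(columns=["seq"]))
        counts["merge"] = {
            "input_calls": sum(len(v) for v in cohort.callsets.values()),
            "merged_records": len(records),
        }
        logger.info("merge: %s", counts["merge"])

    if "mechanism" in config.stages:
        frame = (
            consensus.records_to_frame(records)
            if records is not None
            else cohort.truth.svs
        )
        calls = mechanism.classify_all(
            frame, cohort.reference.sequences, cohort.reference.te_library
        )
        mdf = mechanism.calls_to_frame(calls)
        io.write_tsv(out / "mechanisms.tsv", mdf)
        by_class = mdf.groupby("mechanism").size().to_dict()
        for cls, grp in mdf.groupby("mechanism"):
            sub = frame[frame["id"].isin(grp["sv_id"])]
            io.write_bed(out / f"mechanism_{cls}.bed", sub[["chrom", "start", "end", "id"]].rename(columns={"id": "name"}))
        counts["mechanism"] = {"classified": len(mdf), **{str(k): int(v) for k, v in by_class.items()}}
        assert sum(by_class.values()) == len(mdf)
        logger.info("mechanism: %s", counts["mechanism"])

    if "popgen" in config.stages:
        gm, removed = popgen.qc_genotypes(
            cohort.genotypes, config.min_call_rate, config.min_mac_exclusive
        )
        io.write_tsv(out / "qc_removed.tsv", removed)
        strains = cohort.config.strains
        freq = popgen.frequencies(gm, delta_groups=(strains[0], strains[2]))
        io.write_tsv(out / "frequencies.tsv", freq)
        ld = popgen.ld_tagging(gm, config.ld_window, config.tag_r2, config.molqtl_r2)
        io.write_tsv(out / "ld_tagging.tsv", ld)
        _, group_ibs = popgen.ibs_matrix(gm, config.ibs_maf)
        group_ibs.to_csv(out / "ibs_groups.tsv", sep="\t")
        if "phenotype" in gm.samples.columns:
            assoc = popgen.assoc_case_control(
                gm.subset_variants((gm.variants["type"] == "SV").to_numpy())
            )
            io.write_tsv(out / "assoc_sv.tsv", assoc)
        if len(cohort.ibd_segments) and cohort.truth.sweep_window:
            nibd = popgen.nibd(
                cohort.ibd_segments, gm.samples, "strain", cohort.truth.sweep_window
            )
            io.write_tsv(out / "nibd.tsv", nibd)
        counts["popgen"] = {
            "variants_after_qc": gm.n_variants,
            "removed": len(removed),
            "tagged_svs": int((ld["tag_class"] == "tagged").sum()),
        }
        logger.info("popgen: %s", counts["popgen"])

    if "scan" in config.stages:
        sw = cohort.config.sweep
        scan = selection.selection_scan(
            cohort.genotypes,
            sw.focal,
            sw.contrast,
            layout.lengths,
            window=config.window,
            step=config.step,
            top_fraction=config.top_fraction,
        )
        io.write_tsv(out / "selection_scan.tsv", scan)
        io.write_bed(
            out / "selected_windows.bed",
            scan[scan["selected"]][["chrom", "start", "end"]],
        )
        counts["scan"] = {
            "windows": len(scan),
            "selected": int(scan["selected"].sum()),
        }
        logger.info("scan: %s", counts["scan"])

    if "abba" in config.stages:
        ig = cohort.config.introgression
        strains = cohort.config.strains
        p1 = next(s for s in strains if s not in (ig.recipient, ig.donor, "RJF"))
        sites = introgression.polarize_sites(
            cohort.genotypes, p1, ig.recipient, ig.donor, strains[-1]
        )
        windows = selection.make_windows(layout.lengths, config.window, config.step)
        dstat = introgression.windowed_dstat(sites, windows, config.min_sites)
        io.write_tsv(out / "abba_baba.tsv", dstat)
        counts["abba"] = {
            "windows": len(dstat),
            "informative_sites": int(dstat["n_informative_sites"].sum()),
        }
        logger.info("abba: %s", counts["abba"])

    if "enrich" in config.stages:
        svs = cohort.truth.svs
        sv_iv = svs[["chrom", "start", "end"]].copy()
        sv_iv["end"] = np.maximum(sv_iv["end"], sv_iv["start"] + 1)  # INS as points
        results = []
        rng = np.random.default_rng(config.seed + 7)
        for cls, regions in cohort.annotations.items():
            results.append(
                enrichment.permutation_enrichment(
                    sv_iv,
                    regions,
                    layout.lengths,
                    n_permutations=config.n_permutations,
                    seed=rng,
                    sv_category="all_svs",
                    region_class=cls,
                )
            )
        io.write_tsv(out / "enrichment.tsv", enrichment.enrichment_table(results))
        counts["enrich"] = {"classes": len(results)}
        logger.info("enrich: %s", counts["enrich"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
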