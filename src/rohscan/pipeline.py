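"""End-to-end pipeline: QC → run detection → summaries → islands → tests.

Driven by a validated :class:`PipelineConfig` (YAML-loadable).  Every stage
writes deterministic CSV/BED outputs into the output directory and records
its record counts in a machine-readable manifest, so reruns with the same
config are byte-identical and the QC cascade is fully auditable.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .data import GenotypeDataset, SHEEP_AUTOSOMES
from .detect import (
    RunConfig,
    TargetState,
    default_roh_config,
    default_rohet_config,
    detect_runs_all,
)
from .io import read_annotation_bed, read_plink, write_csv, write_segments_bed
from .islands import call_islands, islands_to_frame, overlap_annotations, overlaps_to_frame
from .qc import apply_qc
from .stats import pairwise_breed_tests
from .summaries import (
    ROH_SCHEME,
    ROHET_CLASSES,
    ROHET_SCHEME,
    LengthClassScheme,
    breed_summary,
    coefficient_table,
    per_animal_summary,
)

logger = logging.getLogger("rohscan")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see docs for field meanings)."""

    ped_path: str | None = None
    map_path: str | None = None
    output_dir: str = "rohscan_out"
    autosomes: tuple[str, ...] = SHEEP_AUTOSOMES
    min_call_rate: float = 0.95
    max_missing_fraction: float = 0.20
    min_maf: float = 0.05
    hwe_alpha: float = 1e-5
    hwe_per_population: bool = True
    roh: RunConfig = field(default_factory=default_roh_config)
    rohet: RunConfig = field(default_factory=default_rohet_config)
    #: ROHet summaries use the >0.5 Mb ladder; pair it with a 0.5 Mb
    #: detection floor so the shortest class is populated.
    rohet_min_length_for_summaries: int = ROHET_CLASSES[0]
    roh_classes: tuple[int, ...] = ROH_SCHEME.thresholds_bp
    rohet_classes: tuple[int, ...] = ROHET_SCHEME.thresholds_bp
    island_pct: float = 1.0
    min_island_snps: int = 2
    islands_per_breed: bool = True
    annotation_paths: tuple[str, ...] = ()
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        if self.ped_path is not None and not os.path.exists(self.ped_path):
            raise PipelineError(f"PED file not found: {self.ped_path}")
        if self.map_path is not None and not os.path.exists(self.map_path):
            raise PipelineError(f"MAP file not found: {self.map_path}")
        for p in self.annotation_paths:
            if not os.path.exists(p):
                raise PipelineError(f"annotation file not found: {p}")
        if not (0 < self.min_call_rate <= 1):
            raise PipelineError("min_call_rate must be in (0, 1]")
        if not (0 <= self.max_missing_fraction < 1):
            raise PipelineError("max_missing_fraction must be in [0, 1)")
        if not (0 <= self.min_maf < 0.5):
            raise PipelineError("min_maf must be in [0, 0.5)")
        if not (0 <= self.hwe_alpha <= 1):
            raise PipelineError("hwe_alpha must be in [0, 1]")
        if not (0 < self.island_pct < 100):
            raise PipelineError("island_pct must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key in ("roh", "rohet"):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                base = default_roh_config() if key == "roh" else default_rohet_config()
                raw[key] = RunConfig(
                    target_state=TargetState(d.get(
                        "target_state", base.target_state.value)),
                    min_snps=int(d.get("min_snps", base.min_snps)),
                    min_length_bp=int(d.get("min_length_bp", base.min_length_bp)),
                    max_gap_bp=int(d.get("max_gap_bp", base.max_gap_bp)),
                    max_opposite=int(d.get("max_opposite", base.max_opposite)),
                    max_missing=int(d.get("max_missing", base.max_missing)),
                )
        for key in ("autosomes", "annotation_paths", "roh_classes",
                    "rohet_classes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("roh", "rohet"):
            d[key]["target_state"] = d[key]["target_state"].value \
                if hasattr(d[key]["target_state"], "value") else str(d[key]["target_state"])
        return d


def run_pipeline(
    config: PipelineConfig,
    dataset: GenotypeDataset | None = None,
) -> dict:
    """Run the full analysis; returns the manifest dict.

    ``dataset`` may be passed directly (e.g., a simulated cohort); otherwise
    the PED/MAP pair from the config is read.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "tool": "rohscan",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "stages": [],
    }

    def stage(name: str, **records):
        logger.info("stage %s: %s", name, records)
        manifest["stages"].append({"name": name, "status": "ok", **records})

    try:
        # 1. load
        t0 = time.time()
        if dataset is None:
            if config.ped_path is None or config.map_path is None:
                raise PipelineError("no dataset given and no PED/MAP paths")
            dataset = read_plink(config.ped_path, config.map_path)
        stage("load", n_samples=dataset.n_samples, n_snps=dataset.n_snps,
              seconds=round(time.time() - t0, 2))

        # 2. QC
        t0 = time.time()
        ds, qc_report = apply_qc(
            dataset,
            min_call_rate=config.min_call_rate,
            autosomes=config.autosomes,
            max_missing_fraction=config.max_missing_fraction,
            min_maf=config.min_maf,
            hwe_alpha=config.hwe_alpha,
            hwe_per_population=config.hwe_per_population,
        )
        if not qc_report.check_consistency():
            raise PipelineError("QC report counts do not reconcile")
        write_csv(qc_report.to_frame(), os.path.join(out, "qc_report.csv"))
        stage("qc", n_samples=ds.n_samples, n_snps=ds.n_snps,
              seconds=round(time.time() - t0, 2))

        # 3. run detection (ROH + ROHet)
        t0 = time.time()
        roh_runs = detect_runs_all(ds, config.roh, config.autosomes)
        rohet_cfg = RunConfig(
            target_state=config.rohet.target_state,
            min_snps=config.rohet.min_snps,
            min_length_bp=min(config.rohet.min_length_bp,
                              config.rohet_min_length_for_summaries),
            max_gap_bp=config.rohet.max_gap_bp,
            max_opposite=config.rohet.max_opposite,
            max_missing=config.rohet.max_missing,
        )
        rohet_runs = detect_runs_all(ds, rohet_cfg, config.autosomes)
        write_csv(roh_runs, os.path.join(out, "runs_roh.csv"))
        write_csv(rohet_runs, os.path.join(out, "runs_rohet.csv"))
        write_segments_bed(roh_runs, os.path.join(out, "runs_roh.bed"))
        write_segments_bed(rohet_runs, os.path.join(out, "runs_rohet.bed"))
        stage("detect", n_roh=len(roh_runs), n_rohet=len(rohet_runs),
              seconds=round(time.time() - t0, 2))

        # 4. summaries and genomic coefficients
        t0 = time.time()
        roh_scheme = LengthClassScheme(config.roh_classes)
        rohet_scheme = LengthClassScheme(config.rohet_classes)
        animal_roh = per_animal_summary(roh_runs, ds.samples, roh_scheme)
        animal_rohet = per_animal_summary(rohet_runs, ds.samples, rohet_scheme)
        write_csv(animal_roh, os.path.join(out, "animal_summary_roh.csv"))
        write_csv(animal_rohet, os.path.join(out, "animal_summary_rohet.csv"))
        write_csv(breed_summary(animal_roh),
                  os.path.join(out, "breed_summary_roh.csv"))
        write_csv(breed_summary(animal_rohet),
                  os.path.join(out, "breed_summary_rohet.csv"))
        froh = coefficient_table(roh_runs, ds.samples, ds.map, roh_scheme,
                                 config.autosomes)
        drohet = coefficient_table(rohet_runs, ds.samples, ds.map,
                                   rohet_scheme, config.autosomes)
        write_csv(froh, os.path.join(out, "froh.csv"))
        write_csv(drohet, os.path.join(out, "drohet.csv"))
        stage("summarize", n_animal_rows=len(animal_roh) + len(animal_rohet),
              seconds=round(time.time() - t0, 2))

        # 5. islands (+ optional annotation overlap)
        t0 = time.time()
        island_list, incidence = call_islands(
            roh_runs, ds.map, ds.samples,
            pct=config.island_pct,
            min_island_snps=config.min_island_snps,
            per_breed=config.islands_per_breed,
        )
        isl_df = islands_to_frame(island_list)
        write_csv(isl_df.drop(columns=["snp_ids"]),
                  os.path.join(out, "islands.csv"))
        if len(isl_df):
            bed_df = isl_df.rename(columns={"population": "sample_id"})
            write_segments_bed(bed_df, os.path.join(out, "islands.bed"))
        else:
            write_segments_bed(pd.DataFrame(
                columns=["chromosome", "start_bp", "end_bp", "sample_id"]),
                os.path.join(out, "islands.bed"))
        n_overlaps = 0
        if config.annotation_paths:
            annotations = []
            for p in config.annotation_paths:
                annotations.extend(read_annotation_bed(p))
            overlaps = overlap_annotations(island_list, annotations)
            write_csv(overlaps_to_frame(overlaps),
                      os.path.join(out, "overlaps.csv"))
            n_overlaps = len(overlaps)
        else:
            logger.info("no annotation files configured; overlap stage skipped")
        if config.make_plots:
            from .plotting import incidence_manhattan
            plot_dir = os.path.join(out, "plots")
            os.makedirs(plot_dir, exist_ok=True)
            for pop, sub in incidence.groupby("population", sort=False):
                incidence_manhattan(
                    sub, float(sub["threshold"].iloc[0]),
                    os.path.join(plot_dir, f"incidence_{pop}.png"),
                    title=f"ROH incidence — {pop}",
                )
        stage("islands", n_islands=len(island_list), n_overlaps=n_overlaps,
              seconds=round(time.time() - t0, 2))

        # 6. breed comparisons
        t0 = time.time()
        tests = pairwise_breed_tests(animal_roh)
        write_csv(tests, os.path.join(out, "pairwise_tests_roh.csv"))
        tests_het = pairwise_breed_tests(animal_rohet)
        write_csv(tests_het, os.path.join(out, "pairwise_tests_rohet.csv"))
        stage("compare", n_tests=len(tests) + len(tests_het),
              seconds=round(time.time() - t0, 2))
    except Exception as exc:
        manifest["stages"].append({
            "name": "failed", "status": "error", "error": str(exc)})
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        stable = {k: v for k, v in manifest.items()}
        json.dump(stable, fh, indent=2, sort_keys=True)
    return manifest
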