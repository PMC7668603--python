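"""End-to-end orchestration: simulate -> trim -> align -> quantify ->
normalize -> differential expression -> clustering -> report.

A run is driven by a single :class:`RunConfig` (loadable from YAML); every
stage's parameters and seeds land in a manifest JSON so that a run can be
reproduced exactly.  Deterministic stages are bit-identical across reruns
with the same configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .annotate_quantify import (AssignmentWindows, CountMatrix, count_sample,
                                count_spikeins, liftover_annotations,
                                merge_counts, read_bed)
from .cluster_report import (build_dendrogram, correlation_matrix,
                             label_association, select_candidates)
from .mini_align import AlignerParams, align_reads, build_index
from .normalize_diffexp import (class_enrichment_test, differential_expression,
                                spikein_normalize)
from .preprocess import TrimParams, read_fastq, trim_reads
from .synthetic_data import (SimulationDesign, read_fasta, simulate_experiment,
                             write_simulation)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` holds a :class:`SimulationDesign` (synthetic mode)
    or the genome/annotations/spike-ins/FASTQ paths point at real inputs.
    """

    outdir: str = "exomir_run"
    simulate: SimulationDesign | None = None
    genome: str | None = None
    annotations: str | None = None
    spikeins: str | None = None
    fastq: dict[str, str] | None = None       # sample -> fastq path
    sample_sheet: str | None = None
    chain_file: str | None = None             # liftover applied to piRNAs
    liftover_min_ratio: float = 0.95
    trim: TrimParams = field(default_factory=TrimParams)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    windows: AssignmentWindows = field(default_factory=AssignmentWindows)
    candidate_threshold: float = 0.05
    batch_covariate: bool = False
    max_candidates: int = 12
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        cfg = dict(cfg)
        if "simulate" in cfg and cfg["simulate"] is not None:
            sim = dict(cfg["simulate"])
            for key in ("groups", "batches", "timepoints"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "jitter_probs" in sim:
                sim["jitter_probs"] = {int(k): float(v)
                                       for k, v in sim["jitter_probs"].items()}
            cfg["simulate"] = SimulationDesign(**sim)
        if "trim" in cfg:
            cfg["trim"] = TrimParams(**cfg["trim"])
        if "aligner" in cfg:
            cfg["aligner"] = AlignerParams(**cfg["aligner"])
        if "windows" in cfg:
            cfg["windows"] = AssignmentWindows(**cfg["windows"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(str(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every invariant violation; an empty list means valid."""
    errors: list[str] = []

    def check(build, msg):
        try:
            build()
        except (ValueError, TypeError) as exc:
            errors.append(f"{msg}: {exc}")

    check(lambda: TrimParams(**asdict(cfg.trim)), "trim")
    check(lambda: AlignerParams(**asdict(cfg.aligner)), "aligner")
    check(lambda: AssignmentWindows(**asdict(cfg.windows)), "windows")
    if not 0 < cfg.candidate_threshold < 1:
        errors.append("candidate_threshold must be in (0,1)")
    if cfg.simulate is None:
        for name in ("genome", "annotations", "sample_sheet"):
            path = getattr(cfg, name)
            if path is None:
                errors.append(f"{name} path required when not simulating")
            elif not Path(path).exists():
                errors.append(f"{name} path does not exist: {path}")
        if cfg.fastq:
            for sample, path in cfg.fastq.items():
                if not Path(path).exists():
                    errors.append(f"fastq for {sample} missing: {path}")
        elif cfg.fastq is not None and not cfg.fastq:
            errors.append("fastq map is empty")
    if cfg.chain_file and not Path(cfg.chain_file).exists():
        errors.append(f"chain_file does not exist: {cfg.chain_file}")
    return errors


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "seed": cfg.seed,
                                "stages": {}, "parameters": {
                                    "trim": asdict(cfg.trim),
                                    "aligner": asdict(cfg.aligner),
                                    "windows": asdict(cfg.windows),
                                    "candidate_threshold":
                                        cfg.candidate_threshold,
                                    "batch_covariate": cfg.batch_covariate}}

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                        **info}
        return done

    # --- inputs -----------------------------------------------------------
    if cfg.simulate is not None:
        end = stage("simulate")
        design = cfg.simulate
        genome, annotations, spikeins, sim = simulate_experiment(design)
        write_simulation(sim, genome, spikeins, annotations, out / "sim")
        sheet = sim.sheet
        libraries = sim.reads
        manifest["parameters"]["simulate"] = _design_dict(design)
        end(samples=len(sheet), species=len({a.species_id
                                             for a in annotations}))
    else:
        end = stage("load_inputs")
        genome = read_fasta(cfg.genome)
        annotations = read_bed(cfg.annotations)
        spikeins = read_fasta(cfg.spikeins) if cfg.spikeins else {}
        sheet = pd.read_csv(cfg.sample_sheet, sep="\t")
        libraries = {s: read_fastq(p) for s, p in (cfg.fastq or {}).items()}
        end(samples=len(sheet))

    if cfg.chain_file:
        end = stage("liftover")
        pirna = [a for a in annotations if a.rna_class == "piRNA"]
        rest = [a for a in annotations if a.rna_class != "piRNA"]
        lifted, rejected = liftover_annotations(pirna, cfg.chain_file,
                                                cfg.liftover_min_ratio)
        annotations = rest + lifted
        end(lifted=len(lifted), rejected=len(rejected))

    # --- trim -> align -> quantify ---------------------------------------
    index = build_index(genome)
    columns: dict[str, pd.Series] = {}
    total_mapped: dict[str, float] = {}
    spike_totals: dict[str, float] = {}
    attrition: dict[str, dict] = {}
    align_stats: dict[str, dict] = {}
    end = stage("trim_align_quantify")
    for sample in sheet["sample"]:
        reads = libraries[sample]
        trimmed, report = trim_reads(reads, cfg.trim)
        attrition[sample] = report
        spike_counts = count_spikeins(trimmed, spikeins) if spikeins else \
            pd.Series(dtype=float)
        by_read, astats = align_reads(trimmed, index, cfg.aligner)
        align_stats[sample] = astats
        col, cstats = count_sample(by_read, annotations, cfg.windows)
        columns[sample] = col
        total_mapped[sample] = astats["mapped_reads"]
        spike_totals[sample] = float(spike_counts.sum())
    classes = pd.Series({a.species_id: a.rna_class for a in annotations})
    matrix = merge_counts(columns, sheet, classes, total_mapped, spike_totals)
    matrix.to_tsv(out / "counts.tsv", out / "counts_meta.json")
    mapped = sum(s["mapped_reads"] for s in align_stats.values())
    total = sum(s["total_reads"] for s in align_stats.values())
    unique = sum(s["unique_mapped_reads"] for s in align_stats.values())
    end(attrition=attrition,
        mapping_rate=round(mapped / total, 4) if total else None,
        unique_fraction_of_mapped=round(unique / mapped, 4) if mapped else None)

    # --- normalize + enrichment ------------------------------------------
    end = stage("normalize")
    normalized = spikein_normalize(matrix)
    normalized.to_tsv(out / "counts_normalized.tsv")
    enr = class_enrichment_test(normalized)
    with open(out / "class_enrichment.json", "w") as fh:
        json.dump({"t_stat": enr.t_stat, "p_value": enr.p_value,
                   "df": enr.df, "mean_difference": enr.mean_difference,
                   "ci": [enr.ci_low, enr.ci_high]}, fh, indent=2)
    end(class_enrichment_p=enr.p_value)

    # --- differential expression ------------------------------------------
    end = stage("differential_expression")
    timepoints = sorted(sheet["timepoint"].unique())
    de_tables: dict[str, pd.DataFrame] = {}
    candidate_frames = []
    for tp in timepoints:
        for cls in ("miRNA", "piRNA"):
            de = differential_expression(
                matrix, sheet, tp, cls,
                batch_covariate=cfg.batch_covariate,
                candidate_threshold=cfg.candidate_threshold)
            if de.empty:
                continue
            de.to_csv(out / f"de_{cls}_{tp}.tsv", sep="\t",
                      index_label="species")
            de_tables[f"{cls}_{tp}"] = de
            if cls == "miRNA":
                cand = select_candidates(de, cfg.max_candidates,
                                         cfg.candidate_threshold)
                cand.insert(0, "timepoint", tp)
                candidate_frames.append(cand)
    candidates = (pd.concat(candidate_frames)
                  if candidate_frames else pd.DataFrame())
    candidates.to_csv(out / "candidates.tsv", sep="\t",
                      index_label="species")
    end(n_candidates=len(candidates),
        tables={k: int(v["candidate"].sum()) for k, v in de_tables.items()})

    # --- clustering --------------------------------------------------------
    end = stage("cluster")
    corr = correlation_matrix(normalized, rna_class="miRNA")
    corr.to_csv(out / "correlation_miRNA.tsv", sep="\t")
    tree = build_dendrogram(corr)
    (out / "dendrogram_miRNA.nwk").write_text(tree.newick() + "\n")
    assoc = {}
    labels = sheet.set_index("sample")
    for col in ("batch", "condition", "timepoint"):
        if labels[col].nunique() < 2:
            continue
        res = label_association(corr, labels[col], n_permutations=2000,
                                seed=cfg.seed)
        assoc[col] = {"score": res.score, "p_value": res.p_value}
    with open(out / "label_association.json", "w") as fh:
        json.dump(assoc, fh, indent=2)
    end(**{k: round(v["score"], 4) for k, v in assoc.items()})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _design_dict(design: SimulationDesign) -> dict:
    d = asdict(design)
    d["jitter_probs"] = {str(k): v for k, v in d["jitter_probs"].items()}
    return d
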