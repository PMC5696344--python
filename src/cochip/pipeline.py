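"""Reproducible simulate -> quantify -> analyze -> report pipeline.

Stages hand files to each other on disk so each one is independently
inspectable and the whole run is byte-reproducible under a fixed seed.
Every stage appends one structured log line (name, wall time, md5 of its
inputs) and the run ends with a machine-readable summary that echoes the
full configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage_quant import build_coverage, quantify_regions
from .genome_io import read_bed_frame, read_intervals, write_bed_frame, write_intervals
from .kinetics import compare_fits, fit_mm
from .peak_analysis import (correlate_intensities, dependency_analysis,
                            metaprofile, overlap_peaks, signal_matrix,
                            stratify_by_cofactor)
from .synthetic_data import (SimConfig, generate_annotation, generate_expression,
                             generate_kinetics, generate_landscape, generate_reads)
from .target_genes import (assign_targets, detect_super_targets,
                           fold_change_classify, repression_enrichment,
                           score_and_rank)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

SAMPLES = [
    ("WT", "Ash1"), ("WT", "Mrg15"), ("WT", "H3K36me2"),
    ("Ash1KD", "Ash1"), ("Ash1KD", "H3K36me2"),
    ("Mrg15KD", "Ash1"), ("Mrg15KD", "H3K36me2"),
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""


@dataclass
class RunConfig:
    """Pipeline parameters; every field is echoed into the results bundle."""

    seed: int = 0
    outdir: str = "cochip_run"
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    fragment_size: int = 250
    bin_size: int = 50
    depth_scale: float = 1e7
    profile_window: int = 2000
    top_n: int = 200
    share_threshold: float = 0.45
    n_strata: int = 5
    n_ash1_strata: int = 3
    fold: float = 2.0
    pseudocount: float = 1.0
    run_kinetics: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Log:
    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def stage(self, name, seconds, inputs=(), note=""):
        hashes = ",".join(f"{Path(p).name}:{_md5(p)}" for p in inputs)
        line = f"stage={name}\tseconds={seconds:.2f}\tinputs={hashes}\t{note}\n"
        with open(self.path, "a") as fh:
            fh.write(line)


def _require(path, stage):
    if not Path(path).exists():
        raise PipelineError(f"stage {stage!r}: missing input file {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the results bundle.

    Outputs land in ``config.outdir``: simulated inputs (GTF/BED/TSV),
    per-stage TSV/JSON results, ``pipeline.log`` and ``run_summary.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "pipeline.log")
    bundle: dict = {"version": __version__, "config": asdict(config)}
    results: dict = {}

    # --- stage: simulate ---------------------------------------------------
    t0 = time.perf_counter()
    sim = SimConfig(seed=config.seed, **config.simulate)
    genes = generate_annotation(sim)
    truth = generate_landscape(sim, genes)
    gtf = out / "annotation.gtf"
    write_intervals(genes, gtf, format="gtf")
    ash1_bed, mrg15_bed = out / "ash1_peaks.bed", out / "mrg15_peaks.bed"
    write_intervals(truth.ash1_peak_objects(), ash1_bed, format="bed")
    write_intervals(truth.mrg15_peak_objects(), mrg15_bed, format="bed")
    read_paths = {}
    for cond, ab in SAMPLES:
        p = out / f"reads_{cond}_{ab}.bed"
        write_bed_frame(generate_reads(truth, cond, ab), p)
        read_paths[(cond, ab)] = p
    expr_tsv = out / "expression.tsv"
    generate_expression(truth).to_csv(expr_tsv, sep="\t", index=False)
    truth.to_json(out / "truth.json")
    log.stage("simulate", time.perf_counter() - t0,
              [gtf, ash1_bed, mrg15_bed, expr_tsv])

    # --- stage: coverage ---------------------------------------------------
    t0 = time.perf_counter()
    reads = {key: read_bed_frame(_require(p, "coverage"))
             for key, p in read_paths.items()}
    chrom_sizes = dict(sim.chrom_sizes)
    track_wt_ash1 = build_coverage(reads[("WT", "Ash1")], config.fragment_size,
                                   config.bin_size, config.depth_scale, chrom_sizes)
    bg_path = out / "coverage_WT_Ash1.bedgraph"
    track_wt_ash1.to_bedgraph(bg_path)
    log.stage("coverage", time.perf_counter() - t0, [read_paths[("WT", "Ash1")]])

    # --- stage: overlap ----------------------------------------------------
    t0 = time.perf_counter()
    ash1_peaks = read_intervals(_require(ash1_bed, "overlap"))
    mrg15_peaks = read_intervals(_require(mrg15_bed, "overlap"))
    ov = overlap_peaks(ash1_peaks, mrg15_peaks)
    results["overlap"] = {
        "n_ash1": ov.n_a, "n_mrg15": ov.n_b,
        "ash1_overlapping": ov.count_overlapping_a,
        "ash1_overlap_fraction": ov.fraction_a,
        "mrg15_overlapping": ov.count_overlapping_b,
    }
    (out / "overlap.json").write_text(json.dumps(results["overlap"], indent=1,
                                                 sort_keys=True))
    log.stage("overlap", time.perf_counter() - t0, [ash1_bed, mrg15_bed])

    # --- stage: signal matrix ---------------------------------------------
    t0 = time.perf_counter()
    samples = {f"{ab}:{cond}": reads[(cond, ab)] for cond, ab in SAMPLES}
    matrix = signal_matrix(ash1_peaks, samples, config.fragment_size,
                           config.depth_scale).sorted_by("Ash1:WT")
    matrix_tsv = out / "signal_matrix.tsv"
    matrix.table.to_csv(matrix_tsv, sep="\t")
    log.stage("signal_matrix", time.perf_counter() - t0, [ash1_bed])

    # --- stage: metaprofile -------------------------------------------------
    t0 = time.perf_counter()
    prof = metaprofile(ash1_peaks, track_wt_ash1, window=config.profile_window)
    prof_tsv = out / "profile_WT_Ash1.tsv"
    pd.DataFrame({"offset": prof.offsets,
                  "mean_density": prof.mean_profile}).to_csv(prof_tsv, sep="\t",
                                                             index=False)
    log.stage("metaprofile", time.perf_counter() - t0, [bg_path])

    # --- stage: correlation -------------------------------------------------
    t0 = time.perf_counter()
    tbl = matrix.table
    r, n = correlate_intensities(tbl["Ash1:WT"], tbl["Mrg15:WT"])
    results["correlation"] = {"R": r, "n": n, "transform": "log2(1+d)"}
    (out / "correlation.json").write_text(json.dumps(results["correlation"],
                                                     indent=1, sort_keys=True))
    log.stage("correlation", time.perf_counter() - t0, [matrix_tsv])

    # --- stage: stratification ----------------------------------------------
    t0 = time.perf_counter()
    strat = stratify_by_cofactor(tbl["H3K36me2:WT"], tbl["Mrg15:WT"],
                                 tbl["Ash1:WT"], n_strata=config.n_ash1_strata)
    strat_tsv = out / "stratified_k36.tsv"
    strat.summary.to_csv(strat_tsv, sep="\t", index=False)
    results["stratified"] = {
        f"stratum{s}": {"high": strat.median("high", s), "low": strat.median("low", s)}
        for s in range(config.n_ash1_strata)
    }
    log.stage("stratify", time.perf_counter() - t0, [matrix_tsv])

    # --- stage: dependency ---------------------------------------------------
    t0 = time.perf_counter()
    dep = dependency_analysis(tbl["Ash1:WT"], tbl["Ash1:Mrg15KD"],
                              n_strata=config.n_strata)
    dep_tsv = out / "dependency_ash1_mrg15kd.tsv"
    dep.to_csv(dep_tsv, sep="\t", index=False)
    k36 = {}
    for cond in ("Ash1KD", "Mrg15KD"):
        d1 = dependency_analysis(tbl["H3K36me2:WT"], tbl[f"H3K36me2:{cond}"],
                                 n_strata=1)
        k36[cond] = float(d1["retained"].iloc[0])
    results["dependency"] = {
        "ash1_retained_by_stratum": dep["retained"].tolist(),
        "h3k36me2_retained": k36,
    }
    log.stage("dependency", time.perf_counter() - t0, [matrix_tsv])

    # --- stage: target genes -------------------------------------------------
    t0 = time.perf_counter()
    genes_in = read_intervals(_require(gtf, "targets"), format="gtf")
    targets = assign_targets(genes_in, ash1_peaks)
    target_genes = [g for g in genes_in
                    if targets.set_index("gene_id")["has_peak"].get(g.gene_id, False)]
    ranked = score_and_rank(target_genes, reads[("WT", "Ash1")], top_n=config.top_n,
                            fragment_size=config.fragment_size,
                            depth_scale=config.depth_scale, chrom_sizes=chrom_sizes)
    ranked_tsv = out / "target_ranking.tsv"
    ranked.to_csv(ranked_tsv, sep="\t", index=False)
    supers = detect_super_targets(ranked, config.share_threshold)
    (out / "super_targets.txt").write_text("\n".join(supers.super_target_ids) + "\n")
    results["super_targets"] = {
        "n_targets": len(target_genes), "top_n": supers.top_n,
        "n_super": supers.n_super, "share_captured": supers.share_captured,
    }
    log.stage("targets", time.perf_counter() - t0, [gtf, ash1_bed])

    # --- stage: expression ---------------------------------------------------
    t0 = time.perf_counter()
    expr = pd.read_csv(_require(expr_tsv, "expression"), sep="\t")
    classes = fold_change_classify(expr["wt"], expr["ash1_kd"], expr["gene_id"],
                                   pseudocount=config.pseudocount, fold=config.fold)
    top_ids = set(ranked.loc[ranked["in_top_n"], "gene_id"])
    sub = classes[classes["gene_id"].isin(top_ids)].reset_index(drop=True)
    super_ids = set(supers.super_target_ids)
    enrich = repression_enrichment(sub["class"],
                                   sub["gene_id"].isin(super_ids).to_numpy())
    target_ids = set(targets.loc[targets["has_peak"], "gene_id"])
    tgt_classes = classes[classes["gene_id"].isin(target_ids)]
    results["expression"] = {
        "n_down": int((tgt_classes["class"] == "down").sum()),
        "n_up": int((tgt_classes["class"] == "up").sum()),
        "enrichment_odds_ratio": enrich["odds_ratio"],
        "enrichment_p": enrich["p"],
    }
    classes_tsv = out / "expression_classes.tsv"
    classes.to_csv(classes_tsv, sep="\t", index=False)
    log.stage("expression", time.perf_counter() - t0, [expr_tsv, ranked_tsv])

    # --- stage: kinetics -----------------------------------------------------
    if config.run_kinetics:
        t0 = time.perf_counter()
        rng = np.random.default_rng([config.seed % (2**31), 900])
        base = generate_kinetics(vmax=10.0, km=2.0, rng=rng, label="Ash1C")
        stim = generate_kinetics(vmax=25.0, km=2.0, rng=rng, label="Ash1C-Mrg15")
        fit_a, fit_b = fit_mm(base), fit_mm(stim)
        comp = compare_fits(fit_a, fit_b)
        results["kinetics"] = {
            "Ash1C": {"Vmax": fit_a.vmax, "Km": fit_a.km,
                      "Vmax_sem": fit_a.vmax_sem, "Km_sem": fit_a.km_sem},
            "Ash1C-Mrg15": {"Vmax": fit_b.vmax, "Km": fit_b.km,
                            "Vmax_sem": fit_b.vmax_sem, "Km_sem": fit_b.km_sem},
            "t_test": comp,
        }
        (out / "kinetics.json").write_text(json.dumps(results["kinetics"],
                                                      indent=1, sort_keys=True))
        log.stage("kinetics", time.perf_counter() - t0, [])

    bundle["results"] = results
    (out / "run_summary.json").write_text(json.dumps(bundle, indent=1,
                                                     sort_keys=True))
    return bundle
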