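"""End-to-end orchestration: config validation, stage chaining, run manifest.

All thresholds default to the study values (signal/noise floor 20, log2FC
0.5, 50% feature overlap, 2-kb promoters, 6-nt motifs, alpha 0.05); every
stage exchanges data through files under the output directory, and a
machine-readable manifest records parameter snapshots and output hashes so
deterministic stages can be verified to reproduce byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    binding_kinetics as bk,
    de_integration as dei,
    genomic_core as gc,
    interactome as im,
    motif_enrichment as me,
    peak_analysis as pa,
    synthetic_data as sd,
)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tsppi_out"
    sn_threshold: float = 20.0
    log2fc_threshold: float = 0.5
    min_overlap: float = 0.5
    promoter_width_bp: int = 2000
    flank_bp: int = 5000  # methods-mode gene pairing
    vicinity_bp: int = 1000  # results-mode vicinity for the ChIP-RNA intersection
    motif_k: int = 6
    alpha: float = 0.05
    min_unique_peptides: int = 1
    shared_policy: str = "both"
    steady_state_window_s: float = 5.0

    def validate(self) -> None:
        if self.sn_threshold <= 0:
            raise ValueError("sn_threshold must be > 0")
        if self.log2fc_threshold < 0:
            raise ValueError("log2fc_threshold must be >= 0")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.flank_bp < 0 or self.vicinity_bp < 0 or self.promoter_width_bp <= 0:
            raise ValueError("widths must be non-negative")
        if self.motif_k < 1:
            raise ValueError("motif_k must be >= 1")
        if self.shared_policy not in ("both", "either"):
            raise ValueError("shared_policy must be 'both' or 'either'")


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; missing keys take defaults.

    Unknown keys are rejected; numeric strings are coerced with a warning on
    stderr.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        target = known[key].type
        if isinstance(value, str) and target in ("float", "int"):
            print(f"warning: coercing {key}={value!r} to number", file=sys.stderr)
            value = float(value) if target == "float" else int(value)
        coerced[key] = value
    config = PipelineConfig(**coerced)
    config.validate()
    return config


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "timestamp": time.time(),
                "outputs": {p.name: _hash_file(p) for p in sorted(outputs) if p.exists()},
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"parameters": self.parameters, "stages": self.stages}, fh, indent=1)


# ---------------------------------------------------------------------------
# Stages (each reads/writes files under outdir)


def stage_simulate(config: PipelineConfig, outdir: Path) -> Path:
    simdir = outdir / "sim"
    sim_config = sd.SimConfig(seed=config.seed)
    sd.simulate_all(sim_config, simdir)
    return simdir


def stage_interactome(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    manifest = pd.read_csv(simdir / "run_manifest.tsv", sep="\t")
    runs_a, runs_b = [], []
    for row in manifest.itertuples(index=False):
        run = im.RimeRun(
            row.run_id,
            row.group,
            im.read_hit_table(simdir / row.bait_path),
            im.read_hit_table(simdir / row.igg_path),
        )
        (runs_a if row.group == "TNBC" else runs_b).append(run)
    comparison = im.compare_groups(runs_a, runs_b, config.min_unique_peptides)
    im.summary_table(comparison).to_csv(outdir / "interactome_summary.tsv", sep="\t", index=False)
    candidates = im.nominate_candidates(comparison)
    candidates.to_csv(outdir / "interactome_candidates.tsv", sep="\t", index=False)
    scores = pd.DataFrame(
        sorted(comparison.cumulative_scores.items()), columns=["accession", "cumulative_score"]
    )
    scores.to_csv(outdir / "interactome_scores.tsv", sep="\t", index=False)
    return {
        "candidates": list(candidates["accession"]),
        "a_union": len(comparison.a_union),
        "b_union": len(comparison.b_union),
        "shared": len(comparison.shared),
        "a_only": len(comparison.a_only),
    }


def stage_peaks(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    samples = [f"chip_{ip}_{cond}" for ip, cond in sd.CHIP_SAMPLES]
    peak_sets = {s: gc.read_bed(simdir / f"{s}.bed") for s in samples}
    coverage = {s: gc.read_bedgraph(simdir / f"{s}.bedgraph") for s in samples}
    genome = gc.read_fasta(simdir / "genome.fa")
    genes = gc.read_gene_models(simdir / "genes.tsv", "tsv")

    catalog = pa.build_consensus(peak_sets, known_chroms=genome.chroms)
    matrix = pa.quantify(catalog, coverage, read_length=100)
    matrix = pa.apply_noise_threshold(matrix, config.sn_threshold)
    control_of = {
        f"chip_{ip}_{cond}": f"chip_{ip}_control" for ip, cond in sd.CHIP_SAMPLES
    }
    matrix = pa.scale_to_control_mode(matrix, control_of)
    sample_plan = {
        (ip[-1], cond if cond == "control" else cond[-1]): f"chip_{ip}_{cond}"
        for ip, cond in sd.CHIP_SAMPLES
    }
    result = pa.run_codependency(
        matrix, sample_plan, config.log2fc_threshold, config.shared_policy
    )
    matrix.values.to_csv(outdir / "peak_matrix.tsv", sep="\t")
    gc.write_bed(
        [dataclasses.replace(p.interval, name=p.peak_id) for p in catalog],
        outdir / "consensus_peaks.bed",
    )
    classes = pd.DataFrame(
        sorted(result.classes.items()), columns=["peak_id", "class"]
    )
    classes.to_csv(outdir / "peak_classes.tsv", sep="\t", index=False)

    tracks = []
    for label in ("cpg_island", "enhancer", "tfbs", "ctcf"):
        path = simdir / f"track_{label}.bed"
        if path.exists():
            tracks.append(gc.FeatureTrack(label, gc.read_bed(path)))
    chrom_lengths = {c: genome.length(c) for c in genome.chroms}
    annotation = pa.annotate(
        catalog, genes, tracks, config.min_overlap, config.promoter_width_bp, chrom_lengths
    )
    annotation.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
    pairs = pa.pair_with_genes(catalog, genes, config.vicinity_bp)
    pairs.to_csv(outdir / "peak_gene_pairs.tsv", sep="\t", index=False)
    return {"n_consensus": len(catalog), "class_counts": result.class_counts()}


def stage_atac(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    coverage = {s: gc.read_bedgraph(simdir / f"{s}.bedgraph") for s in sd.ATAC_SAMPLES}
    site_ivs = gc.read_bed(simdir / "atac_sites.bed")
    regions = [pa.ConsensusPeak(iv.name, iv, {"atac": [iv]}) for iv in site_ivs]
    matrix = pa.quantify(regions, coverage, read_length=100)
    matrix = pa.quantile_normalise(matrix)
    # promoters of genes adjacent to co-dependent (shared) binding loci, if
    # the ChIP stage has run already
    codependent_genes: set[str] = set()
    pairs_path, classes_path = outdir / "peak_gene_pairs.tsv", outdir / "peak_classes.tsv"
    if pairs_path.exists() and classes_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t")
        classes = pd.read_csv(classes_path, sep="\t")
        shared_peaks = set(classes.loc[classes["class"] == "shared", "peak_id"])
        codependent_genes = set(pairs.loc[pairs["peak_id"].isin(shared_peaks), "gene_id"])
    changes, codependent_changes = {}, {}
    for kd in ("atac_kdA", "atac_kdB"):
        fc = pa.accessibility_change(matrix, "atac_control", kd)
        fc.to_csv(outdir / f"atac_log2fc_{kd[-1]}.tsv", sep="\t", index=False)
        changes[kd] = float(fc["log2fc"].mean())
        if codependent_genes:
            sub = fc[fc["peak_id"].isin(codependent_genes)]
            codependent_changes[kd] = float(sub["log2fc"].mean())
    return {"mean_log2fc": changes, "mean_log2fc_codependent_promoters": codependent_changes}


def stage_motifs(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    genome = gc.read_fasta(simdir / "genome.fa")
    genes = gc.read_gene_models(simdir / "genes.tsv", "tsv")
    catalog_bed = outdir / "consensus_peaks.bed"
    classes = pd.read_csv(outdir / "peak_classes.tsv", sep="\t")
    peaks = gc.read_bed(catalog_bed)
    shared_ids = set(classes.loc[classes["class"] == "shared", "peak_id"])
    fg_ivs = [iv for iv in peaks if iv.name in shared_ids]
    chrom_lengths = {c: genome.length(c) for c in genome.chroms}
    promoters = [
        p
        for g in genes
        if (p := gc.promoter_of(g, config.promoter_width_bp, chrom_lengths.get(g.interval.chrom)))
        is not None
    ]
    fg = me.count_kmer_presence(me.extract_sequences(fg_ivs, genome), config.motif_k)
    bg_all = me.count_kmer_presence(me.extract_sequences(peaks, genome), config.motif_k)
    bg_up = me.count_kmer_presence(me.extract_sequences(promoters, genome), config.motif_k)
    report = me.dual_background_report(fg, bg_all, bg_up, config.alpha)
    report.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    results = me.fisher_enrichment(fg, bg_all, config.alpha, background_label="all_peaks")
    me.write_meme_minimal(results, str(outdir / "motifs_significant.meme"), config.alpha)
    top = report.sort_values("p_value").iloc[0]["kmer"] if len(report) else ""
    return {"top_motif": top, "n_tested": int(report["kmer"].nunique()) if len(report) else 0}


def stage_integrate(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    de_a = dei.read_de_table(simdir / "de_knockdownA.tsv", config.alpha)
    de_b = dei.read_de_table(simdir / "de_knockdownB.tsv", config.alpha)
    classification = dei.classify_overlap(de_a, de_b)
    shared = dei.shared_fc_table(de_a, de_b, classification)
    trend = dei.fit_trend(shared["log2fc_a"].to_numpy(), shared["log2fc_b"].to_numpy())
    pairs = pd.read_csv(outdir / "peak_gene_pairs.tsv", sep="\t")
    classes = pd.read_csv(outdir / "peak_classes.tsv", sep="\t")
    shared_peaks = set(classes.loc[classes["class"] == "shared", "peak_id"])
    shared_pairs = pairs[pairs["peak_id"].isin(shared_peaks)]
    intersection = dei.intersect_chip_rna(classification, shared_pairs)
    quad = pd.DataFrame(sorted(classification.counts().items()), columns=["set", "n"])
    quad.to_csv(outdir / "de_quadrants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"slope": trend.slope, "intercept": trend.intercept, "r_squared": trend.r_squared, "n": trend.n}]
    ).to_csv(outdir / "de_trend.tsv", sep="\t", index=False)
    intersection.to_csv(outdir / "chip_rna_intersection.tsv", sep="\t", index=False)
    return {
        "quadrants": classification.counts(),
        "r_squared": trend.r_squared,
        "n_intersection": len(intersection),
        "intersection_directions": intersection["direction"].value_counts().to_dict()
        if len(intersection)
        else {},
    }


def stage_spr(config: PipelineConfig, simdir: Path, outdir: Path) -> dict:
    pairs = sd.read_sensorgram_csv(simdir / "sensorgrams.csv")
    blank = next(p for p in pairs if p[0].concentration_nM == 0.0)
    concs, reqs, rows = [], [], []
    for active, reference in pairs:
        if active.concentration_nM == 0.0:
            continue
        corrected = bk.double_reference(active, reference, blank[0], blank[1])
        req, equilibrated = bk.steady_state_response(corrected, config.steady_state_window_s)
        concs.append(active.concentration_nM)
        reqs.append(req)
        rows.append((active.cycle_id, active.concentration_nM, req, equilibrated))
    fit = bk.fit_steady_state(np.array(concs), np.array(reqs))
    pd.DataFrame(rows, columns=["cycle_id", "concentration_nM", "req_RU", "equilibrated"]).to_csv(
        outdir / "spr_req.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"kd_nM": fit.kd_nM, "rmax_RU": fit.rmax_RU, "rss": fit.rss, "converged": fit.converged}]
    ).to_csv(outdir / "spr_fit.tsv", sep="\t", index=False)
    return {"kd_nM": fit.kd_nM, "rmax_RU": fit.rmax_RU, "converged": fit.converged}


STAGES = [
    ("simulate", None),
    ("interactome", stage_interactome),
    ("peaks", stage_peaks),
    ("atac", stage_atac),
    ("motifs", stage_motifs),
    ("integrate", stage_integrate),
    ("spr", stage_spr),
]


def run_all(config: PipelineConfig) -> dict:
    """Chain all stages on a fresh synthetic dataset; returns the summary report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters=dataclasses.asdict(config))
    report: dict = {}
    before = set(outdir.glob("*"))
    simdir = stage_simulate(config, outdir)
    manifest.record("simulate", sorted(simdir.glob("*")))
    for stage_name, fn in STAGES:
        if fn is None:
            continue
        try:
            report[stage_name] = fn(config, simdir, outdir)
        except Exception as exc:  # noqa: BLE001 - abort naming the failing stage
            manifest.write(outdir / "run_manifest.json")
            raise RuntimeError(f"stage {stage_name!r} failed: {exc}") from exc
        new = set(outdir.glob("*")) - before - {simdir}
        manifest.record(stage_name, sorted(p for p in new if p.is_file()))
    manifest.write(outdir / "run_manifest.json")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
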