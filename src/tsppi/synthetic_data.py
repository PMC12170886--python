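"""Seeded generator for every input the pipeline consumes, with planted truth.

The generator emulates the statistical structure of a two-factor knockdown
multi-omics study on a small synthetic genome (default 2 chromosomes x 1 Mb,
200 genes, ~560 binding loci), at a scale where every stage runs in seconds:

* ChIP coverage for two IPs (A, B) under control and either knockdown, with
  planted peak classes: A-specific loci lose signal only in IP-A under A
  knockdown, B-specific symmetrically, shared co-dependent loci lose signal
  in BOTH IPs under EITHER knockdown, unchanged loci never move.
* ATAC coverage whose accessibility at co-dependent promoters drops under
  the B knockdown only.
* A GC-rich 6-mer written into shared loci at a configurable planting rate.
* Two DE tables with correlated shared effects whose planted quadrant sizes
  and per-knockdown up/down totals match the study design (237 genes up on
  both knockdowns, 130 down on both, 1 discordant; totals 624 and 820), a
  subset of shared genes being placed next to shared binding loci so the
  ChIP-RNA intersection recovers exactly 78 genes (38 down + 40 up).
* Bait/IgG IP-MS hit tables where one planted accession appears in every
  group-A run and never in group-B or IgG runs.
* Multi-cycle SPR sensorgrams from 1:1 binding kinetics (true KD = kd/ka,
  default 870 nM) with drift and bulk artefacts that double referencing
  removes.

Amplitude noise is multiplicative log-normal; sensorgram noise is additive
Gaussian.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_kinetics import Sensorgram, serial_dilution
from .genomic_core import (
    CoverageTrack,
    FeatureTrack,
    GeneModel,
    Genome,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gene_tsv,
)
from .interactome import ProteinHit, RimeRun

CHIP_SAMPLES = [
    ("ipA", "control"),
    ("ipA", "kdA"),
    ("ipA", "kdB"),
    ("ipB", "control"),
    ("ipB", "kdA"),
    ("ipB", "kdB"),
]
ATAC_SAMPLES = ["atac_control", "atac_kdA", "atac_kdB"]


@dataclass
class PeakPlan:
    n_a_specific: int = 100
    n_b_specific: int = 60
    n_shared: int = 100
    n_unchanged: int = 300
    n_linked_down: int = 38  # shared loci at promoters of co_down DE genes
    n_linked_up: int = 40
    peak_width_bp: int = 400
    amplitude_mean: float = 200.0
    amplitude_sigma_ln: float = 0.2  # log-normal spread of per-locus base amplitude
    # per-sample multiplicative noise; at 0.05 the 0.5 log2FC decision
    # threshold sits ~4 sd from both the unchanged and the reduced class
    # even after worst-case mode-estimation quantisation
    noise_sigma_ln: float = 0.05
    reduction_a: float = 0.5  # knockdown survival factor for A-specific loci
    reduction_b: float = 0.5
    reduction_shared: float = 0.5
    sample_scale_lo: float = 0.8  # per-sample library-size factor range
    sample_scale_hi: float = 1.25
    atac_amplitude: float = 150.0
    # wide spread keeps the site-amplitude distributions overlapping across
    # conditions, so quantile normalisation is near shape-preserving and the
    # planted accessibility fold change survives it
    atac_amplitude_sigma_ln: float = 0.5
    atac_reduction: float = 0.5


@dataclass
class DePlan:
    # class sizes in knockdown-vs-control log2FC sign convention
    n_co_up: int = 237  # up on both knockdowns (repressed by both proteins)
    n_co_down: int = 130  # down on both knockdowns (activated by both proteins)
    n_discordant: int = 1  # down on A knockdown, up on B knockdown
    n_a_only_up: int = 158
    n_a_only_down: int = 98
    n_b_only_up: int = 266
    n_b_only_down: int = 186
    n_null: int = 2000
    effect_size: float = 1.5  # mean |log2FC| of planted genes
    correlation: float = 0.95  # target corr of shared-gene log2FCs

    def __post_init__(self) -> None:
        if not (-1.0 < self.correlation < 1.0):
            raise ValueError("correlation target must be in (-1, 1)")


@dataclass
class InteractomePlan:
    n_runs_a: int = 7
    n_runs_b: int = 2
    n_a_background: int = 60  # group-A interactors seen in some but not all runs
    n_shared_ab: int = 20
    n_b_only: int = 15
    n_contaminants: int = 12  # present in bait and IgG lists
    candidate_accession: str = "CANDID01"
    candidate_gene: str = "Chd8"


@dataclass
class SprPlan:
    ka_per_M_s: float = 1e4
    kd_per_s: float = 8.7e-3  # true KD = kd/ka = 870 nM
    rmax_RU: float = 250.0
    noise_sd_RU: float = 1.0
    top_nM: float = 5737.5
    dilution_factor: float = 3.0
    n_points: int = 8
    association_s: float = 600.0
    dissociation_s: float = 300.0
    dt_s: float = 1.0
    drift_RU_per_s: float = 0.01
    bulk_jump_RU: float = 15.0

    @property
    def true_kd_nM(self) -> float:
        return self.kd_per_s / self.ka_per_M_s * 1e9


@dataclass
class MotifPlan:
    kmer: str = "GCCGCC"
    planting_rate: float = 0.8


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 200
    gc_background: float = 0.45
    read_length: int = 100
    protein_coding_fraction: float = 0.9
    peaks: PeakPlan = field(default_factory=PeakPlan)
    de: DePlan = field(default_factory=DePlan)
    interactome: InteractomePlan = field(default_factory=InteractomePlan)
    spr: SprPlan = field(default_factory=SprPlan)
    motif: MotifPlan = field(default_factory=MotifPlan)

    def noise_free(self) -> "SimConfig":
        """Copy with all stochastic amplitude/response noise switched off."""
        return replace(
            self,
            peaks=replace(
                self.peaks,
                amplitude_sigma_ln=0.0,
                noise_sigma_ln=0.0,
                sample_scale_lo=1.0,
                sample_scale_hi=1.0,
            ),
            spr=replace(self.spr, noise_sd_RU=0.0),
        )


@dataclass
class SimTruth:
    peak_classes: dict[str, str] = field(default_factory=dict)  # locus_id -> class
    peak_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    motif_planted: dict[str, bool] = field(default_factory=dict)
    linked_genes_down: list[str] = field(default_factory=list)
    linked_genes_up: list[str] = field(default_factory=list)
    de_classes: dict[str, str] = field(default_factory=dict)  # gene_id -> class
    atac_sites: dict[str, bool] = field(default_factory=dict)  # site_id -> reduced in B-KD
    atac_regions: list[tuple[str, str, int, int]] = field(default_factory=list)
    candidate_accession: str = ""
    true_kd_nM: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# Genome


_SLOT = 10_000  # one gene per 10-kb slot; gene body occupies [4000, 6000)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[Genome, list[GeneModel], list[FeatureTrack]]:
    """Random genome with tiled genes and placed feature tracks.

    Genes sit one per 10-kb slot (body at slot offset 4000-6000, two exons),
    leaving deterministic intergenic space for peak placement.  GC content
    follows the configured background fraction.
    """
    genes_per_chrom = config.n_genes // config.n_chroms + (config.n_genes % config.n_chroms > 0)
    if genes_per_chrom * _SLOT > config.chrom_len:
        raise ValueError("genome too small for n_genes")
    gc = config.gc_background
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(["A", "C", "G", "T"])
    sequences = {}
    for c in range(config.n_chroms):
        idx = rng.choice(4, size=config.chrom_len, p=probs)
        sequences[f"chr{c + 1}"] = "".join(bases[idx])
    genome = Genome(sequences)

    genes: list[GeneModel] = []
    n_made = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for slot in range(genes_per_chrom):
            if n_made >= config.n_genes:
                break
            start = slot * _SLOT + 4000
            end = start + 2000
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "protein_coding" if rng.random() < config.protein_coding_fraction else "lncRNA"
            )
            exons = (
                GenomicInterval(chrom, start, start + 600, strand),
                GenomicInterval(chrom, start + 1200, end, strand),
            )
            gid = f"gene_{n_made:04d}"
            genes.append(GeneModel(gid, gid.upper(), GenomicInterval(chrom, start, end, strand), exons, biotype))
            n_made += 1

    tracks = []
    for label, width, rate in (("cpg_island", 300, 0.3), ("enhancer", 500, 0.15), ("tfbs", 12, 0.4), ("ctcf", 20, 0.2)):
        ivs = []
        for g in genes:
            if rng.random() < rate:
                tss = g.tss
                lo = max(tss - width // 2, 0)
                hi = min(lo + width, config.chrom_len)
                ivs.append(GenomicInterval(g.interval.chrom, lo, hi))
        tracks.append(FeatureTrack(label, ivs))
    return genome, genes, tracks


# ---------------------------------------------------------------------------
# Peak experiment


def _triangle_profile(depth: np.ndarray, centre: int, width: int, area: float) -> None:
    """Add a triangular pileup of given integrated area centred at ``centre``."""
    half = width // 2
    lo, hi = max(centre - half, 0), min(centre + half, len(depth))
    x = np.arange(lo, hi)
    h = 2.0 * area / width
    depth[lo:hi] += h * (1.0 - np.abs(x - centre) / half)


def _rle_to_track(depth_by_chrom: dict[str, np.ndarray]) -> CoverageTrack:
    records = []
    for chrom, depth in depth_by_chrom.items():
        depth = np.round(depth, 4)
        change = np.flatnonzero(np.diff(depth)) + 1
        bounds = np.concatenate([[0], change, [len(depth)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            d = depth[s]
            if d > 0:
                records.append((chrom, int(s), int(e), float(d)))
    return CoverageTrack.from_records(records)


def _reduction_factor(plan: PeakPlan, cls: str, ip: str, condition: str) -> float:
    """Survival factor applied to a locus amplitude in one ChIP sample."""
    if condition == "control" or cls == "unchanged":
        return 1.0
    if cls == "shared":  # co-dependent: either knockdown hits both IPs
        return plan.reduction_shared
    if cls == "A_specific" and ip == "ipA" and condition == "kdA":
        return plan.reduction_a
    if cls == "B_specific" and ip == "ipB" and condition == "kdB":
        return plan.reduction_b
    return 1.0


def simulate_peak_experiment(
    config: SimConfig,
    genome: Genome,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[
    dict[str, list[GenomicInterval]],
    dict[str, CoverageTrack],
    dict[str, CoverageTrack],
    SimTruth,
]:
    """Plant peak loci and simulate per-sample ChIP and ATAC coverage.

    Returns (per-sample peak intervals, ChIP coverage, ATAC coverage, truth).
    Shared loci linked to DE genes are centred on those genes' TSSs; all
    other loci occupy deterministic intergenic positions so no two loci ever
    merge under the midpoint rule.  Coverage is the expected fragment pileup
    (triangular shape whose integral equals amplitude x read length).
    """
    plan = config.peaks
    pc_genes = [g for g in genes if g.biotype == "protein_coding"]
    n_linked = plan.n_linked_down + plan.n_linked_up
    if n_linked > plan.n_shared:
        raise ValueError("linked loci cannot exceed n_shared")
    if n_linked > len(pc_genes):
        raise ValueError("not enough protein-coding genes for linked loci")
    linked_idx = rng.choice(len(pc_genes), size=n_linked, replace=False)
    linked_genes = [pc_genes[i] for i in linked_idx]
    down_genes = linked_genes[: plan.n_linked_down]
    up_genes = linked_genes[plan.n_linked_down :]

    # intergenic positions: 3 deterministic centres per 10-kb slot
    free_centres = []
    for chrom in genome.chroms:
        n_slots = genome.length(chrom) // _SLOT
        for slot in range(n_slots):
            for off in (7000, 8600, 10200):
                pos = slot * _SLOT + off
                if pos + plan.peak_width_bp // 2 < genome.length(chrom):
                    free_centres.append((chrom, pos))
    n_free_needed = (plan.n_shared - n_linked) + plan.n_a_specific + plan.n_b_specific + plan.n_unchanged
    if n_free_needed > len(free_centres):
        raise ValueError("genome too small for the requested peak plan")
    chosen = rng.choice(len(free_centres), size=n_free_needed, replace=False)
    free_iter = iter(chosen)

    truth = SimTruth(
        linked_genes_down=[g.gene_id for g in down_genes],
        linked_genes_up=[g.gene_id for g in up_genes],
    )
    loci: list[tuple[str, str, int, str]] = []  # (locus_id, chrom, centre, class)
    k = 0

    def add_locus(chrom: str, centre: int, cls: str) -> str:
        nonlocal k
        lid = f"locus_{k:04d}"
        loci.append((lid, chrom, centre, cls))
        w = plan.peak_width_bp
        truth.peak_classes[lid] = cls
        truth.peak_intervals[lid] = (chrom, centre - w // 2, centre + w // 2)
        k += 1
        return lid

    for g in linked_genes:
        add_locus(g.interval.chrom, g.tss, "shared")
    for _ in range(plan.n_shared - n_linked):
        chrom, pos = free_centres[next(free_iter)]
        add_locus(chrom, pos, "shared")
    for cls, n in (("A_specific", plan.n_a_specific), ("B_specific", plan.n_b_specific), ("unchanged", plan.n_unchanged)):
        for _ in range(n):
            chrom, pos = free_centres[next(free_iter)]
            add_locus(chrom, pos, cls)

    # plant the GC-rich 6-mer into shared loci sequences
    seqs = {c: list(genome.sequences[c]) for c in genome.sequences}
    kmer = config.motif.kmer
    for lid, chrom, centre, cls in loci:
        planted = cls == "shared" and rng.random() < config.motif.planting_rate
        truth.motif_planted[lid] = planted
        if planted:
            pos = centre - len(kmer) // 2
            seqs[chrom][pos : pos + len(kmer)] = list(kmer)
    for c in seqs:
        genome.sequences[c] = "".join(seqs[c])

    base_amp = {
        lid: plan.amplitude_mean * float(rng.lognormal(0.0, plan.amplitude_sigma_ln))
        if plan.amplitude_sigma_ln > 0
        else plan.amplitude_mean
        for lid, _, _, _ in loci
    }

    chip_peaks: dict[str, list[GenomicInterval]] = {}
    chip_cov: dict[str, CoverageTrack] = {}
    for ip, condition in CHIP_SAMPLES:
        sample = f"chip_{ip}_{condition}"
        scale = float(rng.uniform(plan.sample_scale_lo, plan.sample_scale_hi))
        depth = {c: np.zeros(genome.length(c)) for c in genome.chroms}
        intervals = []
        for lid, chrom, centre, cls in loci:
            amp = base_amp[lid] * _reduction_factor(plan, cls, ip, condition) * scale
            if plan.noise_sigma_ln > 0:
                amp *= float(rng.lognormal(0.0, plan.noise_sigma_ln))
            _triangle_profile(depth[chrom], centre, plan.peak_width_bp, amp * config.read_length)
            jitter = int(rng.integers(-20, 21))
            half = plan.peak_width_bp // 2
            intervals.append(
                GenomicInterval(chrom, centre - half + jitter, centre + half + jitter, ".", lid)
            )
        chip_peaks[sample] = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
        chip_cov[sample] = _rle_to_track(depth)

    # ATAC: accessibility sites at every protein-coding promoter plus all
    # non-linked binding loci (accessible chromatin, unchanged across
    # conditions); co-dependent promoters (linked genes) lose signal only
    # under the B knockdown.  Site amplitudes get a wide log-normal spread.
    linked_ids = {g.gene_id for g in linked_genes}
    atac_sites: list[tuple[str, str, int, bool]] = []  # (site_id, chrom, centre, reduced_in_kdB)
    for g in pc_genes:
        atac_sites.append((g.gene_id, g.interval.chrom, g.tss, g.gene_id in linked_ids))
    linked_tss = {(g.interval.chrom, g.tss) for g in linked_genes}
    for lid, chrom, centre, _cls in loci:
        if (chrom, centre) not in linked_tss:
            atac_sites.append((f"atac_{lid}", chrom, centre, False))
    atac_base = {
        sid: plan.atac_amplitude
        * (float(rng.lognormal(0.0, plan.atac_amplitude_sigma_ln)) if plan.atac_amplitude_sigma_ln > 0 else 1.0)
        for sid, _, _, _ in atac_sites
    }
    truth.atac_sites = {sid: reduced for sid, _, _, reduced in atac_sites}
    atac_cov: dict[str, CoverageTrack] = {}
    for sample in ATAC_SAMPLES:
        condition = sample.split("_")[1]
        depth = {c: np.zeros(genome.length(c)) for c in genome.chroms}
        for sid, chrom, centre, reduced in atac_sites:
            amp = atac_base[sid]
            if condition == "kdB" and reduced:
                amp *= plan.atac_reduction
            if plan.noise_sigma_ln > 0:
                amp *= float(rng.lognormal(0.0, plan.noise_sigma_ln))
            _triangle_profile(depth[chrom], centre, plan.peak_width_bp, amp * config.read_length)
        atac_cov[sample] = _rle_to_track(depth)
    half = plan.peak_width_bp // 2
    truth.atac_regions = [
        (sid, chrom, max(centre - half, 0), centre + half) for sid, chrom, centre, _ in atac_sites
    ]
    return chip_peaks, chip_cov, atac_cov, truth


# ---------------------------------------------------------------------------
# DE tables


def simulate_de_tables(
    config: SimConfig,
    rng: np.random.Generator,
    linked_down: list[str] | None = None,
    linked_up: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Two DE tables with planted quadrant structure and correlated shared effects.

    Shared genes draw a common effect plus independent per-table noise scaled
    so the A/B log2FC correlation hits the configured target; signs are
    enforced by reflection so quadrant recovery is exact.  ``linked_down`` /
    ``linked_up`` gene ids (genes adjacent to co-dependent binding loci) are
    used for the first co_down / co_up genes so the ChIP-RNA intersection is
    recoverable; remaining genes get synthetic ids.  Null genes receive
    adjusted p uniform on [0.1, 1) so planted counts are recovered exactly at
    the default alpha.
    """
    plan = config.de
    linked_down = list(linked_down or [])
    linked_up = list(linked_up or [])
    if len(linked_down) > plan.n_co_down or len(linked_up) > plan.n_co_up:
        raise ValueError("linked gene lists exceed planted class sizes")
    truth = SimTruth()
    rows_a, rows_b = [], []
    gid_counter = [0]

    def next_id(prefix: str) -> str:
        gid_counter[0] += 1
        return f"{prefix}_{gid_counter[0]:05d}"

    def planted_p() -> float:
        return float(10 ** rng.uniform(-6, np.log10(0.04)))

    # shared genes: common effect magnitude e_i with per-class signs; the
    # per-table noise sd is scaled against the variance of the full signed
    # effect mixture (sign-class separation included) so the realised A/B
    # correlation matches the configured target
    shared_specs: list[tuple[str, float, float, str]] = []
    for i in range(plan.n_co_up):
        gid = linked_up[i] if i < len(linked_up) else next_id("de_up")
        shared_specs.append((gid, +1.0, +1.0, "co_up"))
    for i in range(plan.n_co_down):
        gid = linked_down[i] if i < len(linked_down) else next_id("de_down")
        shared_specs.append((gid, -1.0, -1.0, "co_down"))
    for _ in range(plan.n_discordant):
        shared_specs.append((next_id("de_disc"), -1.0, +1.0, "discordant"))
    sigma_shared = 0.4  # spread of the common effect magnitude across genes
    e = plan.effect_size + sigma_shared * rng.standard_normal(len(shared_specs))
    signs_a = np.array([s[1] for s in shared_specs])
    rho = plan.correlation
    var_signed = float(np.var(signs_a * e)) if len(shared_specs) > 1 else sigma_shared**2
    sigma_eps = np.sqrt(var_signed * (1.0 - rho) / rho)
    for (gid, sa, sb, cls), ei in zip(shared_specs, e):
        fa = sa * abs(ei + sigma_eps * float(rng.standard_normal()))
        fb = sb * abs(ei + sigma_eps * float(rng.standard_normal()))
        rows_a.append((gid, fa, planted_p()))
        rows_b.append((gid, fb, planted_p()))
        truth.de_classes[gid] = cls

    def add_specific(table_rows: list, other_rows: list, sign: float, cls: str) -> None:
        gid = next_id("de_spec")
        fc = sign * abs(plan.effect_size + 0.5 * float(rng.standard_normal()))
        table_rows.append((gid, fc, planted_p()))
        other_rows.append((gid, 0.1 * float(rng.standard_normal()), float(rng.uniform(0.1, 1.0))))
        truth.de_classes[gid] = cls

    for _ in range(plan.n_a_only_up):
        add_specific(rows_a, rows_b, +1.0, "a_only")
    for _ in range(plan.n_a_only_down):
        add_specific(rows_a, rows_b, -1.0, "a_only")
    for _ in range(plan.n_b_only_up):
        add_specific(rows_b, rows_a, +1.0, "b_only")
    for _ in range(plan.n_b_only_down):
        add_specific(rows_b, rows_a, -1.0, "b_only")
    for _ in range(plan.n_null):
        gid = next_id("de_null")
        for rows in (rows_a, rows_b):
            rows.append((gid, 0.1 * float(rng.standard_normal()), float(rng.uniform(0.1, 1.0))))
        truth.de_classes[gid] = "null"

    de_a = pd.DataFrame(rows_a, columns=["gene_id", "log2fc", "p_adj"])
    de_b = pd.DataFrame(rows_b, columns=["gene_id", "log2fc", "p_adj"])
    return de_a, de_b, truth


# ---------------------------------------------------------------------------
# Interactome runs


def simulate_interactome_runs(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[RimeRun], list[RimeRun], SimTruth]:
    """Bait/IgG hit tables for two run groups with one planted candidate.

    The candidate appears in every group-A bait run (>= 1 unique peptide) and
    never in group-B runs nor any IgG list.  Background group-A interactors
    are each omitted from at least one run, so the candidate is the unique
    all-A intersection; contaminants appear in bait and IgG lists of both
    groups (removed by subtraction).
    """
    plan = config.interactome
    a_bg = [f"ABKG{i:04d}" for i in range(plan.n_a_background)]
    shared = [f"SHRD{i:04d}" for i in range(plan.n_shared_ab)]
    b_only = [f"BONL{i:04d}" for i in range(plan.n_b_only)]
    contaminants = [f"CONT{i:04d}" for i in range(plan.n_contaminants)]

    def hit(acc: str, gene: str = "") -> ProteinHit:
        return ProteinHit(
            accession=acc,
            gene=gene or acc.lower(),
            mascot_score=float(np.round(rng.uniform(50, 1500), 1)),
            unique_peptides=int(rng.integers(1, 30)),
            coverage_pct=float(np.round(rng.uniform(1, 60), 1)),
        )

    omit_run = {acc: int(rng.integers(0, plan.n_runs_a)) for acc in a_bg}
    runs_a = []
    for r in range(plan.n_runs_a):
        bait = [hit(plan.candidate_accession, plan.candidate_gene)]
        bait += [hit(acc) for acc in a_bg if omit_run[acc] != r and rng.random() < 0.8]
        bait += [hit(acc) for acc in shared if rng.random() < 0.7]
        bait += [hit(acc) for acc in contaminants]
        igg = [hit(acc) for acc in contaminants]
        runs_a.append(RimeRun(f"tnbc_{r + 1}", "TNBC", bait, igg))
    runs_b = []
    for r in range(plan.n_runs_b):
        bait = [hit(acc) for acc in shared]  # all shared present so A-union overlap is stable
        bait += [hit(acc) for acc in b_only if rng.random() < 0.8]
        bait += [hit(acc) for acc in contaminants]
        igg = [hit(acc) for acc in contaminants]
        runs_b.append(RimeRun(f"bcell_{r + 1}", "BCELL", bait, igg))
    truth = SimTruth(candidate_accession=plan.candidate_accession)
    return runs_a, runs_b, truth


# ---------------------------------------------------------------------------
# SPR sensorgrams


def _binding_curve(
    t: np.ndarray, conc_nM: float, plan: SprPlan
) -> np.ndarray:
    """Closed-form 1:1 binding response for a single association/dissociation cycle."""
    C = conc_nM * 1e-9
    kobs = plan.ka_per_M_s * C + plan.kd_per_s
    req = plan.rmax_RU * C / (C + plan.true_kd_nM * 1e-9)
    r = np.zeros_like(t)
    assoc = (t >= 0) & (t < plan.association_s)
    r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
    r_end = req * (1.0 - np.exp(-kobs * plan.association_s))
    dissoc = t >= plan.association_s
    r[dissoc] = r_end * np.exp(-plan.kd_per_s * (t[dissoc] - plan.association_s))
    return r


def simulate_sensorgrams(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[tuple[Sensorgram, Sensorgram]], SimTruth]:
    """Multi-cycle kinetics: (active, reference) sensorgram pairs per cycle.

    Cycle 0 is the zero-concentration blank.  The active cell carries the
    binding signal plus a bulk refractive-index jump during injection; both
    cells share a linear drift.  Double referencing removes both artefacts.
    """
    plan = config.spr
    if plan.ka_per_M_s <= 0 or plan.kd_per_s <= 0 or plan.rmax_RU <= 0:
        raise ValueError("ka, kd and Rmax must all be > 0")
    concs = [0.0] + sorted(serial_dilution(plan.top_nM, plan.dilution_factor, plan.n_points))
    t = np.arange(-30.0, plan.association_s + plan.dissociation_s + plan.dt_s, plan.dt_s)
    pairs = []
    for i, conc in enumerate(concs):
        signal = _binding_curve(t, conc, plan)
        drift = plan.drift_RU_per_s * (t - t[0])
        bulk = np.where((t >= 0) & (t < plan.association_s), plan.bulk_jump_RU, 0.0)
        noise_a = rng.normal(0.0, plan.noise_sd_RU, len(t)) if plan.noise_sd_RU > 0 else 0.0
        noise_r = rng.normal(0.0, plan.noise_sd_RU, len(t)) if plan.noise_sd_RU > 0 else 0.0
        active = Sensorgram(
            cycle_id=f"cycle_{i:02d}",
            concentration_nM=conc,
            time_s=t,
            response_RU=signal + drift + bulk + noise_a,
            association_start_s=0.0,
            association_end_s=plan.association_s,
            dissociation_end_s=plan.association_s + plan.dissociation_s,
            flow_cell="active",
        )
        reference = Sensorgram(
            cycle_id=f"cycle_{i:02d}",
            concentration_nM=conc,
            time_s=t,
            response_RU=drift + noise_r,
            association_start_s=0.0,
            association_end_s=plan.association_s,
            dissociation_end_s=plan.association_s + plan.dissociation_s,
            flow_cell="reference",
        )
        pairs.append((active, reference))
    truth = SimTruth(true_kd_nM=plan.true_kd_nM)
    return pairs, truth


def simulate_req_values(
    kd_nM: float,
    rmax_RU: float,
    concentrations_nM: np.ndarray,
    noise_sd_RU: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Equilibrium responses from the 1:1 isotherm with additive Gaussian noise."""
    conc = np.asarray(concentrations_nM, dtype=float)
    req = rmax_RU * conc / (kd_nM + conc)
    if noise_sd_RU > 0:
        req = req + rng.normal(0.0, noise_sd_RU, len(conc))
    return req


def write_sensorgram_csv(pairs: list[tuple[Sensorgram, Sensorgram]], path: str | Path) -> None:
    rows = []
    for active, reference in pairs:
        for sg in (active, reference):
            for tt, rr in zip(sg.time_s, sg.response_RU):
                rows.append((sg.cycle_id, sg.flow_cell, sg.concentration_nM, tt, rr))
    pd.DataFrame(
        rows, columns=["cycle_id", "flow_cell", "concentration_nM", "time_s", "response_RU"]
    ).to_csv(path, index=False)


def read_sensorgram_csv(
    path: str | Path, association_s: float = 600.0, dissociation_s: float = 300.0
) -> list[tuple[Sensorgram, Sensorgram]]:
    df = pd.read_csv(path)
    pairs = []
    for cycle_id, grp in df.groupby("cycle_id", sort=True):
        cells = {}
        for cell, sub in grp.groupby("flow_cell"):
            sub = sub.sort_values("time_s")
            cells[cell] = Sensorgram(
                cycle_id=str(cycle_id),
                concentration_nM=float(sub["concentration_nM"].iloc[0]),
                time_s=sub["time_s"].to_numpy(),
                response_RU=sub["response_RU"].to_numpy(),
                association_start_s=0.0,
                association_end_s=association_s,
                dissociation_end_s=association_s + dissociation_s,
                flow_cell=str(cell),
            )
        pairs.append((cells["active"], cells["reference"]))
    return pairs


# ---------------------------------------------------------------------------
# Orchestration


def simulate_all(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Generate every pipeline input under ``outdir`` and write the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome, genes, tracks = simulate_genome(config, rng)
    chip_peaks, chip_cov, atac_cov, truth = simulate_peak_experiment(config, genome, genes, rng)
    write_fasta(genome, outdir / "genome.fa")
    write_gene_tsv(genes, outdir / "genes.tsv")
    for track in tracks:
        write_bed(track.intervals, outdir / f"track_{track.label}.bed")
    for sample, ivs in chip_peaks.items():
        write_bed(ivs, outdir / f"{sample}.bed")
    for sample, cov in chip_cov.items():
        write_bedgraph(cov, outdir / f"{sample}.bedgraph")
    for sample, cov in atac_cov.items():
        write_bedgraph(cov, outdir / f"{sample}.bedgraph")
    write_bed(
        [GenomicInterval(chrom, s, e, ".", sid) for sid, chrom, s, e in truth.atac_regions],
        outdir / "atac_sites.bed",
    )

    de_a, de_b, de_truth = simulate_de_tables(
        config, rng, truth.linked_genes_down, truth.linked_genes_up
    )
    de_a.to_csv(outdir / "de_knockdownA.tsv", sep="\t", index=False)
    de_b.to_csv(outdir / "de_knockdownB.tsv", sep="\t", index=False)

    runs_a, runs_b, int_truth = simulate_interactome_runs(config, rng)
    manifest_rows = []
    for run in runs_a + runs_b:
        bait_path = outdir / f"hits_{run.run_id}_bait.tsv"
        igg_path = outdir / f"hits_{run.run_id}_igg.tsv"
        for hits, path in ((run.bait_hits, bait_path), (run.igg_hits, igg_path)):
            pd.DataFrame(
                [
                    (h.accession, h.gene, h.mascot_score, h.unique_peptides, h.coverage_pct)
                    for h in hits
                ],
                columns=["accession", "gene", "mascot_score", "unique_peptides", "coverage_pct"],
            ).to_csv(path, sep="\t", index=False)
        manifest_rows.append((run.run_id, run.group, bait_path.name, igg_path.name))
    pd.DataFrame(
        manifest_rows, columns=["run_id", "group", "bait_path", "igg_path"]
    ).to_csv(outdir / "run_manifest.tsv", sep="\t", index=False)

    pairs, spr_truth = simulate_sensorgrams(config, rng)
    write_sensorgram_csv(pairs, outdir / "sensorgrams.csv")

    truth.de_classes = de_truth.de_classes
    truth.candidate_accession = int_truth.candidate_accession
    truth.true_kd_nM = spr_truth.true_kd_nM
    truth.to_json(outdir / "sim_truth.json")
    return truth
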