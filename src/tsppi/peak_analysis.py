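"""Consensus-peak construction, amplitude quantification and co-dependency calling.

The ChIP arm follows a threshold pipeline: per-sample narrow peaks are
merged into consensus loci by the midpoint-in-span rule, amplitudes are
computed from coverage and scaled on read length, a signal/noise floor is
applied, samples are aligned on the mode of their log2 amplitude
distribution against the matching control IP, and "disappearing" peaks
(log2(control/kd) >= 0.5) under each knockdown are combined into a
co-dependency classification (A-specific / B-specific / shared / unchanged).
The ATAC arm quantifies the same way but normalises by quantile
normalisation and reports per-region accessibility log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    CoverageTrack,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    midpoint,
    overlap_fraction,
    promoter_of,
)


@dataclass
class ConsensusPeak:
    peak_id: str
    interval: GenomicInterval
    members: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.members)


@dataclass
class PeakMatrix:
    """Consensus peaks x samples amplitude matrix with a provenance log."""

    peaks: list[ConsensusPeak]
    values: pd.DataFrame  # index: peak_id, columns: sample_id
    read_length: int
    provenance: list[str] = field(default_factory=list)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(list(self.peaks), self.values.copy(), self.read_length, list(self.provenance))

    def peak_by_id(self, peak_id: str) -> ConsensusPeak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)


@dataclass
class CodependencyResult:
    classes: dict[str, str]  # peak_id -> {A_specific, B_specific, shared, unchanged}
    disappearing: dict[tuple[str, str], set[str]]  # (ip, kd) -> peak ids
    log2fc: pd.DataFrame  # peak_id x (ip, kd) log2FC

    def class_counts(self) -> dict[str, int]:
        out = {"A_specific": 0, "B_specific": 0, "shared": 0, "unchanged": 0}
        for c in self.classes.values():
            out[c] += 1
        return out


# ---------------------------------------------------------------------------
# Consensus construction


def _peaks_match(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Midpoint-in-span match: either midpoint lies within the other's span."""
    if a.chrom != b.chrom:
        return False
    return (a.start <= midpoint(b) < a.end) or (b.start <= midpoint(a) < b.end)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_consensus(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    known_chroms: Iterable[str] | None = None,
) -> list[ConsensusPeak]:
    """Merge per-sample peaks into consensus loci.

    Two peaks match when the midpoint of one falls within the span of the
    other; connected components of the match graph become one consensus
    peak spanning min(start)..max(end).  Matching pairs necessarily
    overlap, so a single coordinate sweep finds all candidate edges.
    """
    if not peak_sets:
        raise ValueError("need at least one sample")
    flat: list[tuple[str, GenomicInterval]] = []
    for sample_id in peak_sets:
        for iv in peak_sets[sample_id]:
            if known_chroms is not None and iv.chrom not in set(known_chroms):
                raise ValueError(f"peak on unknown chromosome {iv.chrom!r}")
            flat.append((sample_id, iv))
    if not flat:
        return []
    order = sorted(range(len(flat)), key=lambda i: (flat[i][1].chrom, flat[i][1].start, flat[i][1].end))
    uf = _UnionFind(len(flat))
    active: list[int] = []  # indices (into flat) of intervals that may still overlap
    prev_chrom = None
    for i in order:
        iv = flat[i][1]
        if iv.chrom != prev_chrom:
            active = []
            prev_chrom = iv.chrom
        active = [j for j in active if flat[j][1].end > iv.start]
        for j in active:
            if _peaks_match(iv, flat[j][1]):
                uf.union(i, j)
        active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(uf.find(i), []).append(i)
    peaks = []
    for idxs in groups.values():
        ivs = [flat[i][1] for i in idxs]
        chrom = ivs[0].chrom
        span = GenomicInterval(chrom, min(v.start for v in ivs), max(v.end for v in ivs))
        members: dict[str, list[GenomicInterval]] = {}
        for i in idxs:
            members.setdefault(flat[i][0], []).append(flat[i][1])
        peaks.append(ConsensusPeak("", span, members))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    for k, p in enumerate(peaks):
        p.peak_id = f"peak_{k:05d}"
    return peaks


def build_consensus_bruteforce(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[ConsensusPeak]:
    """O(n^2) pairwise-match + connected-components reference (tests only)."""
    flat = [(s, iv) for s in peak_sets for iv in peak_sets[s]]
    n = len(flat)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _peaks_match(flat[i][1], flat[j][1]):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    peaks = []
    for idxs in groups.values():
        ivs = [flat[i][1] for i in idxs]
        span = GenomicInterval(ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs))
        members: dict[str, list[GenomicInterval]] = {}
        for i in idxs:
            members.setdefault(flat[i][0], []).append(flat[i][1])
        peaks.append(ConsensusPeak("", span, members))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    for k, p in enumerate(peaks):
        p.peak_id = f"peak_{k:05d}"
    return peaks


# ---------------------------------------------------------------------------
# Quantification and scaling


def quantify(
    catalog: Sequence[ConsensusPeak],
    coverage: Mapping[str, CoverageTrack],
    read_length: int,
) -> PeakMatrix:
    """Amplitude = summed per-base depth over the consensus span / read length.

    Dividing by read length converts the pileup integral into an estimated
    fragment count, making samples with different read lengths comparable.
    """
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    data = {}
    for sample_id, track in coverage.items():
        col = np.empty(len(catalog))
        for k, peak in enumerate(catalog):
            iv = peak.interval
            col[k] = track.sum_over(iv.chrom, iv.start, iv.end) / read_length
        data[sample_id] = col
    values = pd.DataFrame(data, index=[p.peak_id for p in catalog])
    return PeakMatrix(list(catalog), values, read_length, ["quantified (raw)"])


def apply_noise_threshold(matrix: PeakMatrix, threshold: float = 20.0) -> PeakMatrix:
    """Floor amplitudes below the signal/noise threshold; drop all-floored rows."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = matrix.copy()
    below = out.values < threshold
    all_floored = below.all(axis=1)
    out.values = out.values.clip(lower=threshold)
    keep = ~all_floored
    out.values = out.values.loc[keep]
    kept_ids = set(out.values.index)
    out.peaks = [p for p in out.peaks if p.peak_id in kept_ids]
    out.provenance.append(
        f"noise floor {threshold} applied; {int(all_floored.sum())} all-floored rows dropped"
    )
    return out


def _log2_mode(values: np.ndarray, bin_width: float = 0.1) -> float:
    """Mode of log2(values) from a fixed-width histogram; ties -> lowest bin."""
    logs = np.log2(values[values > 0])
    if len(logs) == 0:
        raise ValueError("no positive values")
    lo = np.floor(logs.min() / bin_width) * bin_width
    idx = np.floor((logs - lo) / bin_width).astype(int)
    counts = np.bincount(idx)
    best = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    return lo + (best + 0.5) * bin_width


def scale_to_control_mode(
    matrix: PeakMatrix,
    control_of: Mapping[str, str],
    bin_width: float = 0.1,
) -> PeakMatrix:
    """Scale each sample so its log2-amplitude mode matches its control's.

    Each knockdown sample is multiplied by 2^(mode_control - mode_sample),
    aligning the bulk of the (mostly unchanged) peak distribution so that
    fold changes are comparable across samples.  Controls map to themselves.
    """
    out = matrix.copy()
    modes = {s: _log2_mode(out.values[s].to_numpy(), bin_width) for s in out.values.columns}
    factors = {}
    for sample in out.values.columns:
        control = control_of.get(sample, sample)
        if control not in modes:
            raise ValueError(f"sample {sample!r} maps to unknown control {control!r}")
        factors[sample] = 2.0 ** (modes[control] - modes[sample])
        out.values[sample] = out.values[sample] * factors[sample]
    out.provenance.append(
        "mode-scaled to controls: " + ", ".join(f"{s}x{f:.4g}" for s, f in factors.items())
    )
    return out


def quantile_normalise(matrix: PeakMatrix) -> PeakMatrix:
    """Classic quantile normalisation: replace each value by the across-sample
    mean of its order statistic; ties receive the mean over their rank span."""
    if matrix.values.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    normed = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        normed[:, j] = (ref[lo] + ref[hi]) / 2.0
    out.values = pd.DataFrame(normed, index=out.values.index, columns=out.values.columns)
    out.provenance.append("quantile normalised")
    return out


# ---------------------------------------------------------------------------
# Disappearing peaks and co-dependency


def call_disappearing(
    matrix: PeakMatrix,
    control_col: str,
    kd_col: str,
    log2fc_threshold: float = 0.5,
) -> tuple[set[str], pd.Series]:
    """Peaks whose amplitude drops in knockdown: log2(control/kd) >= threshold."""
    log2fc = np.log2(matrix.values[control_col] / matrix.values[kd_col])
    disappearing = set(log2fc.index[log2fc >= log2fc_threshold])
    return disappearing, log2fc


def classify_codependency(
    disappearing: Mapping[tuple[str, str], set[str]],
    catalog_ids: Iterable[str],
    shared_policy: str = "both",
) -> CodependencyResult:
    """Partition the catalog by which knockdown reduces binding.

    ``disappearing`` maps (ip, kd) with ip in {A, B} and kd in {A, B} to the
    disappearing peak-id sets.  A peak is "reduced under knockdown X" when
    it disappears in at least one IP under X-KD.  Reduced under A only ->
    A_specific; B only -> B_specific; both -> shared (policy "both") —
    policy "either" additionally requires reduction in both IPs pooled over
    knockdowns; neither -> unchanged.
    """
    if shared_policy not in ("both", "either"):
        raise ValueError("shared_policy must be 'both' or 'either'")
    expected = {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}
    if set(disappearing) != expected:
        raise ValueError(f"need disappearing sets for all four (ip, kd) pairs, got {set(disappearing)}")
    reduced_under_a = disappearing[("A", "A")] | disappearing[("B", "A")]
    reduced_under_b = disappearing[("A", "B")] | disappearing[("B", "B")]
    classes = {}
    for pid in catalog_ids:
        in_a, in_b = pid in reduced_under_a, pid in reduced_under_b
        if in_a and in_b:
            classes[pid] = "shared"
        elif in_a:
            classes[pid] = "A_specific"
        elif in_b:
            classes[pid] = "B_specific"
        else:
            classes[pid] = "unchanged"
    if shared_policy == "either":
        # reduced under at least one knockdown, in both IPs pooled
        reduced_ip_a = disappearing[("A", "A")] | disappearing[("A", "B")]
        reduced_ip_b = disappearing[("B", "A")] | disappearing[("B", "B")]
        for pid in classes:
            if classes[pid] != "unchanged" and pid in reduced_ip_a and pid in reduced_ip_b:
                classes[pid] = "shared"
    return CodependencyResult(classes, dict(disappearing), pd.DataFrame())


def run_codependency(
    matrix: PeakMatrix,
    sample_plan: Mapping[tuple[str, str], str],
    log2fc_threshold: float = 0.5,
    shared_policy: str = "both",
) -> CodependencyResult:
    """Full co-dependency calling from a scaled matrix.

    ``sample_plan`` maps (ip, condition) to sample column names; conditions
    are 'control', 'A', 'B' (the two knockdowns).
    """
    disappearing = {}
    fc_cols = {}
    for ip in ("A", "B"):
        control = sample_plan[(ip, "control")]
        for kd in ("A", "B"):
            ids, fc = call_disappearing(matrix, control, sample_plan[(ip, kd)], log2fc_threshold)
            disappearing[(ip, kd)] = ids
            fc_cols[f"ip{ip}_kd{kd}"] = fc
    result = classify_codependency(disappearing, matrix.values.index, shared_policy)
    result.log2fc = pd.DataFrame(fc_cols)
    return result


# ---------------------------------------------------------------------------
# Annotation, gene pairing, profiles, accessibility


def _covered_fraction(peak: GenomicInterval, intervals: Sequence[GenomicInterval]) -> float:
    """Fraction of peak covered by the union of a track's intervals."""
    segs = []
    for iv in intervals:
        if iv.chrom != peak.chrom:
            continue
        s, e = max(iv.start, peak.start), min(iv.end, peak.end)
        if s < e:
            segs.append((s, e))
    if not segs:
        return 0.0
    segs.sort()
    covered = 0
    cur_s, cur_e = segs[0]
    for s, e in segs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / len(peak)


def annotate(
    catalog: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    feature_tracks: Sequence[FeatureTrack],
    min_overlap: float = 0.5,
    promoter_width: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assign feature labels to peaks where >= min_overlap of the peak is covered.

    Gene-derived tracks (exon, intron, promoter) are built here from the
    gene models; other tracks (enhancer, CpG island, TFBS, CTCF, UTRs) come
    from ``feature_tracks``.
    """
    tracks: dict[str, list[GenomicInterval]] = {t.label: list(t.intervals) for t in feature_tracks}
    tracks.setdefault("exon", [])
    tracks.setdefault("intron", [])
    tracks.setdefault("promoter", [])
    for g in genes:
        tracks["exon"].extend(g.exons)
        tracks["intron"].extend(g.introns())
        clen = chrom_lengths.get(g.interval.chrom) if chrom_lengths else None
        prom = promoter_of(g, promoter_width, clen)
        if prom is not None:
            tracks["promoter"].append(prom)
    rows = []
    for peak in catalog:
        labels = sorted(
            label
            for label, ivs in tracks.items()
            if ivs and _covered_fraction(peak.interval, ivs) >= min_overlap
        )
        rows.append({"peak_id": peak.peak_id, "labels": ",".join(labels)})
    return pd.DataFrame(rows)


def pair_with_genes(
    catalog: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Pair peaks with genes whose span intersects the peak extended by flank_bp.

    Distance is 0 for overlapping pairs, otherwise the gap in bp.  The flank
    default (5000) matches methods-mode pairing; results-mode vicinity uses
    1000.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    rows = []
    for peak in catalog:
        iv = peak.interval
        lo, hi = max(iv.start - flank_bp, 0), iv.end + flank_bp
        for g in genes:
            gi = g.interval
            if gi.chrom != iv.chrom or gi.end <= lo or gi.start >= hi:
                continue
            if gi.end <= iv.start:
                dist = iv.start - gi.end
            elif gi.start >= iv.end:
                dist = gi.start - iv.end
            else:
                dist = 0
            rows.append({"peak_id": peak.peak_id, "gene_id": g.gene_id, "distance_bp": dist})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance_bp"])


def tss_profile_matrix(
    coverage: Mapping[str, CoverageTrack],
    anchors: Sequence[tuple[str, int]],
    halfwidth: int = 2000,
    n_bins: int = 100,
    control_of: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Anchor-centred binned coverage profiles, scaled so controls match.

    Each sample yields an anchors x n_bins matrix of mean depth over
    [anchor-halfwidth, anchor+halfwidth).  When ``control_of`` is given,
    per-control scale factors equalise the control matrices' total sums and
    the same factor is applied to each control's knockdown samples.
    """
    if (2 * halfwidth) % n_bins != 0:
        raise ValueError("2*halfwidth must be divisible by n_bins")
    mats = {}
    for sample, track in coverage.items():
        mat = np.zeros((len(anchors), n_bins))
        for i, (chrom, pos) in enumerate(anchors):
            mat[i] = track.binned_means(chrom, pos - halfwidth, pos + halfwidth, n_bins)
        mats[sample] = mat
    if control_of:
        controls = sorted(set(control_of.values()))
        sums = {c: mats[c].sum() for c in controls}
        target = min(s for s in sums.values() if s > 0) if any(s > 0 for s in sums.values()) else 1.0
        factors = {c: (target / s if s > 0 else 1.0) for c, s in sums.items()}
        for sample in mats:
            mats[sample] = mats[sample] * factors[control_of.get(sample, sample)]
    return mats


def accessibility_change(
    atac_matrix: PeakMatrix,
    control_col: str,
    kd_col: str,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region accessibility log2FC = log2(control/kd) on a normalised matrix."""
    fc = np.log2(atac_matrix.values[control_col] / atac_matrix.values[kd_col])
    out = pd.DataFrame({"peak_id": fc.index, "log2fc": fc.to_numpy()})
    if annotation is not None:
        out = out.merge(annotation, on="peak_id", how="left")
    return out
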