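"""Short-motif (k-mer) enrichment in peak sequences by Fisher's exact test.

Counting is per-sequence presence/absence of each canonical (strand
collapsed) k-mer; enrichment of a foreground peak set against a background
set is a one-sided Fisher exact test on the 2x2 presence table.  Two
backgrounds mirror the analysis design: all consensus peaks, and gene
upstream (promoter) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genomic_core import Genome, GenomicInterval

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerPresence:
    k: int
    n_sequences: int
    counts: dict[str, int] = field(default_factory=dict)  # kmer -> n sequences containing it
    canonical: bool = True


@dataclass
class MotifResult:
    kmer: str
    fg_with: int
    fg_without: int
    bg_with: int
    bg_without: int
    odds_ratio: float
    p_value: float
    p_adj: float
    significant: bool
    background_label: str = ""


def extract_sequences(
    intervals: Sequence[GenomicInterval], genome: Genome
) -> list[str]:
    """Uppercase sequence per interval; '-' strand reverse-complemented."""
    return [genome.fetch(iv) for iv in intervals]


def count_kmer_presence(
    sequences: Sequence[str], k: int = 6, canonical: bool = True
) -> KmerPresence:
    """Number of sequences containing each k-mer at least once.

    Presence (not occurrence count) avoids confounding by sequence length.
    k-mers containing N are skipped; with canonical=True a k-mer and its
    reverse complement pool under one key.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequences:
        raise ValueError("need at least one sequence")
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                kmer = canonical_kmer(kmer)
            seen.add(kmer)
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerPresence(k=k, n_sequences=len(sequences), counts=counts, canonical=canonical)


def fisher_enrichment(
    fg: KmerPresence,
    bg: KmerPresence,
    alpha: float = 0.05,
    alternative: str = "greater",
    background_label: str = "",
) -> list[MotifResult]:
    """One-sided Fisher exact enrichment per k-mer, fg vs bg presence counts.

    Odds ratios use a 0.5 Haldane correction when any cell is zero; raw
    p < alpha flags significance (a BH-adjusted column is reported
    alongside).  Results sort by ascending p, then k-mer.
    """
    if fg.k != bg.k or fg.canonical != bg.canonical:
        raise ValueError("foreground and background must share k and canonical setting")
    kmers = sorted(set(fg.counts) | set(bg.counts))
    results = []
    pvals = []
    for kmer in kmers:
        fw = fg.counts.get(kmer, 0)
        bw = bg.counts.get(kmer, 0)
        fo, bo = fg.n_sequences - fw, bg.n_sequences - bw
        table = [[fw, fo], [bw, bo]]
        p = float(fisher_exact(table, alternative=alternative).pvalue)
        if min(fw, fo, bw, bo) == 0:
            orr = ((fw + 0.5) * (bo + 0.5)) / ((fo + 0.5) * (bw + 0.5))
        else:
            orr = (fw * bo) / (fo * bw)
        pvals.append(p)
        results.append(
            MotifResult(kmer, fw, fo, bw, bo, orr, p, 1.0, p < alpha, background_label)
        )
    if results:
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, p_adj):
            r.p_adj = float(q)
    results.sort(key=lambda r: (r.p_value, r.kmer))
    return results


def dual_background_report(
    fg: KmerPresence,
    bg_all_peaks: KmerPresence,
    bg_upstream: KmerPresence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment against both backgrounds; a k-mer is robust when significant in both."""
    res_all = fisher_enrichment(fg, bg_all_peaks, alpha, background_label="all_peaks")
    res_up = fisher_enrichment(fg, bg_upstream, alpha, background_label="upstream_regions")
    sig_all = {r.kmer for r in res_all if r.significant}
    sig_up = {r.kmer for r in res_up if r.significant}
    robust = sig_all & sig_up
    rows = [
        {
            "kmer": r.kmer,
            "background": r.background_label,
            "fg_with": r.fg_with,
            "fg_without": r.fg_without,
            "bg_with": r.bg_with,
            "bg_without": r.bg_without,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "p_adj": r.p_adj,
            "significant": r.significant,
            "robust": r.kmer in robust,
        }
        for r in res_all + res_up
    ]
    return pd.DataFrame(rows)


def write_meme_minimal(results: Sequence[MotifResult], path: str, alpha: float = 0.05) -> None:
    """Export significant k-mers as single-letter PWMs in MEME minimal format."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for r in results:
            if not r.significant:
                continue
            fh.write(f"MOTIF {r.kmer}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(r.kmer)} nsites= {r.fg_with}\n")
            for base in r.kmer:
                row = [0.0, 0.0, 0.0, 0.0]
                row[base_idx[base]] = 1.0
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
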