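"""Differential bait-IP mass-spectrometry interactome comparison.

Each RIME-style run pairs a bait IP hit list with a matched IgG isotype
control list.  Per run, IgG hits are subtracted (non-specific background)
and hits below the unique-peptide floor are dropped; groups are then
compared by set algebra.  The candidate set — proteins found in every
group-A run but in no group-B run — is the tumour-specific interactor
nomination rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

GROUPS = ("TNBC", "BCELL", "BRAIN", "other")


@dataclass(frozen=True)
class ProteinHit:
    accession: str
    gene: str = ""
    mascot_score: float = 0.0
    unique_peptides: int = 0
    coverage_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.mascot_score < 0 or self.unique_peptides < 0:
            raise ValueError("scores and peptide counts must be >= 0")


@dataclass
class RimeRun:
    run_id: str
    group: str
    bait_hits: list[ProteinHit]
    igg_hits: list[ProteinHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class InteractomeComparison:
    a_union: set[str]
    b_union: set[str]
    shared: set[str]
    a_only: set[str]
    candidates: set[str]
    cumulative_scores: dict[str, float]
    gene_map: dict[str, str]


def read_hit_table(path: str | Path) -> list[ProteinHit]:
    """Read a TSV hit table (accession, gene, mascot_score, unique_peptides[, coverage_pct])."""
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            ProteinHit(
                accession=str(row.accession),
                gene=str(getattr(row, "gene", "")),
                mascot_score=float(getattr(row, "mascot_score", 0.0)),
                unique_peptides=int(getattr(row, "unique_peptides", 0)),
                coverage_pct=float(getattr(row, "coverage_pct", 0.0)),
            )
        )
    return hits


def filter_run(run: RimeRun, min_unique_peptides: int = 1) -> set[str]:
    """Run-specific accessions: bait hits minus IgG hits, >= peptide floor."""
    igg = {h.accession for h in run.igg_hits}
    return {
        h.accession
        for h in run.bait_hits
        if h.accession not in igg and h.unique_peptides >= min_unique_peptides
    }


def cumulative_scores(
    runs: Sequence[RimeRun], min_unique_peptides: int = 1
) -> dict[str, float]:
    """Summed Mascot score per accession over filtered runs (word-cloud weights)."""
    totals: dict[str, float] = {}
    for run in runs:
        keep = filter_run(run, min_unique_peptides)
        for h in run.bait_hits:
            if h.accession in keep:
                totals[h.accession] = totals.get(h.accession, 0.0) + h.mascot_score
    return totals


def compare_groups(
    runs_a: Sequence[RimeRun],
    runs_b: Sequence[RimeRun],
    min_unique_peptides: int = 1,
) -> InteractomeComparison:
    """Set algebra between two run groups after per-run IgG subtraction.

    a_only = A_union \\ B_union; candidates = (intersection of all filtered
    A runs) \\ B_union, i.e. proteins seen in every A sample and no B sample.
    """
    if not runs_a or not runs_b:
        raise ValueError("each group needs at least one run")
    filtered_a = [filter_run(r, min_unique_peptides) for r in runs_a]
    filtered_b = [filter_run(r, min_unique_peptides) for r in runs_b]
    a_union = set().union(*filtered_a)
    b_union = set().union(*filtered_b)
    shared = a_union & b_union
    a_only = a_union - shared
    candidates = set.intersection(*filtered_a) - b_union
    gene_map = {
        h.accession: h.gene
        for run in list(runs_a) + list(runs_b)
        for h in run.bait_hits
        if h.gene
    }
    return InteractomeComparison(
        a_union=a_union,
        b_union=b_union,
        shared=shared,
        a_only=a_only,
        candidates=candidates,
        cumulative_scores=cumulative_scores(runs_a, min_unique_peptides),
        gene_map=gene_map,
    )


def nominate_candidates(comparison: InteractomeComparison) -> pd.DataFrame:
    """Candidate table ranked by descending cumulative score, ties by accession."""
    rows = [
        {
            "accession": acc,
            "gene": comparison.gene_map.get(acc, ""),
            "cumulative_score": comparison.cumulative_scores.get(acc, 0.0),
        }
        for acc in comparison.candidates
    ]
    df = pd.DataFrame(rows, columns=["accession", "gene", "cumulative_score"])
    if len(df):
        df = df.sort_values(
            ["cumulative_score", "accession"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def summary_table(comparison: InteractomeComparison) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": ["A_union", "B_union", "shared", "A_only", "candidates"],
            "n": [
                len(comparison.a_union),
                len(comparison.b_union),
                len(comparison.shared),
                len(comparison.a_only),
                len(comparison.candidates),
            ],
        }
    )
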