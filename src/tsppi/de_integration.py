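"""Differential-expression overlap, trend regression, ChIP-RNA intersection, ΔΔCt.

Two knockdown DE tables (gene, log2FC vs control, adjusted p) are compared
gene-by-gene: genes significant in both split into quadrants by fold-change
sign (co_down: both decrease on knockdown; co_up: both increase;
discordant: opposite signs).  In regulation-by-protein vocabulary a co_up
gene is repressed by both proteins, a co_down gene activated by both.  The
shared set feeds an OLS trend fit and an intersection with genes paired to
shared (co-dependent) binding sites.  ΔΔCt converts qPCR Ct tables to fold
changes against a reference gene and control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QuadrantClassification:
    co_down: set[str]
    co_up: set[str]
    discordant: set[str]
    a_only: set[str]
    b_only: set[str]

    @property
    def shared(self) -> set[str]:
        return self.co_down | self.co_up | self.discordant

    def counts(self) -> dict[str, int]:
        return {
            "co_down": len(self.co_down),
            "co_up": len(self.co_up),
            "discordant": len(self.discordant),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "shared": len(self.shared),
        }


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def read_de_table(path: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    """Read a DE TSV (gene_id, log2fc, p_adj); adds a significance flag."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "p_adj"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    df["significant"] = df["p_adj"] < alpha
    return df


def classify_overlap(de_a: pd.DataFrame, de_b: pd.DataFrame) -> QuadrantClassification:
    """Quadrant classification of significant genes across two knockdowns."""
    for name, df in (("A", de_a), ("B", de_b)):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in table {name}")
    a = de_a.set_index("gene_id")
    b = de_b.set_index("gene_id")
    sig_a = set(a.index[a["significant"]])
    sig_b = set(b.index[b["significant"]])
    shared = sig_a & sig_b
    co_down, co_up, discordant = set(), set(), set()
    for g in shared:
        fa, fb = a.loc[g, "log2fc"], b.loc[g, "log2fc"]
        if fa < 0 and fb < 0:
            co_down.add(g)
        elif fa > 0 and fb > 0:
            co_up.add(g)
        else:
            discordant.add(g)
    return QuadrantClassification(co_down, co_up, discordant, sig_a - shared, sig_b - shared)


def fit_trend(log2fc_a: np.ndarray, log2fc_b: np.ndarray) -> TrendFit:
    """OLS of B-knockdown log2FC on A-knockdown log2FC over shared genes."""
    x = np.asarray(log2fc_a, dtype=float)
    y = np.asarray(log2fc_b, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("all x equal: slope undefined")
    res = stats.linregress(x, y)
    return TrendFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2, len(x))


def shared_fc_table(
    de_a: pd.DataFrame, de_b: pd.DataFrame, classification: QuadrantClassification
) -> pd.DataFrame:
    """Paired log2FC table for the shared gene set (trend-fit input)."""
    a = de_a.set_index("gene_id")["log2fc"]
    b = de_b.set_index("gene_id")["log2fc"]
    genes = sorted(classification.shared)
    return pd.DataFrame(
        {"gene_id": genes, "log2fc_a": a.loc[genes].to_numpy(), "log2fc_b": b.loc[genes].to_numpy()}
    )


def intersect_chip_rna(
    classification: QuadrantClassification, peak_gene_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Shared DE genes that are also paired to shared-class binding sites.

    ``peak_gene_pairs`` must already be restricted to shared (co-dependent)
    peaks.  Direction comes from the quadrant class; the summary is obtained
    with ``.groupby('direction')``.
    """
    if len(peak_gene_pairs) == 0:
        return pd.DataFrame(columns=["gene_id", "direction"])
    paired = set(peak_gene_pairs["gene_id"])
    direction = {}
    for g in classification.co_down:
        direction[g] = "down"
    for g in classification.co_up:
        direction[g] = "up"
    for g in classification.discordant:
        direction[g] = "discordant"
    genes = sorted(classification.shared & paired)
    return pd.DataFrame({"gene_id": genes, "direction": [direction[g] for g in genes]})


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Relative expression per sample by the ΔΔCt method.

    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = ΔCt − mean ΔCt over
    the control group; fold change = 2^(−ΔΔCt).  Table columns: sample,
    group, gene, ct (long format).  Samples missing either gene's Ct are
    excluded with a warning column in the result.
    """
    wide = ct_table.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    wide = wide.reset_index()
    complete = wide.dropna(subset=[target_gene, reference_gene]).copy()
    complete["delta_ct"] = complete[target_gene] - complete[reference_gene]
    control = complete[complete["group"] == control_group]
    if len(control) == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    control_mean = control["delta_ct"].mean()
    complete["delta_delta_ct"] = complete["delta_ct"] - control_mean
    complete["fold_change"] = 2.0 ** (-complete["delta_delta_ct"])
    return complete[["sample", "group", "delta_ct", "delta_delta_ct", "fold_change"]].reset_index(
        drop=True
    )
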