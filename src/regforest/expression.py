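"""Differential-expression tables, node prizes, and closed-form assay math.

The pipeline consumes finished differential-expression results (gene,
log2 fold change, Benjamini-Hochberg adjusted p) for two contrasts: an
*early* contrast (the onset of the response) and a *late* contrast (the
subsequent wave).  Genes significantly up-regulated early prize the
protein layer; genes up-regulated late prize the rna layer.  The DE model
itself is out of scope here - tables are inputs.

Also included are the small closed-form quantifications used alongside the
sequencing data: reads-per-million normalization, ddCt relative qPCR fold
change, and ChIP-qPCR percent-of-input recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interactome import PROTEIN, RNA, Interactome, NodeRef, _norm

logger = logging.getLogger(__name__)

DEFAULT_FDR_MAX = 0.01
DEFAULT_MIN_ABS_LOG2FC = 2.0


@dataclass
class DETable:
    """Per-gene differential-expression records for one contrast.

    One record per gene; ``padj`` may be missing (treated as
    non-significant, never imputed); ``log2fc`` must be finite.
    """

    data: pd.DataFrame  # columns: gene, log2fc, padj (padj may be NaN)
    contrast: str = ""

    def __post_init__(self):
        df = self.data
        required = {"gene", "log2fc", "padj"}
        if not required.issubset(df.columns):
            raise ValueError(f"DETable needs columns {sorted(required)}")
        df = df.copy()
        df["gene_key"] = df["gene"].map(_norm)
        if df["gene_key"].duplicated().any():
            dup = df.loc[df["gene_key"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene in DE table: {dup}")
        if not np.isfinite(df["log2fc"].to_numpy(float)).all():
            raise ValueError("non-finite log2fc in DE table")
        padj = df["padj"].to_numpy(float)
        ok = np.isnan(padj) | ((padj >= 0) & (padj <= 1))
        if not ok.all():
            raise ValueError("padj outside [0, 1]")
        self.data = df.reset_index(drop=True)

    def log2fc_of(self, gene: str, default: float = 0.0) -> float:
        sel = self.data.loc[self.data["gene_key"] == _norm(gene), "log2fc"]
        return float(sel.iloc[0]) if len(sel) else default

    def padj_of(self, gene: str) -> float:
        sel = self.data.loc[self.data["gene_key"] == _norm(gene), "padj"]
        return float(sel.iloc[0]) if len(sel) else math.nan

    def __len__(self) -> int:
        return len(self.data)


def read_de_table(path, contrast: str = "") -> DETable:
    """Read the TSV dialect exported by common DE tools.

    Expects a header with ``gene``, ``log2FoldChange`` and ``padj`` (extra
    columns ignored; ``log2fc`` accepted as an alias).
    """
    df = pd.read_csv(Path(path), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene = cols.get("gene")
    lfc = cols.get("log2foldchange") or cols.get("log2fc")
    padj = cols.get("padj")
    if gene is None or lfc is None or padj is None:
        raise ValueError(
            f"{path}: expected columns gene, log2FoldChange, padj; got {list(df.columns)}")
    out = df[[gene, lfc, padj]].rename(
        columns={gene: "gene", lfc: "log2fc", padj: "padj"})
    return DETable(out, contrast=contrast or Path(path).stem)


# ---------------------------------------------------------------------------
# normalization

def compute_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million: each count divided by its sample total, times 1e6.

    ``counts`` is a gene x sample matrix of non-negative integers.  Every
    column of the result sums to 1e6.
    """
    arr = counts.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    totals = arr.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero sample column: {counts.columns[zero[0]]!r}")
    return counts / totals * 1e6


# ---------------------------------------------------------------------------
# gene selection

def select_up_genes(de: DETable, fdr_max: float = DEFAULT_FDR_MAX,
                    min_log2fc: float = 0.0) -> set[str]:
    """Significantly up-regulated genes: padj < fdr_max and log2fc > min_log2fc.

    Returns normalized gene symbols; missing padj excludes the gene.
    """
    df = de.data
    keep = (df["padj"] < fdr_max) & (df["log2fc"] > min_log2fc)
    return set(df.loc[keep.fillna(False), "gene_key"])


def select_de_genes(de: DETable, fdr_max: float = DEFAULT_FDR_MAX,
                    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC) -> set[str]:
    """Differentially expressed genes: padj < fdr_max and |log2fc| > min_abs_log2fc.

    Both inequalities are strict.
    """
    df = de.data
    keep = (df["padj"] < fdr_max) & (df["log2fc"].abs() > min_abs_log2fc)
    return set(df.loc[keep.fillna(False), "gene_key"])


# ---------------------------------------------------------------------------
# prizes

@dataclass
class PrizeAssignment:
    """Non-negative node prizes plus provenance of which contrast fed which layer."""

    prizes: dict[NodeRef, float] = field(default_factory=dict)
    beta: float = 1.0
    provenance: dict = field(default_factory=dict)

    def prize_of(self, node: NodeRef) -> float:
        return self.prizes.get(node, 0.0)

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.prizes.values() if p > 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": n.gene, "layer": n.layer, "prize": p}
                for n, p in sorted(self.prizes.items())]
        return pd.DataFrame(rows, columns=["gene", "layer", "prize"])


def assign_prizes(interactome: Interactome, de_early: DETable, de_late: DETable,
                  beta: float = 1.0, fdr_max: float = DEFAULT_FDR_MAX) -> PrizeAssignment:
    """Prize the two layers from the two contrasts.

    A protein-layer node gets ``beta * log2fc_early`` iff its gene is
    significantly up-regulated in the early contrast; an rna-layer node gets
    ``beta * log2fc_late`` iff up-regulated in the late contrast.  All other
    nodes are Steiner candidates with prize 0.  Significant genes absent from
    the corresponding layer are logged as unmapped.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    up_early = select_up_genes(de_early, fdr_max=fdr_max)
    up_late = select_up_genes(de_late, fdr_max=fdr_max)

    assignment = PrizeAssignment(beta=beta, provenance={
        "protein": de_early.contrast, "rna": de_late.contrast})
    unmapped_early, unmapped_late = [], []
    for g in sorted(up_early):
        ref = NodeRef(g, PROTEIN)
        if ref in interactome.nodes:
            assignment.prizes[ref] = beta * de_early.log2fc_of(g)
        else:
            unmapped_early.append(g)
    for g in sorted(up_late):
        ref = NodeRef(g, RNA)
        if ref in interactome.nodes:
            assignment.prizes[ref] = beta * de_late.log2fc_of(g)
        else:
            unmapped_late.append(g)
    if unmapped_early:
        logger.info("%d early-up genes not on the protein layer (e.g. %s)",
                    len(unmapped_early), unmapped_early[:5])
    if unmapped_late:
        logger.info("%d late-up genes not on the rna layer (e.g. %s)",
                    len(unmapped_late), unmapped_late[:5])
    return assignment


# ---------------------------------------------------------------------------
# assay closed forms

def ddct_fold_change(ct_gene_sample: float, ct_ref_sample: float,
                     ct_gene_control: float, ct_ref_control: float) -> float:
    """Relative qPCR quantification: 2**(-ddCt) against a reference gene.

    ddCt = (Ct_gene,sample - Ct_ref,sample) - (Ct_gene,control - Ct_ref,control).
    """
    for ct in (ct_gene_sample, ct_ref_sample, ct_gene_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("non-finite Ct value")
    ddct = (ct_gene_sample - ct_ref_sample) - (ct_gene_control - ct_ref_control)
    return 2.0 ** (-ddct)


def percent_of_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP-qPCR recovery relative to the dilution-adjusted input chromatin.

    The input Ct is first adjusted for the fraction of chromatin it
    represents (``ct_input - log2(1/input_fraction)``); recovery is then
    ``100 * 2**(adjusted_input_ct - ct_ip)`` percent.
    """
    if not (0 < input_fraction < 1):
        raise ValueError(f"input_fraction must be in (0, 1), got {input_fraction}")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValueError("non-finite Ct value")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)
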