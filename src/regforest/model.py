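"""Model/Results interface over the full network-inference pipeline.

``RegulatorInference`` bundles the data of one analysis - the two-layer
interactome and the early/late differential-expression contrasts - with the
optimization parameters (prize scaling ``beta``, tree-opening cost
``omega``).  ``fit()`` runs prize assignment, the prize-collecting Steiner
forest optimization, network induction and regulator ranking, and returns a
``RegulatorInferenceResults`` carrying the forest, the induced regulatory
network, the ranked regulator table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import regnet
from .expression import DETable, PrizeAssignment, assign_prizes, read_de_table
from .interactome import (Interactome, assemble_interactome, load_ppi,
                          load_regulons, read_ppi_table, read_regulon_table)
from .pcst import (DEFAULT_OMEGA, PCSTInstance, SteinerForest, solve_pcsf,
                   write_forest)
from .regnet import (RegulatoryNetwork, find_regulators, induce_network,
                     rank_regulators, regulators_to_frame, write_network)


class RegulatorInference:
    """Prize-collecting Steiner forest inference of transcriptional regulators.

    Parameters
    ----------
    interactome
        Assembled two-layer interactome.
    de_early, de_late
        Differential-expression tables for the early contrast (prizes the
        protein layer) and the late contrast (prizes the rna layer).
    beta
        Prize scaling (> 0); multiplies every log2 fold-change prize.
    omega
        Tree-opening cost of the forest formulation (> 0).
    fdr_max
        Adjusted-p cutoff defining up-regulated genes.
    """

    def __init__(self, interactome: Interactome, de_early: DETable,
                 de_late: DETable, beta: float = 1.0,
                 omega: float = DEFAULT_OMEGA, fdr_max: float = 0.01):
        self.interactome = interactome
        self.de_early = de_early
        self.de_late = de_late
        self.beta = float(beta)
        self.omega = float(omega)
        self.fdr_max = float(fdr_max)

    @classmethod
    def from_tables(cls, ppi_table, regulon_table, de_early, de_late,
                    score_scale: str = "thousand", **kwargs) -> "RegulatorInference":
        """Build from in-memory tables (DataFrames or row iterables)."""
        inter = assemble_interactome(load_ppi(ppi_table, score_scale=score_scale),
                                     load_regulons(regulon_table))
        if not isinstance(de_early, DETable):
            de_early = DETable(de_early.rename(columns={"log2FoldChange": "log2fc"}),
                               contrast="early")
        if not isinstance(de_late, DETable):
            de_late = DETable(de_late.rename(columns={"log2FoldChange": "log2fc"}),
                              contrast="late")
        return cls(inter, de_early, de_late, **kwargs)

    @classmethod
    def from_files(cls, ppi_path, regulon_path, de_early_path, de_late_path,
                   score_scale: str = "thousand", **kwargs) -> "RegulatorInference":
        inter = assemble_interactome(
            load_ppi(read_ppi_table(ppi_path), score_scale=score_scale),
            load_regulons(read_regulon_table(regulon_path)))
        return cls(inter, read_de_table(de_early_path, "early"),
                   read_de_table(de_late_path, "late"), **kwargs)

    def build_instance(self) -> tuple[PCSTInstance, PrizeAssignment]:
        prizes = assign_prizes(self.interactome, self.de_early, self.de_late,
                               beta=self.beta, fdr_max=self.fdr_max)
        g = self.interactome.to_networkx()
        instance = PCSTInstance(
            nodes=list(g.nodes),
            edges={(u, v): d["cost"] for u, v, d in g.edges(data=True)},
            prizes={(n.gene, n.layer): p for n, p in prizes.prizes.items() if p > 0},
            omega=self.omega)
        return instance, prizes

    def fit(self) -> "RegulatorInferenceResults":
        instance, prizes = self.build_instance()
        forest = solve_pcsf(instance, omega=self.omega)
        network = induce_network(forest, self.interactome)
        regulators = find_regulators(network)
        records = rank_regulators(regulators, self.de_early, self.de_late,
                                  network, fdr_max=self.fdr_max)
        return RegulatorInferenceResults(
            model=self, instance=instance, prizes=prizes, forest=forest,
            network=network, records=records)


@dataclass
class RegulatorInferenceResults:
    """Fitted pipeline outputs: forest, induced network, ranked regulators."""

    model: RegulatorInference
    instance: PCSTInstance
    prizes: PrizeAssignment
    forest: SteinerForest
    network: RegulatoryNetwork
    records: list

    @property
    def regulators(self) -> pd.DataFrame:
        return regulators_to_frame(self.records)

    @property
    def top_regulator(self) -> str | None:
        return self.records[0].gene if self.records else None

    def focal_analysis(self, focal_gene: str, **kwargs):
        """Interactor/shared-target analysis around one regulator."""
        return regnet.focal_interactors(self.network, focal_gene,
                                        self.model.de_late, **kwargs)

    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = write_forest(self.forest, self.instance, outdir / "forest")
        paths.update(write_network(self.network, outdir / "network"))
        rpath = outdir / "regulators.tsv"
        self.regulators.to_csv(rpath, sep="\t", index=False, float_format="%.17g")
        paths["regulators"] = rpath
        return paths

    def summary(self) -> str:
        inter = self.model.interactome
        lines = [
            "Prize-Collecting Steiner Forest regulator inference",
            "=" * 55,
            f"Interactome: {inter.n_protein} protein nodes, {inter.n_rna} rna nodes, "
            f"{len(inter.ppi_edges)} PPI edges, {len(inter.reg_edges)} regulatory edges",
            f"Prizes:      {self.prizes.n_positive} positive "
            f"(beta={self.model.beta:g}, fdr_max={self.model.fdr_max:g})",
            f"Forest:      {self.forest.n_trees} trees, "
            f"{len(self.forest.node_set())} nodes, objective "
            f"{self.forest.objective:.4f} (omega={self.model.omega:g})",
            f"Network:     {len(self.network.nodes)} nodes, "
            f"{self.network.n_edges} edges, "
            f"{len(find_regulators(self.network))} regulators",
            "",
            f"{'rank':>4}  {'gene':<12} {'early_lfc':>9} {'up_targets':>10} "
            f"{'composite':>9}",
        ]
        for i, r in enumerate(self.records[:10], start=1):
            lines.append(f"{i:>4}  {r.gene:<12} {r.early_log2fc:>9.3f} "
                         f"{r.n_up_targets:>10d} {r.composite_rank:>9.1f}")
        if len(self.records) > 10:
            lines.append(f"... ({len(self.records) - 10} more regulators)")
        return "\n".join(lines)
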