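"""From an optimized Steiner forest back to a transcriptional regulatory network.

The forest selects the nodes; the network is the full interactome subgraph
induced on them, so edges the optimization did not need (but that exist in
the databases) reappear with their original kind, direction and cost.
Transcriptional regulators are the protein-layer nodes of this network with
at least one direct regulatory edge onto an rna-layer node; they are ranked
by two criteria the analysis cares about - early fold change, and how many
of their in-network targets are up-regulated late - combined as the mean of
the two dense ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import DETable, select_up_genes
from .interactome import PROTEIN, RNA, Interactome, NodeRef, PPIEdge, RegEdge, _norm
from .pcst import SteinerForest

DEFAULT_REPROGRAMMING_SET = frozenset({"Pou5f1", "Nanog", "Sox2", "Klf4", "Myc"})


@dataclass
class RegulatoryNetwork:
    """Interactome subgraph induced on the forest's node set."""

    nodes: dict  # NodeRef -> display gene
    ppi_edges: dict  # frozenset pair -> PPIEdge
    reg_edges: dict  # (tf, target) -> RegEdge

    def protein_nodes(self) -> set[str]:
        return {n.gene for n in self.nodes if n.layer == PROTEIN}

    def rna_nodes(self) -> set[str]:
        return {n.gene for n in self.nodes if n.layer == RNA}

    def targets_of(self, tf: str) -> set[str]:
        key = _norm(tf)
        return {t for (s, t) in self.reg_edges if s == key}

    def ppi_neighbors(self, gene: str) -> set[str]:
        key = _norm(gene)
        out = set()
        for pair in self.ppi_edges:
            if key in pair:
                out |= pair - {key}
        return out

    @property
    def n_edges(self) -> int:
        return len(self.ppi_edges) + len(self.reg_edges)


@dataclass
class RegulatorRecord:
    """Per-regulator ranking entry."""

    gene: str
    early_log2fc: float
    n_up_targets: int
    n_down_targets: int
    rank_by_lfc: int = 0
    rank_by_targets: int = 0
    composite_rank: float = 0.0


def induce_network(forest: SteinerForest, interactome: Interactome) -> RegulatoryNetwork:
    """Interactome subgraph induced on the forest nodes.

    Forest nodes must be (gene, layer) pairs present in the interactome;
    every PPI and regulatory edge with both endpoints in the forest is kept
    with its original attributes.
    """
    refs = set()
    for (gene, layer) in forest.node_set():
        ref = NodeRef(gene, layer)
        if ref not in interactome.nodes:
            raise ValueError(f"forest node {ref} missing from interactome")
        refs.add(ref)
    genes_by_layer = {
        PROTEIN: {r.gene for r in refs if r.layer == PROTEIN},
        RNA: {r.gene for r in refs if r.layer == RNA},
    }
    net = RegulatoryNetwork(
        nodes={r: interactome.nodes[r] for r in refs}, ppi_edges={}, reg_edges={})
    for pair, e in interactome.ppi_edges.items():
        if pair <= genes_by_layer[PROTEIN]:
            net.ppi_edges[pair] = e
    for (tf, tg), e in interactome.reg_edges.items():
        if tf in genes_by_layer[PROTEIN] and tg in genes_by_layer[RNA]:
            net.reg_edges[(tf, tg)] = e
    return net


def find_regulators(network: RegulatoryNetwork) -> set[str]:
    """Protein-layer nodes with >= 1 regulatory out-edge to an rna node in-network."""
    return {tf for (tf, _) in network.reg_edges}


def rank_regulators(regulators: set[str], de_early: DETable, de_late: DETable,
                    network: RegulatoryNetwork,
                    fdr_max: float = 0.01) -> list[RegulatorRecord]:
    """Rank regulators by early fold change and late up-regulated target count.

    ``rank_by_lfc`` and ``rank_by_targets`` are descending dense ranks;
    ``composite_rank`` is their mean.  The returned list is sorted by
    composite rank ascending with alphabetical tie-break on the gene symbol.
    """
    regulators = {_norm(g) for g in regulators}
    unknown = regulators - {tf for (tf, _) in network.reg_edges}
    if unknown:
        raise ValueError(f"not regulators of this network: {sorted(unknown)}")
    up_late = select_up_genes(de_late, fdr_max=fdr_max)
    down_late = {
        g for g in de_late.data.loc[
            (de_late.data["padj"] < fdr_max) & (de_late.data["log2fc"] < 0),
            "gene_key"]}

    records = []
    for g in sorted(regulators):
        targets = network.targets_of(g)
        records.append(RegulatorRecord(
            gene=g,
            early_log2fc=de_early.log2fc_of(g, default=0.0),
            n_up_targets=len(targets & up_late),
            n_down_targets=len(targets & down_late),
        ))
    if not records:
        return []
    df = pd.DataFrame({"lfc": [r.early_log2fc for r in records],
                       "nup": [r.n_up_targets for r in records]})
    rank_lfc = df["lfc"].rank(method="dense", ascending=False).astype(int)
    rank_nup = df["nup"].rank(method="dense", ascending=False).astype(int)
    for r, rl, rt in zip(records, rank_lfc, rank_nup):
        r.rank_by_lfc = int(rl)
        r.rank_by_targets = int(rt)
        r.composite_rank = (rl + rt) / 2.0
    records.sort(key=lambda r: (r.composite_rank, r.gene))
    return records


def regulators_to_frame(records: list[RegulatorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": r.gene, "early_log2fc": r.early_log2fc,
          "n_up_targets": r.n_up_targets, "n_down_targets": r.n_down_targets,
          "rank_by_lfc": r.rank_by_lfc, "rank_by_targets": r.rank_by_targets,
          "composite_rank": r.composite_rank} for r in records],
        columns=["gene", "early_log2fc", "n_up_targets", "n_down_targets",
                 "rank_by_lfc", "rank_by_targets", "composite_rank"])


@dataclass
class FocalInteractorRecord:
    """One PPI partner of the focal regulator and their shared regulon."""

    gene: str
    shared_targets: set = field(default_factory=set)
    n_shared_up: int = 0
    n_shared_down: int = 0
    shared_reprogramming: set = field(default_factory=set)


def focal_interactors(network: RegulatoryNetwork, focal_gene: str, de_late: DETable,
                      reprogramming_set=DEFAULT_REPROGRAMMING_SET,
                      fdr_max: float = 0.01) -> list[FocalInteractorRecord]:
    """Regulators sharing a PPI edge with the focal regulator, with shared targets.

    For each PPI-neighboring regulator the shared in-network regulatory
    targets are intersected with the late contrast: counts of shared targets
    significantly up- and down-regulated (padj < ``fdr_max``, sign of
    log2fc), plus which reprogramming factors are shared targets.
    """
    focal = _norm(focal_gene)
    regulators = find_regulators(network)
    if focal not in regulators:
        raise ValueError(f"{focal_gene!r} is not a regulator of this network")
    reprog = {_norm(g) for g in reprogramming_set}
    sig = de_late.data["padj"] < fdr_max
    up_late = set(de_late.data.loc[sig & (de_late.data["log2fc"] > 0), "gene_key"])
    down_late = set(de_late.data.loc[sig & (de_late.data["log2fc"] < 0), "gene_key"])
    focal_targets = network.targets_of(focal)

    out = []
    for g in sorted(network.ppi_neighbors(focal) & regulators - {focal}):
        shared = network.targets_of(g) & focal_targets
        out.append(FocalInteractorRecord(
            gene=g,
            shared_targets=shared,
            n_shared_up=len(shared & up_late),
            n_shared_down=len(shared & down_late),
            shared_reprogramming=shared & reprog,
        ))
    return out


def focal_target_overlap(network: RegulatoryNetwork, focal_gene: str,
                         candidate_regulators) -> set[str]:
    """Candidates whose rna-layer node is a regulatory target of the focal gene."""
    focal_targets = network.targets_of(focal_gene)
    return {_norm(g) for g in candidate_regulators if _norm(g) in focal_targets}


# ---------------------------------------------------------------------------
# export

def write_network(network: RegulatoryNetwork, prefix,
                  reprogramming_set=DEFAULT_REPROGRAMMING_SET) -> dict[str, Path]:
    """GraphML + TSV tables; nodes flagged as regulator / reprogramming factor."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    regulators = find_regulators(network)
    reprog = {_norm(g) for g in reprogramming_set}

    g = nx.Graph()
    for ref in sorted(network.nodes):
        g.add_node((ref.gene, ref.layer), gene=network.nodes[ref], layer=ref.layer,
                   is_regulator=(ref.layer == PROTEIN and ref.gene in regulators),
                   is_reprogramming=(ref.gene in reprog))
    for pair in sorted(network.ppi_edges, key=lambda p: tuple(sorted(p))):
        e = network.ppi_edges[pair]
        g.add_edge((e.u, PROTEIN), (e.v, PROTEIN), kind="ppi",
                   confidence=e.confidence, cost=e.cost)
    for key in sorted(network.reg_edges):
        e = network.reg_edges[key]
        g.add_edge((e.tf, PROTEIN), (e.target, RNA), kind="regulatory",
                   confidence=float(e.n_sources), cost=e.cost)
    mapping = {n: f"{n[0]}|{n[1]}" for n in g.nodes}
    graphml = prefix.with_suffix(".graphml")
    nx.write_graphml(nx.relabel_nodes(g, mapping), graphml)

    nrows = [{"gene": network.nodes[ref], "gene_key": ref.gene, "layer": ref.layer,
              "is_regulator": int(ref.layer == PROTEIN and ref.gene in regulators),
              "is_reprogramming": int(ref.gene in reprog)}
             for ref in sorted(network.nodes)]
    npath = Path(str(prefix) + ".nodes.tsv")
    pd.DataFrame(nrows, columns=["gene", "gene_key", "layer", "is_regulator",
                                 "is_reprogramming"]).to_csv(npath, sep="\t", index=False)
    erows = []
    for pair in sorted(network.ppi_edges, key=lambda p: tuple(sorted(p))):
        e = network.ppi_edges[pair]
        erows.append({"u": e.u, "u_layer": PROTEIN, "v": e.v, "v_layer": PROTEIN,
                      "kind": "ppi", "confidence": e.confidence, "cost": e.cost})
    for key in sorted(network.reg_edges):
        e = network.reg_edges[key]
        erows.append({"u": e.tf, "u_layer": PROTEIN, "v": e.target, "v_layer": RNA,
                      "kind": "regulatory", "confidence": float(e.n_sources),
                      "cost": e.cost})
    epath = Path(str(prefix) + ".edges.tsv")
    pd.DataFrame(erows, columns=["u", "u_layer", "v", "v_layer", "kind",
                                 "confidence", "cost"]).to_csv(
        epath, sep="\t", index=False, float_format="%.17g")
    return {"graphml": graphml, "nodes": npath, "edges": epath}
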