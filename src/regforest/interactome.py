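"""Two-layer interactome: protein-protein interactions plus TF->target regulons.

The network has two layers.  Proteins (PPI endpoints and transcription
factors) live on the *protein* layer and are linked by undirected PPI edges
whose confidence scores come from a STRING-style combined score.  Regulon
targets live on the *rna* layer and are reached only through directed
TF->target edges.  The same gene symbol may appear on both layers; the node
identity is the (gene, layer) pair.

Edge costs are what the Steiner optimization pays: a reliable PPI edge is
cheap (``cost = 1 - confidence``, clamped away from zero) and every
regulatory edge carries a constant configurable cost, because regulon
membership is binary evidence with no per-edge score.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN = "protein"
RNA = "rna"

#: default clamp keeping PPI costs strictly positive
DEFAULT_COST_FLOOR = 0.01
#: default cost of a TF->target edge
DEFAULT_REG_EDGE_COST = 0.5


class MalformedInputError(ValueError):
    """A row of an input table violates the declared format."""


@dataclass(frozen=True, order=True)
class NodeRef:
    """Identity of one interactome node: a gene symbol on one layer."""

    gene: str
    layer: str

    def __post_init__(self):
        if self.layer not in (PROTEIN, RNA):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.gene or not self.gene.strip():
            raise ValueError("empty gene symbol")


def _norm(gene: str) -> str:
    """Case-normalized comparison key (mouse symbol casing is inconsistent)."""
    return str(gene).strip().upper()


@dataclass
class PPIEdge:
    u: str
    v: str
    confidence: float
    cost: float = 0.0


@dataclass
class RegEdge:
    tf: str
    target: str
    n_sources: int
    cost: float = DEFAULT_REG_EDGE_COST


@dataclass
class Interactome:
    """Assembled two-layer network.

    ``nodes`` maps the case-normalized (gene, layer) identity to the original
    casing seen first in the input.  PPI edges are keyed by the unordered
    normalized pair; regulatory edges by the ordered (tf, target) pair.
    """

    nodes: dict[NodeRef, str] = field(default_factory=dict)
    ppi_edges: dict[frozenset, PPIEdge] = field(default_factory=dict)
    reg_edges: dict[tuple, RegEdge] = field(default_factory=dict)

    # -- queries ---------------------------------------------------------
    def has_node(self, gene: str, layer: str) -> bool:
        return NodeRef(_norm(gene), layer) in self.nodes

    @property
    def n_protein(self) -> int:
        return sum(1 for n in self.nodes if n.layer == PROTEIN)

    @property
    def n_rna(self) -> int:
        return sum(1 for n in self.nodes if n.layer == RNA)

    def targets_of(self, tf: str) -> set[str]:
        """Normalized rna-layer targets of ``tf``."""
        key = _norm(tf)
        return {t for (s, t) in self.reg_edges if s == key}

    def ppi_neighbors(self, gene: str) -> set[str]:
        key = _norm(gene)
        out = set()
        for pair in self.ppi_edges:
            if key in pair:
                (other,) = pair - {key} if len(pair) == 2 else {key}
                out.add(other)
        return out

    def to_networkx(self) -> nx.Graph:
        """Undirected view with (gene, layer) node keys and typed edges.

        Regulatory direction is recoverable from the layers (protein -> rna);
        an undirected graph is what the Steiner optimization consumes.
        """
        g = nx.Graph()
        for ref, display in sorted(self.nodes.items()):
            g.add_node((ref.gene, ref.layer), gene=display, layer=ref.layer)
        for pair, e in sorted(self.ppi_edges.items(), key=lambda kv: tuple(sorted(kv[0]))):
            u, v = sorted(pair)
            g.add_edge((u, PROTEIN), (v, PROTEIN), kind="ppi",
                       confidence=e.confidence, cost=e.cost)
        for (tf, tg), e in sorted(self.reg_edges.items()):
            g.add_edge((tf, PROTEIN), (tg, RNA), kind="regulatory",
                       confidence=float(e.n_sources), cost=e.cost)
        return g


# ---------------------------------------------------------------------------
# loading

def load_ppi(table: pd.DataFrame | Iterable, score_scale: str = "thousand") -> list[PPIEdge]:
    """Parse a STRING-style edge list into merged, rescaled PPI edges.

    Parameters
    ----------
    table
        Rows of (protein1, protein2, combined_score), as a DataFrame with
        those columns or any iterable of 3-tuples.
    score_scale
        ``"unit"`` for scores already in (0, 1]; ``"thousand"`` for
        STRING-style 0-1000 integer scores.

    Self-loops are dropped, symmetric/duplicate rows are merged keeping the
    maximum confidence, and the result is independent of row order.
    """
    if score_scale not in ("unit", "thousand"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    scale = 1.0 if score_scale == "unit" else 1000.0

    if isinstance(table, pd.DataFrame):
        rows = list(table.itertuples(index=False, name=None))
    else:
        rows = [tuple(r) for r in table]
    if not rows:
        warnings.warn("empty PPI table: no edges loaded", stacklevel=2)
        return []

    merged: dict[frozenset, PPIEdge] = {}
    display: dict[str, str] = {}
    for i, row in enumerate(rows):
        a, b, score = row[0], row[1], row[2]
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise MalformedInputError(f"row {i}: non-numeric score {score!r}")
        if not (0 <= score <= scale):
            raise MalformedInputError(
                f"row {i}: score {score} outside declared scale 0-{scale:g}")
        ka, kb = _norm(a), _norm(b)
        if not ka or not kb:
            raise MalformedInputError(f"row {i}: empty protein name")
        if ka == kb:  # self-loop
            continue
        conf = score / scale
        if conf <= 0:
            continue
        display.setdefault(ka, str(a).strip())
        display.setdefault(kb, str(b).strip())
        pair = frozenset((ka, kb))
        prev = merged.get(pair)
        if prev is None or conf > prev.confidence:
            u, v = sorted(pair)
            merged[pair] = PPIEdge(u=u, v=v, confidence=conf)
    edges = [merged[p] for p in sorted(merged, key=lambda p: tuple(sorted(p)))]
    for e in edges:
        e.u_display = display[e.u]  # type: ignore[attr-defined]
        e.v_display = display[e.v]  # type: ignore[attr-defined]
    return edges


def load_regulons(tables: pd.DataFrame | Iterable) -> list[RegEdge]:
    """Parse TF->target rows (tf, target, source) into deduplicated relations.

    Duplicate (tf, target) pairs across source databases collapse into one
    relation carrying the count of distinct supporting sources.  TF
    self-regulation is retained: the protein-layer TF and its rna-layer
    transcript are different nodes.
    """
    if isinstance(tables, pd.DataFrame):
        rows = list(tables.itertuples(index=False, name=None))
    else:
        rows = [tuple(r) for r in tables]
    if not rows:
        warnings.warn("empty regulon table: no relations loaded", stacklevel=2)
        return []

    sources: dict[tuple, set] = {}
    display: dict[str, str] = {}
    for i, row in enumerate(rows):
        tf, target = row[0], row[1]
        src = row[2] if len(row) > 2 else "unspecified"
        ktf, ktg = _norm(tf), _norm(target)
        if not ktf or not ktg:
            raise MalformedInputError(f"row {i}: empty gene symbol")
        display.setdefault(ktf, str(tf).strip())
        display.setdefault(ktg, str(target).strip())
        sources.setdefault((ktf, ktg), set()).add(src)
    out = []
    for (ktf, ktg) in sorted(sources):
        e = RegEdge(tf=ktf, target=ktg, n_sources=len(sources[(ktf, ktg)]))
        e.tf_display = display[ktf]  # type: ignore[attr-defined]
        e.target_display = display[ktg]  # type: ignore[attr-defined]
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# assembly

def default_ppi_cost(confidence: float, cost_floor: float = DEFAULT_COST_FLOOR) -> float:
    """Cost of a PPI edge: 1 - confidence, clamped below by ``cost_floor``."""
    return max(1.0 - confidence, cost_floor)


def assemble_interactome(
    ppi_edges: list[PPIEdge],
    reg_relations: list[RegEdge],
    ppi_cost_rule=default_ppi_cost,
    reg_edge_cost: float = DEFAULT_REG_EDGE_COST,
) -> Interactome:
    """Combine PPI edges and regulon relations into the two-layer network.

    Protein nodes are the union of PPI endpoints and regulon TFs; rna nodes
    are the regulon targets.
    """
    if reg_edge_cost <= 0:
        raise ValueError(f"reg_edge_cost must be positive, got {reg_edge_cost}")

    inter = Interactome()
    for e in ppi_edges:
        cost = float(ppi_cost_rule(e.confidence))
        if cost <= 0:
            raise ValueError(f"ppi_cost_rule produced non-positive cost {cost}")
        inter.nodes.setdefault(NodeRef(e.u, PROTEIN), getattr(e, "u_display", e.u))
        inter.nodes.setdefault(NodeRef(e.v, PROTEIN), getattr(e, "v_display", e.v))
        inter.ppi_edges[frozenset((e.u, e.v))] = PPIEdge(
            u=e.u, v=e.v, confidence=e.confidence, cost=cost)
    for r in reg_relations:
        inter.nodes.setdefault(NodeRef(r.tf, PROTEIN), getattr(r, "tf_display", r.tf))
        inter.nodes.setdefault(NodeRef(r.target, RNA),
                               getattr(r, "target_display", r.target))
        inter.reg_edges[(r.tf, r.target)] = RegEdge(
            tf=r.tf, target=r.target, n_sources=r.n_sources, cost=float(reg_edge_cost))
    logger.info(
        "assembled interactome: %d protein nodes, %d rna nodes, %d ppi edges, %d reg edges",
        inter.n_protein, inter.n_rna, len(inter.ppi_edges), len(inter.reg_edges))
    return inter


# ---------------------------------------------------------------------------
# i/o

def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_ppi_table(path) -> pd.DataFrame:
    """Read a tab-separated PPI edge list (protein1, protein2, combined_score)."""
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t")


def read_regulon_table(path) -> pd.DataFrame:
    """Read a tab-separated regulon table (tf, target, source)."""
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t")


def write_interactome(inter: Interactome, prefix) -> dict[str, Path]:
    """Serialize to GraphML plus flat node/edge TSV tables.

    Returns the written paths keyed by kind.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = inter.to_networkx()
    # GraphML node ids must be strings
    mapping = {n: f"{n[0]}|{n[1]}" for n in g.nodes}
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(nx.relabel_nodes(g, mapping), graphml_path)

    node_rows = [
        {"gene": inter.nodes[ref], "gene_key": ref.gene, "layer": ref.layer}
        for ref in sorted(inter.nodes)
    ]
    nodes_path = Path(str(prefix) + ".nodes.tsv")
    pd.DataFrame(node_rows, columns=["gene", "gene_key", "layer"]).to_csv(
        nodes_path, sep="\t", index=False)

    edge_rows = []
    for pair in sorted(inter.ppi_edges, key=lambda p: tuple(sorted(p))):
        e = inter.ppi_edges[pair]
        edge_rows.append({"u": e.u, "u_layer": PROTEIN, "v": e.v, "v_layer": PROTEIN,
                          "kind": "ppi", "confidence": e.confidence, "cost": e.cost})
    for key in sorted(inter.reg_edges):
        e = inter.reg_edges[key]
        edge_rows.append({"u": e.tf, "u_layer": PROTEIN, "v": e.target, "v_layer": RNA,
                          "kind": "regulatory", "confidence": float(e.n_sources),
                          "cost": e.cost})
    edges_path = Path(str(prefix) + ".edges.tsv")
    pd.DataFrame(edge_rows, columns=["u", "u_layer", "v", "v_layer", "kind",
                                     "confidence", "cost"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.17g")
    return {"graphml": graphml_path, "nodes": nodes_path, "edges": edges_path}


def read_interactome(prefix) -> Interactome:
    """Rebuild an Interactome from the node/edge TSV tables written by
    :func:`write_interactome`."""
    prefix = Path(prefix)
    nodes = pd.read_csv(Path(str(prefix) + ".nodes.tsv"), sep="\t")
    edges = pd.read_csv(Path(str(prefix) + ".edges.tsv"), sep="\t")
    inter = Interactome()
    for row in nodes.itertuples(index=False):
        inter.nodes[NodeRef(row.gene_key, row.layer)] = row.gene
    for row in edges.itertuples(index=False):
        if row.kind == "ppi":
            u, v = sorted((row.u, row.v))
            inter.ppi_edges[frozenset((u, v))] = PPIEdge(
                u=u, v=v, confidence=float(row.confidence), cost=float(row.cost))
        elif row.kind == "regulatory":
            inter.reg_edges[(row.u, row.v)] = RegEdge(
                tf=row.u, target=row.v, n_sources=int(row.confidence),
                cost=float(row.cost))
        else:
            raise MalformedInputError(f"unknown edge kind {row.kind!r}")
    return inter
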