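import pandas as pd
import pytest

from regforest import pcst
from regforest.expression import DETable
from regforest.interactome import assemble_interactome, load_ppi, load_regulons


@pytest.fixture
def path_instance():
    """Path A-B-C, unit edge costs, prizes at the endpoints only."""
    return pcst.PCSTInstance(
        nodes=["A", "B", "C"],
        edges={("A", "B"): 1.0, ("B", "C"): 1.0},
        prizes={"A": 5.0, "C": 5.0},
        omega=1.0)


@pytest.fixture
def toy_interactome():
    """Hand-built two-layer network used by the regulator bookkeeping tests.

    Proteins A, M, B, C; PPI A-M (0.9), M-B (0.8), A-B (0.6), B-C (0.95).
    Regulons: A -> {g1, g2, B}, B -> {g2, g3}, C -> {g4}; the A -> B relation
    creates an rna-layer node for B alongside its protein node.
    """
    ppi = pd.DataFrame(
        [("A", "M", 900), ("M", "B", 800), ("A", "B", 600), ("B", "C", 950)],
        columns=["protein1", "protein2", "combined_score"])
    reg = pd.DataFrame(
        [("A", "g1", "s1"), ("A", "g2", "s1"), ("A", "B", "s1"),
         ("B", "g2", "s1"), ("B", "g3", "s1"), ("C", "g4", "s1")],
        columns=["tf", "target", "source"])
    return assemble_interactome(load_ppi(ppi, score_scale="thousand"),
                                load_regulons(reg))


@pytest.fixture
def toy_forest():
    """Tree over {A, M, B, g1, g2, g3, B(rna)} inside ``toy_interactome``."""
    nodes = frozenset({("A", "protein"), ("M", "protein"), ("B", "protein"),
                       ("G1", "rna"), ("G2", "rna"), ("G3", "rna"), ("B", "rna")})
    edges = (
        (("A", "protein"), ("M", "protein")),
        (("B", "protein"), ("M", "protein")),
        (("A", "protein"), ("G1", "rna")),
        (("A", "protein"), ("G2", "rna")),
        (("B", "protein"), ("G3", "rna")),
        (("A", "protein"), ("B", "rna")),
    )
    tree = pcst.Tree(nodes=nodes, edges=edges)
    return pcst.SteinerForest(trees=[tree], objective=0.0, params={})


@pytest.fixture
def toy_de_tables():
    de_early = DETable(pd.DataFrame({
        "gene": ["A", "B", "M", "C"],
        "log2fc": [3.0, 1.0, 2.0, 0.1],
        "padj": [1e-5, 1e-5, 1e-5, 0.8],
    }), contrast="early")
    de_late = DETable(pd.DataFrame({
        "gene": ["g1", "g2", "g3", "g4", "B"],
        "log2fc": [2.0, 3.0, -2.0, 5.0, -0.5],
        "padj": [1e-4, 1e-4, 1e-4, 0.5, 0.9],
    }), contrast="late")
    return de_early, de_late
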