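"""Prize-collecting Steiner forest optimization.

A PCST instance is an undirected graph with strictly positive edge costs
``c(e)`` and non-negative node prizes ``p(v)``.  A solution is a forest of
node-disjoint trees; it pays the costs of the edges it uses and forfeits
the prizes of the nodes it leaves out.  Maximizing collected prize minus
edge cost and minimizing paid cost plus forfeited prize select the same
forests (the two objectives differ by the constant ``sum_v p(v)``); the
minimization form is used throughout.

Opening a tree costs ``omega`` (the dummy-root formulation): the solvers
optimize ``sum(cost) + sum(forfeited prize) + omega * n_trees``, which is
what makes the trade-off between one large tree and several small ones
well-posed.  The reported ``SteinerForest.objective`` is the omega-free
part, recomputable from the forest alone.  Every tree carries at least one
edge; an isolated node is never a tree.

Two solvers are provided: :func:`solve_exact`, a brute-force enumeration
over connected parts (the test oracle, exponential, capped at 15 nodes),
and :func:`solve_pcsf`, a deterministic Goemans-Williamson-style moat-growth
primal-dual followed by strong pruning, usable at realistic sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_TOL = 1e-12

DEFAULT_OMEGA = 1.0


class ForestValidationError(ValueError):
    """A forest refers to nodes or edges missing from its instance."""


def _ekey(u, v):
    return (u, v) if repr(u) <= repr(v) else (v, u)


@dataclass
class PCSTInstance:
    """Undirected prized, costed graph plus the root-opening cost omega.

    Node ids may be any sortable hashables (gene/layer pairs in the
    pipeline, plain strings in tests).  The dummy root used by the
    primal-dual solver is internal and never a member of ``nodes``.
    """

    nodes: list
    edges: dict  # (u, v) sorted key -> cost > 0
    prizes: dict  # node -> prize >= 0 (missing means 0)
    omega: float = DEFAULT_OMEGA

    def __post_init__(self):
        self.nodes = sorted(set(self.nodes), key=repr)
        nodeset = set(self.nodes)
        edges = {}
        for (u, v), c in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge endpoint not a node: {(u, v)!r}")
            c = float(c)
            if c <= 0:
                raise ValueError(f"non-positive edge cost {c} on {(u, v)!r}")
            edges[_ekey(u, v)] = c
        self.edges = edges
        for v, p in self.prizes.items():
            if v not in nodeset:
                raise ValueError(f"prize on unknown node {v!r}")
            if p < 0:
                raise ValueError(f"negative prize {p} on {v!r}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")

    def prize(self, v) -> float:
        return float(self.prizes.get(v, 0.0))

    @property
    def total_prize(self) -> float:
        return float(sum(self.prizes.values()))

    def cost(self, u, v) -> float:
        return self.edges[_ekey(u, v)]


@dataclass
class Tree:
    """One tree of a forest: a node set and the edges spanning it."""

    nodes: frozenset
    edges: tuple  # of sorted-key pairs; costs live on the instance


@dataclass
class SteinerForest:
    """Node-disjoint trees plus the omega-free objective and run parameters."""

    trees: list
    objective: float  # sum(edge costs) + sum(forfeited prizes); no omega term
    params: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def node_set(self) -> frozenset:
        out = set()
        for t in self.trees:
            out |= t.nodes
        return frozenset(out)

    def edge_list(self) -> list:
        return [e for t in self.trees for e in t.edges]

    def collected_prize(self, instance: PCSTInstance) -> float:
        return sum(instance.prize(v) for v in self.node_set())

    def objective_with_root(self, instance: PCSTInstance) -> float:
        """The quantity the solvers optimize: objective + omega * n_trees."""
        return self.objective + instance.omega * self.n_trees

    def sort_key(self):
        return sorted(sorted(t.nodes, key=repr) for t in self.trees)


def _validate_forest(instance: PCSTInstance, forest: SteinerForest):
    seen = set()
    for t in forest.trees:
        if t.nodes & seen:
            raise ForestValidationError("trees share nodes")
        seen |= t.nodes
        if len(t.edges) != len(t.nodes) - 1:
            raise ForestValidationError("tree is not acyclic/connected")
        # connectivity check by union-find over the tree's own edges
        parent = {v: v for v in t.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (u, v) in t.edges:
            if _ekey(u, v) not in instance.edges:
                raise ForestValidationError(f"edge {(u, v)!r} not in instance")
            if u not in t.nodes or v not in t.nodes:
                raise ForestValidationError("edge endpoint outside its tree")
            ru, rv = find(u), find(v)
            if ru == rv:
                raise ForestValidationError("cycle inside tree")
            parent[ru] = rv


def pcst_objective(instance: PCSTInstance, forest: SteinerForest) -> float:
    """Paid edge costs plus forfeited prizes of excluded nodes (no omega term)."""
    _validate_forest(instance, forest)
    in_forest = forest.node_set()
    cost = sum(instance.edges[_ekey(u, v)] for (u, v) in forest.edge_list())
    forfeited = sum(instance.prize(v) for v in instance.nodes if v not in in_forest)
    return float(cost + forfeited)


def _make_forest(instance: PCSTInstance, trees: list, params: dict) -> SteinerForest:
    forest = SteinerForest(trees=trees, objective=0.0, params=params)
    forest.objective = pcst_objective(instance, forest)
    return forest


# ---------------------------------------------------------------------------
# exact oracle

def solve_exact(instance: PCSTInstance, max_nodes: int = 15) -> SteinerForest:
    """Global optimum by enumeration over connected parts (test oracle).

    For every node subset the minimum spanning cost of its induced subgraph
    is tabulated; a subset-partition dynamic program then assembles the
    cheapest forest, accounting omega per tree.  Ties are broken toward the
    lexicographically smallest sorted node-set list (the empty forest wins a
    tie against any forest).  Exponential: refuses instances above
    ``max_nodes``.
    """
    n = len(instance.nodes)
    if n > max_nodes:
        raise ValueError(
            f"{n} nodes exceeds exact-solver budget of {max_nodes}; use solve_pcsf")
    nodes = instance.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    prizes = [instance.prize(v) for v in nodes]
    p_tot = sum(prizes)
    edges = sorted((c, idx[u], idx[v]) for (u, v), c in instance.edges.items())

    full = 1 << n
    INF = float("inf")

    # minimum spanning cost (Kruskal) of the induced subgraph, per subset
    part_cost = [INF] * full
    part_edges: list = [None] * full
    for mask in range(1, full):
        if bin(mask).count("1") < 2:
            continue
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        cost = 0.0
        chosen = []
        comps = bin(mask).count("1")
        for c, a, b in edges:
            if not ((mask >> a) & 1 and (mask >> b) & 1):
                continue
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                cost += c
                chosen.append((a, b))
                comps -= 1
                if comps == 1:
                    break
        if comps == 1:
            part_cost[mask] = cost + instance.omega
            part_edges[mask] = chosen

    # subset-partition DP: g[mask] = cheapest cover of mask by connected parts
    g = [INF] * full
    choice = [0] * full
    g[0] = 0.0
    for mask in range(1, full):
        low = mask & (-mask)
        sub = mask
        best, best_t = INF, 0
        while sub:
            if (sub & low) and part_cost[sub] < INF:
                cand = part_cost[sub] + g[mask ^ sub]
                if cand < best - _TOL:
                    best, best_t = cand, sub
            sub = (sub - 1) & mask
        g[mask] = best
        choice[mask] = best_t

    # pick the best covered set; tie-break by lexicographic node-set order
    best_mask, best_obj, best_key = 0, p_tot, ()
    for mask in range(1, full):
        if g[mask] >= INF:
            continue
        obj = g[mask] + p_tot - sum(prizes[i] for i in range(n) if (mask >> i) & 1)
        key = tuple(i for i in range(n) if (mask >> i) & 1)
        if obj < best_obj - _TOL or (abs(obj - best_obj) <= _TOL and key < best_key):
            best_mask, best_obj, best_key = mask, obj, key

    trees = []
    mask = best_mask
    while mask:
        t = choice[mask]
        tnodes = frozenset(nodes[i] for i in range(n) if (t >> i) & 1)
        tedges = tuple(sorted(_ekey(nodes[a], nodes[b]) for a, b in part_edges[t]))
        trees.append(Tree(nodes=tnodes, edges=tedges))
        mask ^= t
    trees.sort(key=lambda t: sorted(t.nodes, key=repr))
    return _make_forest(instance, trees, {"solver": "exact", "omega": instance.omega})


# ---------------------------------------------------------------------------
# strong pruning

def _adjacency(nodes, edge_pairs, costs):
    adj = {v: [] for v in nodes}
    for (u, v) in edge_pairs:
        c = costs[_ekey(u, v)]
        adj[u].append((v, c))
        adj[v].append((u, c))
    return adj


def _prune_dp(root, adj, prizes) -> tuple:
    """Leaf-to-root DP rooted at ``root``.

    ``net(v) = p(v) + sum over children of max(0, net(child) - cost)``; a
    child subtree is kept only when its net strictly exceeds the cost of
    the edge attaching it (ties pruned, keeping forests minimal).  Returns
    the per-node net map and the kept-children map.
    """
    order = [(root, None, None)]
    stack = [(root, None, None)]
    while stack:
        v, par, _ = stack.pop()
        for (w, c) in adj[v]:
            if w != par:
                order.append((w, v, c))
                stack.append((w, v, c))
    net = {}
    keep_children = {v: [] for v in adj}
    for (v, par, cost) in reversed(order):
        total = prizes[v]
        for (w, c) in adj[v]:
            if w != par and net[w] - c > _TOL:
                total += net[w] - c
                keep_children[v].append(w)
        net[v] = total
    return net, keep_children


def _expand_kept(root, keep_children) -> set:
    kept = {root}
    stack = [root]
    while stack:
        v = stack.pop()
        for w in keep_children[v]:
            kept.add(w)
            stack.append(w)
    return kept


def _prune_from_root(root, adj, prizes) -> tuple:
    """(net prize at root, kept node set) of the DP rooted at ``root``."""
    net, keep_children = _prune_dp(root, adj, prizes)
    return net[root], _expand_kept(root, keep_children)


def strong_prune(tree: Tree, prizes: dict, costs: dict) -> Tree:
    """Remove every subtree whose summed prize cannot pay for its attachment.

    A leaf-to-root dynamic program is evaluated from every possible rooting
    and the best surviving subtree is returned (deterministic tie-break by
    the sorted node ids).  The objective never increases and the operation
    is idempotent.  The result may be a single node if nothing else is
    profitable.
    """
    nodeset = set(tree.nodes)
    if len(tree.edges) != len(nodeset) - 1:
        raise ForestValidationError("strong_prune input is not a tree")
    for (u, v) in tree.edges:
        if u not in nodeset or v not in nodeset:
            raise ForestValidationError("edge endpoint outside tree")
    adj = _adjacency(tree.nodes, tree.edges, costs)
    # connectivity
    seen = set()
    stack = [next(iter(sorted(nodeset, key=repr)))]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(w for (w, _) in adj[v])
    if seen != nodeset:
        raise ForestValidationError("strong_prune input is not connected")

    pmap = {v: float(prizes.get(v, 0.0)) for v in tree.nodes}
    best_net, best_kept, best_root = -1.0, None, None
    for root in sorted(nodeset, key=repr):
        net, kept = _prune_from_root(root, adj, pmap)
        if net > best_net + _TOL:
            best_net, best_kept, best_root = net, kept, root
    kept = best_kept
    kept_edges = tuple(sorted(_ekey(u, v) for (u, v) in tree.edges
                              if u in kept and v in kept))
    return Tree(nodes=frozenset(kept), edges=kept_edges)


def _best_edge_subtree(tree: Tree, prizes: dict, costs: dict) -> tuple:
    """Best-net subtree of ``tree`` containing at least one edge.

    Like strong pruning, but when the unconstrained DP collapses to a lone
    node the least-bad child branch is kept, so the result always has >= 2
    nodes (forests are edge sets; a singleton is not a tree).  Returns
    (net, Tree); net may be lower than the unconstrained optimum.
    """
    adj = _adjacency(tree.nodes, tree.edges, costs)
    pmap = {v: float(prizes.get(v, 0.0)) for v in tree.nodes}
    best_net, best_kept = None, None
    for root in sorted(tree.nodes, key=repr):
        net, keep_children = _prune_dp(root, adj, pmap)
        kept = _expand_kept(root, keep_children)
        root_net = net[root]
        if len(kept) < 2:
            if not adj[root]:
                continue
            # force the least-bad branch so the subtree keeps an edge
            w, c = min(adj[root], key=lambda wc: (-(net[wc[0]] - wc[1]), repr(wc[0])))
            root_net = net[root] + (net[w] - c)
            kept = {root} | _expand_kept(w, keep_children)
        if best_net is None or root_net > best_net + _TOL:
            best_net, best_kept = root_net, kept
    kept_edges = tuple(sorted(_ekey(u, v) for (u, v) in tree.edges
                              if u in best_kept and v in best_kept))
    return best_net, Tree(nodes=frozenset(best_kept), edges=kept_edges)


# ---------------------------------------------------------------------------
# primal-dual heuristic

def solve_pcsf(instance: PCSTInstance, omega: float | None = None,
               pruning: str = "strong") -> SteinerForest:
    """Goemans-Williamson-style moat growth with a dummy root, then pruning.

    The instance is augmented with a dummy root joined to every
    positive-prize node ``v`` at cost ``omega + min_cost(v)`` (the cheapest
    edge incident to ``v``): since a tree must contain at least one edge,
    that sum is the true minimum cost of opening a tree at ``v``, and
    pricing the root edges below it would tear profitable clusters into
    singletons that no forest may contain.  Active clusters grow moats at
    unit rate; an inter-cluster edge going tight merges the clusters, a
    cluster exhausting its prize deactivates, and the root's cluster is
    never active.  Removing the root edges from the merge forest yields
    candidate trees; each is strong-pruned (constrained to keep an edge)
    and kept only if its net collected prize strictly exceeds ``omega``.
    Fully deterministic: nodes are processed in sorted order and event ties
    resolve by (time, kind, index).
    """
    if pruning not in ("strong", "none"):
        raise ValueError(f"unknown pruning {pruning!r}")
    omega = instance.omega if omega is None else float(omega)
    if omega <= 0:
        raise ValueError("omega must be positive")

    nodes = instance.nodes
    n = len(nodes)
    ROOT = n
    idx = {v: i for i, v in enumerate(nodes)}
    prizes = [instance.prize(v) for v in nodes]

    edge_list = [(idx[u], idx[v], c) for (u, v), c in sorted(
        instance.edges.items(), key=lambda kv: kv[0])]
    min_cost = [float("inf")] * n
    for (u, v, c) in edge_list:
        min_cost[u] = min(min_cost[u], c)
        min_cost[v] = min(min_cost[v], c)
    for i in range(n):
        # isolated nodes can never join a tree: no root edge for them
        if prizes[i] > 0 and min_cost[i] < float("inf"):
            edge_list.append((i, ROOT, omega + min_cost[i]))

    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    surplus = prizes + [0.0]
    active = [p > _TOL for p in prizes] + [False]
    has_root = [False] * n + [True]
    slack = [c for (_, _, c) in edge_list]
    merge_edges: list[int] = []

    max_iter = 4 * (n + len(edge_list) + 2)
    for _ in range(max_iter):
        roots = {find(i) for i in range(n + 1)}
        if not any(active[r] for r in roots):
            break
        # candidate events: (time, kind, index); kind 0 = edge, 1 = deactivate
        best = None
        for ei, (u, v, _) in enumerate(edge_list):
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            rate = int(active[ru]) + int(active[rv])
            if rate == 0:
                continue
            t = slack[ei] / rate
            cand = (t, 0, ei)
            if best is None or cand < best:
                best = cand
        for r in sorted(roots):
            if active[r]:
                cand = (surplus[r], 1, r)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        dt, kind, which = best
        dt = max(dt, 0.0)
        # advance time
        for ei, (u, v, _) in enumerate(edge_list):
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            rate = int(active[ru]) + int(active[rv])
            if rate:
                slack[ei] -= dt * rate
        for r in roots:
            if active[r]:
                surplus[r] -= dt
        if kind == 0:
            u, v, _ = edge_list[which]
            ru, rv = find(u), find(v)
            merge_edges.append(which)
            parent[ru] = rv
            merged = find(rv)
            s = surplus[ru] + surplus[rv]
            hr = has_root[ru] or has_root[rv]
            surplus[merged] = s
            has_root[merged] = hr
            active[merged] = (not hr) and s > _TOL
        else:
            active[which] = False
            surplus[which] = 0.0

    # candidate trees: components of the merge forest, root edges removed
    import networkx as nx

    g = nx.Graph()
    for ei in merge_edges:
        u, v, _ = edge_list[ei]
        if u == ROOT or v == ROOT:
            continue
        g.add_edge(nodes[u], nodes[v])

    trees = []
    for comp in nx.connected_components(g):
        comp_edges = tuple(sorted(_ekey(u, v) for (u, v) in g.subgraph(comp).edges))
        tree = Tree(nodes=frozenset(comp), edges=comp_edges)
        if pruning == "strong":
            net, tree = _best_edge_subtree(tree, instance.prizes, instance.edges)
        else:
            net = (sum(instance.prize(v) for v in tree.nodes)
                   - sum(instance.edges[e] for e in tree.edges))
        if len(tree.nodes) >= 2 and net > omega + _TOL:
            trees.append(tree)
    trees.sort(key=lambda t: sorted(t.nodes, key=repr))
    return _make_forest(instance, trees, {
        "solver": "gw", "omega": omega, "pruning": pruning})


# ---------------------------------------------------------------------------
# i/o

def _node_fields(v):
    if isinstance(v, tuple) and len(v) == 2:
        return str(v[0]), str(v[1])
    return str(v), ""


def write_instance(instance: PCSTInstance, prefix) -> dict[str, Path]:
    """Dump as TSV node table (gene, layer, prize) + edge table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nrows = []
    for v in instance.nodes:
        gene, layer = _node_fields(v)
        nrows.append({"gene": gene, "layer": layer, "prize": instance.prize(v)})
    npath = Path(str(prefix) + ".nodes.tsv")
    pd.DataFrame(nrows, columns=["gene", "layer", "prize"]).to_csv(
        npath, sep="\t", index=False, float_format="%.17g")
    erows = []
    for (u, v), c in sorted(instance.edges.items(), key=lambda kv: kv[0]):
        ug, ul = _node_fields(u)
        vg, vl = _node_fields(v)
        erows.append({"u_gene": ug, "u_layer": ul, "v_gene": vg, "v_layer": vl,
                      "cost": c, "kind": "edge"})
    epath = Path(str(prefix) + ".edges.tsv")
    pd.DataFrame(erows, columns=["u_gene", "u_layer", "v_gene", "v_layer",
                                 "cost", "kind"]).to_csv(
        epath, sep="\t", index=False, float_format="%.17g")
    return {"nodes": npath, "edges": epath}


def read_instance(prefix, omega: float = DEFAULT_OMEGA) -> PCSTInstance:
    prefix = Path(prefix)
    nodes_df = pd.read_csv(Path(str(prefix) + ".nodes.tsv"), sep="\t",
                           keep_default_na=False)
    edges_df = pd.read_csv(Path(str(prefix) + ".edges.tsv"), sep="\t",
                           keep_default_na=False)

    def mk(gene, layer):
        return (gene, layer) if layer else gene

    nodes, prizes = [], {}
    for r in nodes_df.itertuples(index=False):
        v = mk(r.gene, r.layer)
        nodes.append(v)
        if float(r.prize) > 0:
            prizes[v] = float(r.prize)
    edges = {}
    for r in edges_df.itertuples(index=False):
        u, v = mk(r.u_gene, r.u_layer), mk(r.v_gene, r.v_layer)
        edges[_ekey(u, v)] = float(r.cost)
    return PCSTInstance(nodes=nodes, edges=edges, prizes=prizes, omega=omega)


def write_forest(forest: SteinerForest, instance: PCSTInstance, prefix) -> dict[str, Path]:
    """Forest edges in the instance edge-table dialect + a JSON run manifest."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for ti, t in enumerate(forest.trees):
        for (u, v) in t.edges:
            ug, ul = _node_fields(u)
            vg, vl = _node_fields(v)
            rows.append({"tree": ti, "u_gene": ug, "u_layer": ul,
                         "v_gene": vg, "v_layer": vl,
                         "cost": instance.edges[_ekey(u, v)]})
    epath = Path(str(prefix) + ".forest.tsv")
    pd.DataFrame(rows, columns=["tree", "u_gene", "u_layer", "v_gene", "v_layer",
                                "cost"]).to_csv(
        epath, sep="\t", index=False, float_format="%.17g")
    manifest = {
        "objective": forest.objective,
        "objective_with_root": forest.objective_with_root(instance),
        "n_trees": forest.n_trees,
        "n_nodes": len(forest.node_set()),
        "params": forest.params,
    }
    mpath = Path(str(prefix) + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"forest": epath, "manifest": mpath}
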