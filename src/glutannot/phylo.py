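"""Phylogeny of HMW-GS genes: NJ tree with bootstrap and median-joining network.

The phylogenetically informative region of a Glu-1 gene is the conserved
part: the 5'-flanking promoter followed by the coding sequence of the signal
peptide and the N-terminal domain (the repetitive domain is too homoplastic
to align reliably).  From a multiple alignment of such regions this module
computes pairwise p-distances (proportion of differing sites, gaps excluded
pairwise), builds a Saitou-Nei neighbor-joining tree with site-resampling
bootstrap support, and builds a Bandelt median-joining haplotype network.

The distance model is the p-distance (optionally Jukes-Cantor corrected).
On the closely related sequences this pipeline targets, tree topology is
insensitive to the substitution-model choice; that robustness is itself
property-tested on synthetic families.

Determinism: NJ breaks minimum-Q ties lexicographically by the smallest leaf
id under each cluster; bootstrap uses an explicit seed; the median-joining
construction is purely combinatorial.
"""
from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .anatomy import DomainPartition, MatureSubunit
from .seq_io import GeneRecord

GAP = "-"


@dataclass
class PhyloRegion:
    id: str
    sequence: str
    has_promoter: bool = True


def extract_phylo_region(
    gene: GeneRecord, mature: MatureSubunit, partition: DomainPartition
) -> PhyloRegion:
    """Concatenate promoter + signal-peptide CDS + N-terminal-domain CDS.

    A gene without a promoter yields a CDS-only region flagged with
    ``has_promoter=False``.
    """
    signal_len = len(mature.signal_peptide)
    nterm_len = DomainPartition.span_length(partition.n_terminal)
    cds = gene.orf_dna[: 3 * (signal_len + nterm_len)]
    promoter = gene.promoter_dna or ""
    return PhyloRegion(gene.id, promoter + cds, has_promoter=bool(gene.promoter_dna))


# ---------------------------------------------------------------------------
# Distances


class ZeroComparableSitesError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def _as_items(aligned) -> list[tuple[str, str]]:
    if isinstance(aligned, dict):
        return list(aligned.items())
    return [(i, s) for i, s in aligned]


def p_distance_matrix(aligned, gap_policy: str = "pairwise", model: str = "p") -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gapped sites.

    ``aligned`` is a dict id->sequence or a list of (id, sequence) of equal
    lengths.  ``model`` is ``"p"`` or ``"jc"`` (Jukes-Cantor correction).  A
    pair with zero comparable sites raises, naming the pair.
    """
    if gap_policy != "pairwise":
        raise ValueError("only pairwise gap deletion is implemented")
    items = _as_items(aligned)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    ids = [i for i, _ in items]
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    arr = np.array([list(s.upper()) for _, s in items])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(valid.sum())
            if m == 0:
                raise ZeroComparableSitesError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((arr[i][valid] != arr[j][valid]).sum()) / m
            if model == "jc":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {ids[i]!r} and {ids[j]!r} "
                        "out of Jukes-Cantor range"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None, children=None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = children or []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode
    support: dict = field(default_factory=dict)   # bipartition -> percent

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, canonicalized as a frozenset of the two sides."""
        all_leaves = frozenset(self.leaves())
        out = set()

        def visit(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(frozenset({side, all_leaves - side}))
                visit(child)

        visit(self.root)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        return path_distance(self, a, b)


def _leaf_depths(tree: Tree) -> tuple[dict[str, float], dict[str, list]]:
    """Distance from root to each leaf, and the node path root->leaf."""
    depths: dict[str, float] = {}
    paths: dict[str, list] = {}

    def visit(node: TreeNode, acc: float, path: list):
        if not node.children:
            depths[node.name] = acc
            paths[node.name] = path + [id(node)]
            return
        for child, length in node.children:
            visit(child, acc + length, path + [id(node)])

    visit(tree.root, 0.0, [])
    return depths, paths


def path_distance(tree: Tree, a: str, b: str) -> float:
    depths, paths = _leaf_depths(tree)
    if a not in depths or b not in depths:
        raise KeyError(f"leaf not in tree: {a!r} or {b!r}")
    # depth of the last common node on the two root->leaf paths
    node_depth: dict[int, float] = {}

    def visit(node: TreeNode, acc: float):
        node_depth[id(node)] = acc
        for child, length in node.children:
            visit(child, acc + length)

    visit(tree.root, 0.0)
    lca_depth = 0.0
    for na, nb in zip(paths[a], paths[b]):
        if na == nb:
            lca_depth = node_depth[na]
        else:
            break
    return depths[a] + depths[b] - 2 * lca_depth


def newick(tree: Tree, include_support: bool = False) -> str:
    all_leaves = frozenset(tree.leaves())

    def label(node: TreeNode) -> str:
        if not include_support or not tree.support:
            return ""
        side = frozenset(node.leaves())
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = frozenset({side, all_leaves - side})
            if key in tree.support:
                return f"{tree.support[key]:.0f}"
        return ""

    def fmt(node: TreeNode, length: float | None) -> str:
        if not node.children:
            core = node.name
        else:
            inner = ",".join(fmt(c, l) for c, l in node.children)
            core = f"({inner}){label(node)}"
        return core if length is None else f"{core}:{length:.6g}"

    return fmt(tree.root, None) + ";"


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Minimum-Q ties are broken lexicographically by the smallest leaf id under
    each of the two clusters.  Negative branch lengths are clamped to zero
    with the deficit transferred to the sibling branch, preserving the
    pairwise path length.
    """
    n0 = len(D.ids)
    if n0 < 3:
        warnings.warn(f"neighbor_joining: only {n0} taxa; returning trivial tree")
        if n0 == 1:
            return Tree(TreeNode(D.ids[0]))
        d = float(D.d[0, 1])
        root = TreeNode(children=[(TreeNode(D.ids[0]), d / 2), (TreeNode(D.ids[1]), d / 2)])
        return Tree(root)

    nodes: dict[int, TreeNode] = {i: TreeNode(name) for i, name in enumerate(D.ids)}
    keys: dict[int, str] = {i: name for i, name in enumerate(D.ids)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(D.d[i, j]) for i in range(n0) for j in range(i + 1, n0)
    }
    active = set(range(n0))
    next_idx = n0

    def d(i, j):
        return dist[frozenset((i, j))]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        pairs = sorted(
            (tuple(sorted((i, j), key=lambda x: keys[x])) for i, j in combinations(active, 2)),
            key=lambda p: (keys[p[0]], keys[p[1]]),
        )
        best = None
        for i, j in pairs:
            q = (n - 2) * d(i, j) - r[i] - r[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        u = next_idx
        next_idx += 1
        nodes[u] = new
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((u, k))] = 0.5 * (d(i, k) + d(j, k) - dij)
        active.discard(i)
        active.discard(j)
        active.add(u)

    a, b, c = sorted(active, key=lambda x: keys[x])
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root)


def bootstrap_support(aligned, n_reps: int, seed: int, model: str = "p") -> Tree:
    """NJ tree with site-resampling bootstrap support on internal edges.

    Support is the percentage of replicate NJ trees (columns resampled with
    replacement, seeded) containing each internal bipartition of the main
    tree.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    items = _as_items(aligned)
    ids = [i for i, _ in items]
    tree = neighbor_joining(p_distance_matrix(items, model=model))
    arr = np.array([list(s.upper()) for _, s in items])
    ncols = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        sub = arr[:, cols]
        rep_aligned = [(ids[k], "".join(sub[k])) for k in range(len(ids))]
        rep_tree = neighbor_joining(p_distance_matrix(rep_aligned, model=model))
        counts.update(rep_tree.bipartitions())
    tree.support = {bp: 100.0 * counts[bp] / n_reps for bp in tree.bipartitions()}
    return tree


# ---------------------------------------------------------------------------
# Median-joining network


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                       # nodes keyed by variable-site strings
    node_info: dict                       # node -> {"type", "members"}
    variable_sites: list[int]             # 1-based alignment columns
    params: dict

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph) if len(self.graph) else True


def _variable_sites(seqs: list[str]) -> list[int]:
    ncols = len(seqs[0])
    return [i for i in range(ncols) if len({s[i] for s in seqs}) > 1]


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Minimum-spanning network over haplotype strings (Hamming distances).

    Distance classes are processed in ascending order; a link of length d in
    [delta, delta+epsilon] is kept if its endpoints are in different
    components of the graph built from strictly smaller classes.
    """
    from .repeats import hamming

    pairs = {
        (u, v): hamming(u, v) for u, v in combinations(sorted(nodes), 2)
    }
    parent = {v: v for v in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for delta in sorted(set(pairs.values())):
        comp_before = {v: find(v) for v in nodes}
        added = []
        for (u, v), duv in sorted(pairs.items()):
            if delta <= duv <= delta + epsilon and comp_before[u] != comp_before[v]:
                edges.append((u, v, duv))
                added.append((u, v))
        for u, v in added:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return edges


def _mst_length(nodes: list[str]) -> int:
    from .repeats import hamming

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in combinations(sorted(nodes), 2):
        g.add_edge(u, v, weight=hamming(u, v))
    return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)))


def _majority(u: str, v: str, w: str) -> str:
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(b)      # all three differ: keep the hub's state
    return "".join(out)


def median_joining_network(
    haplotypes, epsilon: int = 0, weights: float = 10.0, max_rounds: int = 20
) -> HaplotypeNetwork:
    """Bandelt median-joining network of aligned DNA haplotypes.

    ``haplotypes`` is a dict id->sequence or list of (id, sequence), equal
    lengths.  Invariant sites are dropped; identical haplotypes collapse into
    one node.  Median (Steiner) vectors of connected triplets are added
    iteratively; a median is retained only if removing it would lengthen the
    minimum spanning tree over the remaining nodes.  ``weights`` is the
    uniform per-site weight (recorded; with uniform weights it does not
    change the topology).  Edge attribute ``mutations`` is the number of
    differing variable sites.
    """
    items = _as_items(haplotypes)
    if not items:
        raise ValueError("no haplotypes given")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("haplotypes must have equal aligned lengths")
    seqs = [s.upper() for _, s in items]
    var_sites = _variable_sites(seqs)
    condensed = {hid: "".join(s[i] for i in var_sites) for hid, s in items}

    members: dict[str, list[str]] = {}
    for hid, cs in condensed.items():
        members.setdefault(cs, []).append(hid)
    observed = sorted(members)

    params = {"epsilon": epsilon, "weights": weights}
    if len(observed) == 1:
        g = nx.Graph()
        g.add_node(observed[0])
        info = {observed[0]: {"type": "observed", "members": members[observed[0]]}}
        return HaplotypeNetwork(g, info, [i + 1 for i in var_sites], params)

    nodes = set(observed)
    for _ in range(max_rounds):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(_msn_edges(sorted(nodes), epsilon))
        new = set()
        for v in sorted(g.nodes):
            for u, w in combinations(sorted(g.neighbors(v)), 2):
                m = _majority(u, v, w)
                if m not in nodes:
                    new.add(m)
        if not new:
            break
        nodes |= new

    # prune medians that do not shorten the spanning structure
    changed = True
    while changed:
        changed = False
        base = _mst_length(sorted(nodes))
        for m in sorted(nodes - set(observed)):
            if _mst_length(sorted(nodes - {m})) <= base:
                nodes.discard(m)
                changed = True
                break

    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for u, v, duv in _msn_edges(sorted(nodes), epsilon):
        g.add_edge(u, v, mutations=duv)
    info = {
        n: {
            "type": "observed" if n in members else "median",
            "members": members.get(n, []),
        }
        for n in g.nodes
    }
    return HaplotypeNetwork(g, info, [i + 1 for i in var_sites], params)
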