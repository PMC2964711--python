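"""Reduced median networks and most-parsimonious tree extraction.

Haplotypes are recoded as binary state vectors (0 = reference state), the
median closure of the observed vectors is computed (for binary characters
the closed set contains the latent ancestral vectors of every
most-parsimonious tree), poorly supported conflict resolutions are reduced
away under a frequency criterion with reduction parameter ``r``, and a
most-parsimonious tree is extracted as a minimum-weight Steiner tree of the
network, rooted through an outgroup state vector.

Determinism: sites are ordered ascending by (position, derived state), taxa
lexicographically; all iteration follows those orders, so identical inputs
give bit-identical networks and trees.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .hvs_io import Haplotype, MutationCall
from .reference import ReferenceAnnotation

logger = logging.getLogger(__name__)


class AmbiguousRootError(ValueError):
    """The outgroup attaches equally well to several nodes."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "outgroup equally attachable to nodes "
            f"{sorted(candidates)}; supply a root override"
        )


@dataclass(frozen=True)
class Site:
    """One binary character: a derived state at a reference position."""

    position: int
    derived: str
    event: str
    call: MutationCall
    weight: float = 1.0

    @property
    def label(self) -> str:
        suffix = {"transition": "", "deletion": "d", "insertion": f"i{self.derived}"}
        return f"{self.position}{suffix.get(self.event, self.derived)}"


@dataclass
class BinaryMatrix:
    """Binary recoding of haplotypes: rows unique vectors, 0 = reference."""

    taxa: list[str]                 # one id per unique row
    members: list[list[str]]        # original ids collapsed into each row
    multiplicity: np.ndarray        # summed counts per unique row
    sites: list[Site]               # segregating characters (columns)
    states: np.ndarray              # unique-rows x sites, uint8
    basal_sites: list[Site] = field(default_factory=list)  # shared by all rows

    @property
    def n_individuals(self) -> int:
        return int(self.multiplicity.sum())


def encode(haplotypes: list[Haplotype], ref: ReferenceAnnotation,
           site_weights: dict[int, float] | None = None) -> BinaryMatrix:
    """Binary-recode haplotypes (HVS-I + typed HVS-II + coding calls).

    One column per observed (position, derived state); a triallelic position
    therefore yields two columns sharing the position tag.  Columns carried
    by every row are moved to ``basal_sites`` (they belong on the stem edge
    and are not segregating within the sample).  Identical rows are collapsed
    with multiplicities summed.  Calls at excluded sites never appear.
    """
    site_weights = site_weights or {}

    def active_calls(h: Haplotype) -> list[MutationCall]:
        calls = list(h.hvs1) + (list(h.hvs2) if h.hvs2_typed else []) + list(h.coding)
        return [c for c in calls
                if not c.is_back_mutation and c.position not in ref.excluded_sites]

    keys: dict[tuple, MutationCall] = {}
    for h in haplotypes:
        for c in active_calls(h):
            keys.setdefault((c.position, c.event, c.derived), c)
    ordered = sorted(keys)
    by_pos: dict[int, list] = {}
    for k in ordered:
        by_pos.setdefault(k[0], []).append(k)
    for pos, ks in by_pos.items():
        if len([k for k in ks if k[1] != "insertion"]) > 1:
            logger.info("multi-allelic position %d split into %d binary characters",
                        pos, len(ks))
    sites = [
        Site(position=k[0], derived=k[2], event=k[1], call=keys[k],
             weight=float(site_weights.get(k[0], 1.0)))
        for k in ordered
    ]
    col = {k: j for j, k in enumerate(ordered)}
    mat = np.zeros((len(haplotypes), len(sites)), dtype=np.uint8)
    for i, h in enumerate(haplotypes):
        for c in active_calls(h):
            mat[i, col[(c.position, c.event, c.derived)]] = 1
    # collapse duplicate rows (taxa sorted for determinism)
    order = sorted(range(len(haplotypes)), key=lambda i: haplotypes[i].id)
    rows: dict[bytes, int] = {}
    taxa, members, mult, vecs = [], [], [], []
    for i in order:
        key = mat[i].tobytes()
        if key in rows:
            j = rows[key]
            members[j].append(haplotypes[i].id)
            mult[j] += haplotypes[i].count
        else:
            rows[key] = len(taxa)
            taxa.append(haplotypes[i].id)
            members.append([haplotypes[i].id])
            mult.append(haplotypes[i].count)
            vecs.append(mat[i])
    states = np.array(vecs, dtype=np.uint8) if vecs else np.zeros((0, len(sites)), np.uint8)
    # basal (constant-1) columns out, keep segregating ones
    if len(states):
        const = states.all(axis=0)
    else:
        const = np.zeros(len(sites), dtype=bool)
    basal = [s for s, c in zip(sites, const) if c]
    keep = [j for j, c in enumerate(const) if not c]
    return BinaryMatrix(
        taxa=taxa,
        members=members,
        multiplicity=np.array(mult, dtype=int),
        sites=[sites[j] for j in keep],
        states=states[:, keep] if len(states) else states,
        basal_sites=basal,
    )


# ---------------------------------------------------------------------------
# reduced median network


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                  # nodes: bytes keys; edge attr: site index
    matrix: BinaryMatrix
    vectors: dict[bytes, np.ndarray]
    kinds: dict[bytes, str]          # observed | median | latent
    reticulations: list[list[bytes]] = field(default_factory=list)

    def observed_nodes(self) -> list[bytes]:
        return [n for n, k in self.kinds.items() if k == "observed"]

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        names = _node_names(self)
        for n in self.graph.nodes:
            g.add_node(names[n], kind=self.kinds[n],
                       vector="".join(map(str, self.vectors[n])))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(names[u], names[v], site=self.matrix.sites[d["site"]].label)
        nx.write_graphml(g, path)


def _node_names(net: HaplotypeNetwork) -> dict[bytes, str]:
    names = {}
    taxon_by_vec = {
        net.matrix.states[i].tobytes(): net.matrix.taxa[i]
        for i in range(len(net.matrix.taxa))
    }
    counter = itertools.count(1)
    for n in sorted(net.graph.nodes):
        names[n] = taxon_by_vec.get(n) or f"mv{next(counter)}"
    return names


_MAX_CLOSURE = 4000


def _unique_rows(arr: np.ndarray) -> np.ndarray:
    """Distinct rows of a uint8 matrix (lexsort on 64-bit words; much faster
    than np.unique(axis=0) for short wide-byte rows)."""
    if len(arr) == 0:
        return arr
    pad = (-arr.shape[1]) % 8
    if pad:
        padded = np.zeros((len(arr), arr.shape[1] + pad), np.uint8)
        padded[:, : arr.shape[1]] = arr
    else:
        padded = np.ascontiguousarray(arr)
    words = padded.view(np.uint64).reshape(len(arr), -1)
    order = np.lexsort(words.T[::-1])
    sw = words[order]
    keep = np.ones(len(sw), dtype=bool)
    keep[1:] = (sw[1:] != sw[:-1]).any(axis=1)
    return arr[order[keep]]


def _median_closure(vectors: list[np.ndarray]):
    """Close the observed vectors under triple-wise majority (median).

    Works on bit-packed rows: med(a, b, c) = (a & b) | (c & (a | b)).  Each
    pass only pairs the whole pool against the newly added frontier, which
    covers every triple containing at least one new vector.
    """
    n_sites = len(vectors[0])
    raw = np.array(vectors, dtype=np.uint8)
    packed = np.packbits(raw, axis=1)
    # dedupe observed
    seen: dict[bytes, int] = {}
    rows = []
    for row in packed:
        k = row.tobytes()
        if k not in seen:
            seen[k] = len(rows)
            rows.append(row)
    all_rows = np.array(rows)
    observed_keys = set(seen)
    frontier = all_rows
    while True:
        v = len(all_rows)
        if v > _MAX_CLOSURE:
            raise ValueError(
                f"median closure exceeded {_MAX_CLOSURE} vectors; "
                "reduce the data or down-weight hypervariable sites"
            )
        iu, ju = np.triu_indices(v, k=1)
        pand = all_rows[iu] & all_rows[ju]
        por = all_rows[iu] | all_rows[ju]
        new_rows = []
        for n in frontier:
            meds = pand | (n & por)
            for row in _unique_rows(meds):
                k = row.tobytes()
                if k not in seen:
                    seen[k] = -1
                    new_rows.append(row)
        if not new_rows:
            break
        frontier = np.array(new_rows)
        all_rows = np.vstack([all_rows, frontier])
    pool: dict[bytes, np.ndarray] = {}
    kinds: dict[bytes, str] = {}
    for row in all_rows:
        vec = np.unpackbits(row)[:n_sites]
        key = vec.tobytes()
        pool[key] = vec
        kinds[key] = "observed" if row.tobytes() in observed_keys else "median"
    return kinds, pool


def _between(w, u, v) -> bool:
    """True if w lies strictly within the coordinate interval [u, v]."""
    agree = u == v
    if np.any(w[agree] != u[agree]):
        return False
    return not np.array_equal(w, u) and not np.array_equal(w, v)


def _geodesic_graph(pool: dict[bytes, np.ndarray], kinds: dict[bytes, str],
                    sites: list[Site]) -> nx.Graph:
    """Connect closure vectors whose interval is empty; subdivide multi-site
    links with latent intermediate vectors (sites applied in ascending
    order from the lexicographically smaller endpoint)."""
    g = nx.Graph()
    keys = sorted(pool)
    arrs = np.array([pool[k] for k in keys], dtype=np.uint8)
    packed = np.packbits(arrs, axis=1)
    for k in keys:
        g.add_node(k)
    n = len(keys)
    for i in range(n):
        xor_i = packed ^ packed[i]
        for j in range(i + 1, n):
            u, v = arrs[i], arrs[j]
            # any third node agreeing with u (and v) wherever u == v lies
            # strictly between them
            mask = ~(packed[i] ^ packed[j])
            cand = ~np.bitwise_or.reduce(xor_i & mask, axis=1).astype(bool)
            cand[i] = cand[j] = False
            if cand.any():
                continue
            diff = np.nonzero(u != v)[0]
            if len(diff) == 0:
                continue
            if len(diff) == 1:
                g.add_edge(keys[i], keys[j], site=int(diff[0]))
            else:
                lo, hi = (keys[i], keys[j]) if keys[i] < keys[j] else (keys[j], keys[i])
                cur = pool[lo].copy()
                prev = lo
                for s in diff[:-1]:
                    cur = cur.copy()
                    cur[s] ^= 1
                    key = cur.tobytes()
                    if key not in pool:
                        pool[key] = cur
                        kinds[key] = "latent"
                        g.add_node(key)
                    g.add_edge(prev, key, site=int(s))
                    prev = key
                g.add_edge(prev, hi, site=int(diff[-1]))
    return g


def _incompatible_pairs(matrix: BinaryMatrix) -> list[tuple[int, int]]:
    """Character pairs showing all four gametes among observed rows."""
    out = []
    s = matrix.states
    for i in range(s.shape[1]):
        for j in range(i + 1, s.shape[1]):
            pat = {(int(a), int(b)) for a, b in zip(s[:, i], s[:, j])}
            # reference state 00 is implied by the outgroup
            pat.add((0, 0))
            if len(pat) == 4:
                out.append((i, j))
    return out


def _support(matrix: BinaryMatrix, j: int) -> float:
    """Multiplicity-weighted support of character j's derived state."""
    return float((matrix.multiplicity * matrix.states[:, j]).sum() * matrix.sites[j].weight)


def reduced_median(matrix: BinaryMatrix, r: float = 2.0) -> HaplotypeNetwork:
    """Build the reduced median network of a binary matrix.

    The full median closure is computed first; for each incompatible
    character pair whose support ratio exceeds ``r`` the less-supported
    resolution is reduced: latent degree-2 corners of the conflict cycles
    are removed (weaker-supported corner first) while the network stays
    connected.  The network always contains every observed haplotype and,
    through the closure, at least one most-parsimonious tree as a spanning
    subgraph.
    """
    if r < 1:
        raise ValueError("reduction parameter r must be >= 1")
    if matrix.states.size == 0 and not matrix.taxa:
        return HaplotypeNetwork(nx.Graph(), matrix, {}, {})
    vectors = [matrix.states[i] for i in range(len(matrix.taxa))]
    if matrix.states.shape[1] == 0:
        key = np.zeros(0, np.uint8).tobytes()
        g = nx.Graph()
        g.add_node(key)
        return HaplotypeNetwork(g, matrix, {key: np.zeros(0, np.uint8)},
                                {key: "observed"})
    kinds, pool = _median_closure(vectors)
    g = _geodesic_graph(pool, kinds, matrix.sites)
    _reduce_conflicts(g, pool, kinds, matrix, r)
    _prune_dangling(g, kinds)
    retics = [c for c in nx.cycle_basis(g)]
    return HaplotypeNetwork(g, matrix, pool, {n: kinds[n] for n in g.nodes},
                            reticulations=retics)


def _reduce_conflicts(g, pool, kinds, matrix, r) -> None:
    for i, j in _incompatible_pairs(matrix):
        si, sj = _support(matrix, i), _support(matrix, j)
        if min(si, sj) == 0 or max(si, sj) / min(si, sj) <= r:
            continue
        # candidate corners: latent/median degree-2 nodes incident to one
        # edge of each conflicting character
        corners = []
        for n in list(g.nodes):
            if kinds[n] == "observed" or g.degree(n) != 2:
                continue
            labels = sorted(d["site"] for _, _, d in g.edges(n, data=True))
            if labels == sorted((i, j)):
                neigh_mult = 0
                for nb in g.neighbors(n):
                    row = _row_of(matrix, nb)
                    if row is not None:
                        neigh_mult += int(matrix.multiplicity[row])
                corners.append((neigh_mult, n))
        for _, n in sorted(corners):
            if n not in g or g.degree(n) != 2:
                continue
            nbrs = list(g.neighbors(n))
            h = g.copy()
            h.remove_node(n)
            if nx.has_path(h, nbrs[0], nbrs[1]):
                g.remove_node(n)
                logger.info("reduced weak conflict corner between "
                            "characters %d and %d", i, j)
                break


def _row_of(matrix: BinaryMatrix, key: bytes) -> int | None:
    for idx in range(len(matrix.taxa)):
        if matrix.states[idx].tobytes() == key:
            return idx
    return None


def _prune_dangling(g: nx.Graph, kinds) -> None:
    """Inferred nodes must join >= 2 neighbours; trim inferred leaves."""
    while True:
        leaves = [n for n in g.nodes if kinds[n] != "observed" and g.degree(n) <= 1]
        if not leaves:
            return
        g.remove_nodes_from(leaves)


# ---------------------------------------------------------------------------
# most-parsimonious tree extraction


class TreeNode:
    """A node of a rooted mutation tree."""

    def __init__(self, name: str, vector=None, multiplicity: int = 0):
        self.name = name
        self.vector = vector
        self.multiplicity = multiplicity
        self.members: list[str] = [name]  # collapsed identical haplotypes
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.edge: list = []  # mutations on the edge from parent to this node

    def add_child(self, child: "TreeNode", mutations: list) -> "TreeNode":
        child.parent = self
        child.edge = list(mutations)
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def __repr__(self):
        return f"TreeNode({self.name!r}, m={self.multiplicity})"


class MutationTree:
    """Rooted tree whose edges carry the mutations arising on them."""

    def __init__(self, root: TreeNode, basal_mutations: list | None = None):
        self.root = root
        self.basal_mutations = list(basal_mutations or [])

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def find(self, name: str) -> TreeNode:
        for n in self.root.walk():
            if n.name == name or name in n.members:
                return n
        raise KeyError(name)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if not n.children]

    @property
    def n_individuals(self) -> int:
        return sum(n.multiplicity for n in self.root.walk())

    def path_mutations(self, node: TreeNode) -> list:
        out = []
        while node.parent is not None:
            out.extend(node.edge)
            node = node.parent
        return out

    def mrca(self, names: list[str]) -> TreeNode:
        paths = []
        for name in names:
            node = self.find(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        anc = self.root
        for level in zip(*paths):
            if len({id(n) for n in level}) == 1:
                anc = level[0]
            else:
                break
        return anc

    def parsimony_score(self) -> float:
        total = 0.0
        for n in self.root.walk():
            for m in n.edge:
                total += getattr(m, "weight", 1.0)
        return total

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            muts = ",".join(_mut_label(m) for m in node.edge)
            comment = f"[&mutations={muts}]" if muts else ""
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){node.name}{comment}"
            return f"{node.name}{comment}"

        return fmt(self.root) + ";"


def _mut_label(m) -> str:
    if isinstance(m, Site):
        return m.label
    call = m
    suffix = {"transition": "", "deletion": "d",
              "insertion": f"i{call.derived}"}.get(call.event, call.derived)
    return f"{call.position}{suffix}"


def _steiner_tree(g: nx.Graph, terminals: list, weight_of) -> nx.Graph:
    """Exact minimum Steiner tree (Dreyfus–Wagner) for modest terminal sets."""
    terminals = sorted(set(terminals))
    if len(terminals) == 1:
        t = nx.Graph()
        t.add_node(terminals[0])
        return t
    INF = float("inf")
    k = len(terminals)
    if k > 14:
        logger.warning("Steiner extraction with %d terminals uses the "
                       "networkx approximation", k)
        return nx.algorithms.approximation.steiner_tree(
            g, terminals, weight="w", method="mehlhorn")
    # dp[mask][v] = cheapest tree spanning terminal subset `mask` plus v
    dp: list[dict] = [dict() for _ in range(1 << k)]
    back: list[dict] = [dict() for _ in range(1 << k)]
    for i, t in enumerate(terminals):
        dp[1 << i][t] = 0.0
    for mask in range(1, 1 << k):
        d = dp[mask]
        # merge step
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                for v, c1 in dp[sub].items():
                    c2 = dp[other].get(v)
                    if c2 is not None and d.get(v, INF) > c1 + c2:
                        d[v] = c1 + c2
                        back[mask][v] = ("merge", sub, other)
            sub = (sub - 1) & mask
        # grow step: multi-source dijkstra from current labels
        heap = [(c, v) for v, c in d.items()]
        heapq.heapify(heap)
        while heap:
            c, v = heapq.heappop(heap)
            if c > d.get(v, INF):
                continue
            for nb in g.neighbors(v):
                w = weight_of(g[v][nb])
                if d.get(nb, INF) > c + w:
                    d[nb] = c + w
                    back[mask][nb] = ("edge", v)
                    heapq.heappush(heap, (c + w, nb))
    full = (1 << k) - 1
    root = min(dp[full], key=lambda v: (dp[full][v], v))
    tree = nx.Graph()
    stack = [(full, root)]
    while stack:
        mask, v = stack.pop()
        bp = back[mask].get(v)
        if bp is None:
            tree.add_node(v)
            continue
        if bp[0] == "merge":
            stack.append((bp[1], v))
            stack.append((bp[2], v))
        else:
            u = bp[1]
            tree.add_edge(v, u, **g[v][u])
            stack.append((mask, u))
    return tree


def parse_overrides(lines) -> dict:
    """Parse override directives: ``root=<taxon>`` or ``<site label>=force``."""
    out = {"root": None, "force_sites": []}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        if key.strip() == "root":
            out["root"] = val.strip()
        else:
            out["force_sites"].append(key.strip())
    return out


def extract_tree(network: HaplotypeNetwork,
                 outgroup_state: np.ndarray | None = None,
                 overrides: dict | None = None) -> MutationTree:
    """Extract the minimum-weight mutation tree from a network and root it.

    The outgroup (reference) state vector is all-zeros by default.  The tree
    is the minimum Steiner tree of the network over the observed haplotypes
    plus the outgroup attachment node; site weights are respected and ties
    break deterministically (ascending site order).  ``overrides`` may force
    specific homoplasy resolutions (``force_sites``: the labelled edge is
    kept) or name the root attachment (``root=<taxon id>``).
    """
    overrides = overrides or {}
    matrix = network.matrix
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    vectors = network.vectors
    if outgroup_state is None:
        outgroup_state = np.zeros(matrix.states.shape[1], dtype=np.uint8)

    # outgroup attachment: node(s) at minimal Hamming distance
    dists = {
        n: int(np.sum(vectors[n] != outgroup_state)) for n in sorted(g.nodes)
    }
    dmin = min(dists.values())
    candidates = [n for n, d in dists.items() if d == dmin]
    if overrides.get("root"):
        root_key = _find_taxon_node(network, overrides["root"])
    elif len(candidates) > 1:
        names = _node_names(network)
        raise AmbiguousRootError([names[n] for n in candidates])
    else:
        root_key = candidates[0]

    observed = sorted(network.observed_nodes())
    terminals = sorted(set(observed) | {root_key})

    eps = 1e-9
    forced = set()
    for label in overrides.get("force_sites", []):
        for u, v, d in g.edges(data=True):
            s = d.get("site")
            if s is not None and matrix.sites[s].label == label:
                forced.add((u, v))
                terminals.extend([u, v])

    def weight_of(data):
        s = data.get("site")
        return matrix.sites[s].weight if s is not None else 1.0

    # apply forced-edge epsilon weighting through a shallow copy
    if forced:
        g = g.copy()
        for u, v in forced:
            g[u][v]["forced"] = True

        def weight_of(data):  # noqa: F811
            if data.get("forced"):
                return eps
            s = data.get("site")
            return matrix.sites[s].weight if s is not None else 1.0

    if nx.is_tree(g):
        steiner = _paths_union(g, terminals)
    else:
        steiner = _steiner_tree(g, sorted(set(terminals)), weight_of)
    return _build_tree(network, steiner, root_key)


def _find_taxon_node(network: HaplotypeNetwork, taxon: str) -> bytes:
    m = network.matrix
    for i, t in enumerate(m.taxa):
        if t == taxon or taxon in m.members[i]:
            return m.states[i].tobytes()
    raise KeyError(f"unknown root override taxon {taxon!r}")


def _paths_union(g: nx.Graph, terminals: list) -> nx.Graph:
    tree = nx.Graph()
    base = terminals[0]
    for t in terminals[1:]:
        path = nx.shortest_path(g, base, t)
        for u, v in zip(path, path[1:]):
            tree.add_edge(u, v, **g[u][v])
    if not tree.nodes:
        tree.add_node(base)
    return tree


def _build_tree(network: HaplotypeNetwork, steiner: nx.Graph,
                root_key: bytes) -> MutationTree:
    matrix = network.matrix
    names = _node_names(network)
    mult = {matrix.states[i].tobytes(): int(matrix.multiplicity[i])
            for i in range(len(matrix.taxa))}
    membership = {matrix.states[i].tobytes(): list(matrix.members[i])
                  for i in range(len(matrix.taxa))}
    root = TreeNode(names[root_key], vector=network.vectors[root_key],
                    multiplicity=mult.get(root_key, 0))
    root.members = membership.get(root_key, [root.name])
    seen = {root_key}

    def grow(node: TreeNode, key: bytes):
        for nb in sorted(steiner.neighbors(key)):
            if nb in seen:
                continue
            seen.add(nb)
            sites = [matrix.sites[steiner[key][nb]["site"]]]
            # collapse chains of unobserved degree-2 nodes
            cur, prev = nb, key
            while (network.kinds.get(cur) != "observed"
                   and steiner.degree(cur) == 2):
                nxt = [x for x in steiner.neighbors(cur) if x != prev][0]
                sites.append(matrix.sites[steiner[cur][nxt]["site"]])
                seen.add(nxt)
                prev, cur = cur, nxt
            child = TreeNode(names[cur], vector=network.vectors[cur],
                             multiplicity=mult.get(cur, 0))
            child.members = membership.get(cur, [child.name])
            node.add_child(child, sites)
            grow(child, cur)

    grow(root, root_key)
    out = MutationTree(root, basal_mutations=list(matrix.basal_sites))
    out.matrix = matrix
    return out


def reconstruct_vector(tree: MutationTree, node: TreeNode) -> np.ndarray:
    """Root state + edge mutations along the path; must equal node.vector."""
    matrix: BinaryMatrix = tree.matrix
    index = {s: i for i, s in enumerate(matrix.sites)}
    vec = tree.root.vector.copy()
    path = []
    n = node
    while n.parent is not None:
        path.append(n)
        n = n.parent
    for n in reversed(path):
        for site in n.edge:
            vec = vec.copy()
            vec[index[site]] ^= 1
    return vec
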