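"""Readers/writers and the shared coordinate conventions.

This module owns the three interchange formats used throughout the package
(aligned FASTA, Newick, jplace v3) and the two core containers:

``ReferenceAlignment``
    The column-aligned reference sequences.  All coordinates in the package
    are 0-based column indices into this alignment.

``Topology``
    An unrooted binary tree stored in a rooted-array form (one internal node
    acts as a trifurcating "root" purely for traversal).  Every edge gets a
    stable integer ``edge_num`` assigned in preorder, which is a pure
    function of the input Newick string; jplace output uses these numbers.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReferenceAlignment",
    "AlignedQuery",
    "Topology",
    "AlignmentFormatError",
    "TreeFormatError",
    "read_fasta_alignment",
    "read_query_fasta",
    "read_newick",
    "write_jplace",
    "read_jplace",
    "write_placement_tsv",
]

JPLACE_FIELDS = [
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
]

# nucleotide byte codes used everywhere: A,C,G,T -> 0..3, anything else
# (gaps, N, IUPAC ambiguity) -> 4 and is excluded by pairwise deletion
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
MISSING = np.uint8(4)


class AlignmentFormatError(ValueError):
    pass


class TreeFormatError(ValueError):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class ReferenceAlignment:
    """Column-aligned reference sequences; the coordinate system for everything."""

    ids: list[str]
    seqs: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentFormatError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")
        if any(not i for i in self.ids):
            raise AlignmentFormatError("empty sequence id")
        if self.seqs:
            L = len(self.seqs[0])
            for k, s in enumerate(self.seqs):
                if len(s) != L:
                    raise AlignmentFormatError(
                        f"ragged alignment: record {k + 1} ({self.ids[k]!r}) has "
                        f"length {len(s)}, expected {L}"
                    )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def index_of(self, sid: str) -> int:
        return self.ids.index(sid)

    def codes(self) -> np.ndarray:
        """(n_seqs, n_cols) uint8 code matrix; cached."""
        if self._codes is None:
            self._codes = np.vstack([encode_sequence(s) for s in self.seqs])
        return self._codes

    def drop(self, sid: str) -> "ReferenceAlignment":
        """Alignment without sequence *sid* (columns untouched)."""
        k = self.index_of(sid)
        sub = ReferenceAlignment(
            self.ids[:k] + self.ids[k + 1 :], self.seqs[:k] + self.seqs[k + 1 :]
        )
        if self._codes is not None:
            sub._codes = np.delete(self._codes, k, axis=0)
        return sub


@dataclass
class AlignedQuery:
    """A (partial) query sequence expressed in reference alignment columns.

    ``cols`` are strictly increasing 0-based column indices and ``seq`` holds
    the residue observed at each of those columns.  Columns not listed are
    treated as gaps.
    """

    id: str
    cols: np.ndarray
    seq: str

    def __post_init__(self) -> None:
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if len(self.cols) != len(self.seq):
            raise AlignmentFormatError(f"query {self.id!r}: cols/seq length mismatch")
        if len(self.cols) and np.any(np.diff(self.cols) <= 0):
            raise AlignmentFormatError(f"query {self.id!r}: columns not increasing")

    @classmethod
    def from_gapped(cls, qid: str, gapped: str) -> "AlignedQuery":
        gapped = _normalize(gapped)
        cols = np.flatnonzero(encode_sequence(gapped) != MISSING)
        return cls(qid, cols, "".join(gapped[c] for c in cols))

    @property
    def n_covered(self) -> int:
        return len(self.cols)

    def codes(self) -> np.ndarray:
        return encode_sequence(self.seq)

    def full_codes(self, n_cols: int) -> np.ndarray:
        """Length-``n_cols`` code vector with 4 (missing) off the covered columns."""
        out = np.full(n_cols, MISSING, dtype=np.uint8)
        out[self.cols] = self.codes()
        return out


def read_fasta_alignment(path) -> ReferenceAlignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and ``U`` is mapped to ``T``.  Ragged record
    lengths and duplicate ids raise :class:`AlignmentFormatError`.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(_normalize(str(rec.seq)))
    if not ids:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return ReferenceAlignment(ids, seqs)


def read_query_fasta(path, n_cols: int) -> list[AlignedQuery]:
    """Read pre-aligned queries (rows of the reference coordinate system)."""
    queries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if len(s) != n_cols:
            raise AlignmentFormatError(
                f"query {rec.id!r} has {len(s)} columns, reference has {n_cols}"
            )
        queries.append(AlignedQuery.from_gapped(rec.id, s))
    return queries


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


class Topology:
    """Unrooted binary tree with stable preorder edge numbering.

    Internally rooted at a trifurcating internal node (node 0); every other
    internal node has exactly two children.  Nodes are numbered in preorder,
    so the edge above node ``v`` (v >= 1) has ``edge_num = v - 1`` — the
    numbering is therefore a pure function of the Newick child order.
    """

    def __init__(self, parent, children, label, length):
        self.parent = parent  # list[int], parent[0] == -1
        self.children = children  # list[list[int]]
        self.label = label  # list[str|None], leaf labels
        self.length = length  # list[float|None], length of edge above node
        self._postorder: list[int] | None = None
        self._leafsets: list[frozenset] | None = None
        n = self.n_nodes
        if len(self.children[0]) != 3:
            raise TreeFormatError("root must be a trifurcation")
        for v in range(1, n):
            if len(self.children[v]) not in (0, 2):
                raise TreeFormatError("tree is not binary (polytomy or unifurcation)")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_spec(cls, spec) -> "Topology":
        """Build from a nested spec ``(label, length, [child specs])``.

        The root spec must have exactly three children and label/length None.
        Node ids are assigned in preorder following child order.
        """
        parent, children, label, length = [], [], [], []

        def add(node, par):
            v = len(parent)
            parent.append(par)
            children.append([])
            label.append(node[0])
            length.append(node[1])
            if par >= 0:
                children[par].append(v)
            for ch in node[2]:
                add(ch, v)

        add(spec, -1)
        return cls(parent, children, label, length)

    def to_spec(self, v: int = 0):
        return (
            self.label[v],
            self.length[v],
            [self.to_spec(c) for c in self.children[v]],
        )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_leaf(v)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.label[v] for v in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def node_of_edge(self, e: int) -> int:
        if not 0 <= e < self.n_edges:
            raise KeyError(f"edge {e} not in topology (0..{self.n_edges - 1})")
        return e + 1

    def edge_of_node(self, v: int) -> int:
        if v <= 0:
            raise KeyError("root has no edge")
        return v - 1

    def postorder(self) -> list[int]:
        if self._postorder is None:
            order, stack = [], [0]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            order.reverse()
            self._postorder = order
        return self._postorder

    def leafset_below(self, v: int) -> frozenset:
        if self._leafsets is None:
            sets: list[frozenset | None] = [None] * self.n_nodes
            for v2 in self.postorder():
                if self.is_leaf(v2):
                    sets[v2] = frozenset([self.label[v2]])
                else:
                    acc = frozenset()
                    for c in self.children[v2]:
                        acc |= sets[c]
                    sets[v2] = acc
            self._leafsets = sets
        return self._leafsets[v]

    def split_of_edge(self, e: int) -> frozenset:
        """Leaf labels on the child side of edge ``e``."""
        return self.leafset_below(self.node_of_edge(e))

    def bipartitions(self) -> set[frozenset]:
        """Canonical set of non-trivial splits (smaller side, ties by sort)."""
        full = frozenset(self.leaf_labels)
        out = set()
        for e in range(self.n_edges):
            below = self.split_of_edge(e)
            if 1 < len(below) < len(full) - 1:
                other = full - below
                if (len(below), sorted(below)) <= (len(other), sorted(other)):
                    out.add(below)
                else:
                    out.add(other)
        return out

    def find_edge_by_split(self, labels) -> int:
        """Edge whose bipartition is {labels | rest}; raises if absent."""
        want = frozenset(labels)
        full = frozenset(self.leaf_labels)
        comp = full - want
        for e in range(self.n_edges):
            below = self.split_of_edge(e)
            if below == want or below == comp:
                return e
        raise KeyError(f"no edge with split {sorted(want)}")

    def edge_lengths(self) -> np.ndarray:
        out = np.full(self.n_edges, np.nan)
        for v in range(1, self.n_nodes):
            if self.length[v] is not None:
                out[v - 1] = self.length[v]
        return out

    def with_edge_lengths(self, lengths) -> "Topology":
        t = Topology(
            list(self.parent),
            [list(c) for c in self.children],
            list(self.label),
            [None] + [float(lengths[v - 1]) for v in range(1, self.n_nodes)],
        )
        return t

    # -- newick -------------------------------------------------------------

    def newick(self, edge_numbers: bool = False, lengths: bool = True) -> str:
        def fmt(v):
            parts = ""
            if not self.is_leaf(v):
                parts = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            else:
                parts = self.label[v]
            if v == 0:
                return parts
            if lengths and self.length[v] is not None:
                parts += f":{self.length[v]:.10g}"
            if edge_numbers:
                parts += "{%d}" % (v - 1)
            return parts

        return fmt(0) + ";"

    # -- editing ------------------------------------------------------------

    def prune_leaf(self, leaf_label: str) -> tuple["Topology", int]:
        """Remove a leaf; return the pruned tree and the merged edge's number.

        The two edges flanking the removed attachment node fuse into one; that
        merged edge is the "truth" edge for leave-one-out evaluation.
        """
        if self.n_leaves < 5:
            raise TreeFormatError("cannot prune: fewer than 5 leaves")
        try:
            x = next(
                v for v in range(self.n_nodes) if self.is_leaf(v) and self.label[v] == leaf_label
            )
        except StopIteration:
            raise KeyError(f"leaf {leaf_label!r} not in tree") from None
        p = self.parent[x]

        def spec_without(v, skip):
            lab, ln, ch = self.label[v], self.length[v], []
            for c in self.children[v]:
                if c != skip:
                    ch.append(spec_without(c, skip))
            return (lab, ln, ch)

        if p == 0:
            # root loses one of three children: suppress the degree-2 root by
            # merging its two remaining child edges; re-root at an internal one
            c1, c2 = [c for c in self.children[0] if c != x]
            if self.is_leaf(c1) and self.is_leaf(c2):
                raise TreeFormatError("pruning would leave a degenerate tree")
            if self.is_leaf(c1):
                c1, c2 = c2, c1
            merged_len = _add_len(self.length[c1], self.length[c2])
            sub2 = spec_without(c2, -1)
            sub2 = (sub2[0], merged_len, sub2[2])
            s1 = spec_without(c1, -1)
            root_spec = (None, None, list(s1[2]) + [sub2])
            truth_split = self.leafset_below(c2)
        else:
            s = next(c for c in self.children[p] if c != x)
            merged_len = _add_len(self.length[p], self.length[s])

            def rebuild(v, skip_leaf):
                if v == p:
                    sub = spec_without(s, -1)
                    return (sub[0], merged_len, sub[2])
                lab, ln, ch = self.label[v], self.length[v], []
                for c in self.children[v]:
                    if c != skip_leaf:
                        ch.append(rebuild(c, skip_leaf))
                return (lab, ln, ch)

            root_spec = rebuild(0, x)
            truth_split = self.leafset_below(s)
        pruned = Topology.from_spec(root_spec)
        return pruned, pruned.find_edge_by_split(truth_split)

    def insert_on_edge(self, e: int, new_label: str, pendant_length=None) -> "Topology":
        """Attach a new leaf mid-edge (splitting edge ``e``); used by the oracle."""
        v = self.node_of_edge(e)

        def rebuild(w):
            lab, ln, ch = self.label[w], self.length[w], []
            for c in self.children[w]:
                if c == v:
                    half = None if self.length[v] is None else self.length[v] / 2.0
                    sub = rebuild_sub(v, half)
                    ch.append((None, half, [sub, (new_label, pendant_length, [])]))
                else:
                    ch.append(rebuild(c))
            return (lab, ln, ch)

        def rebuild_sub(w, ln):
            return (self.label[w], ln, [rebuild_sub(c, self.length[c]) for c in self.children[w]])

        return Topology.from_spec(rebuild(0))

    # -- metrics on the tree ------------------------------------------------

    def _edge_graph_nodes(self, e: int) -> tuple[int, int]:
        v = self.node_of_edge(e)
        return self.parent[v], v

    def node_separation(self, e_true: int, e_inf: int) -> int:
        """Number of distinct nodes on the path connecting two edges.

        0 for the same edge; 1 for edges sharing a node.
        """
        if e_true == e_inf:
            return 0
        a = self._edge_graph_nodes(e_true)
        b = self._edge_graph_nodes(e_inf)
        best = min(self._node_path_len(x, y) for x in a for y in b)
        return best + 1

    def _node_path_len(self, x: int, y: int) -> int:
        """Number of edges between nodes x and y."""
        da, db = {}, {}
        v, d = x, 0
        while v != -1:
            da[v] = d
            v = self.parent[v]
            d += 1
        v, d = y, 0
        while v != -1:
            if v in da:
                return da[v] + d
            db[v] = d
            v = self.parent[v]
            d += 1
        raise AssertionError("disconnected tree")

    def branch_separation(self, e_true: int, e_inf: int) -> float:
        """Path length (subs/site) between the midpoints of two edges."""
        if e_true == e_inf:
            return 0.0
        lens = self.edge_lengths()
        if np.isnan(lens).any():
            raise TreeFormatError("branch lengths required for branch separation")
        # distance between midpoints = half of each edge + edges strictly between
        a_par, a_chl = self._edge_graph_nodes(e_true)
        b_par, b_chl = self._edge_graph_nodes(e_inf)
        best = np.inf
        for x, y in ((a_par, b_par), (a_par, b_chl), (a_chl, b_par), (a_chl, b_chl)):
            best = min(best, self._node_path_length_weighted(x, y, lens))
        return best + lens[e_true] / 2.0 + lens[e_inf] / 2.0

    def _node_path_length_weighted(self, x: int, y: int, lens) -> float:
        da = {}
        v, d = x, 0.0
        while v != -1:
            da[v] = d
            if self.parent[v] != -1:
                d += lens[v - 1]
            v = self.parent[v]
        v, d = y, 0.0
        while v != -1:
            if v in da:
                return da[v] + d
            if self.parent[v] != -1:
                d += lens[v - 1]
            v = self.parent[v]
        raise AssertionError("disconnected tree")

    def leaf_path_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Additive (path-length) distances among leaves; needs branch lengths."""
        lens = self.edge_lengths()
        if np.isnan(lens).any():
            raise TreeFormatError("branch lengths required")
        leaves = self.leaves
        labels = [self.label[v] for v in leaves]
        n = len(leaves)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = self._node_path_length_weighted(
                    leaves[i], leaves[j], lens
                )
        return labels, D

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            set(self.leaf_labels) == set(other.leaf_labels)
            and self.bipartitions() == other.bipartitions()
        )


def _add_len(a, b):
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _dendropy_to_spec(tree) -> tuple:
    import dendropy  # local import keeps module import light

    seed = tree.seed_node

    def conv(nd):
        lab = nd.taxon.label if nd.taxon is not None else None
        ch = [conv(c) for c in nd.child_nodes()]
        if ch and len(ch) != 2:
            raise TreeFormatError(
                "reference tree must be binary; found a node with "
                f"{len(ch)} children"
            )
        if ch:
            lab = None
        return (lab, nd.edge.length, ch)

    kids = seed.child_nodes()
    if len(kids) == 2:
        # rooted input: suppress the degree-2 root by merging its child edges
        a, b = kids
        if a.is_leaf() and b.is_leaf():
            raise TreeFormatError("tree has fewer than 4 leaves")
        if a.is_leaf():
            a, b = b, a
        merged = _add_len(a.edge.length, b.edge.length)
        sb = conv(b)
        sub_b = (sb[0], merged, sb[2])
        sa = conv(a)
        return (None, None, list(sa[2]) + [sub_b])
    if len(kids) == 3:
        return (None, None, [conv(k) for k in kids])
    raise TreeFormatError(
        f"root must have 2 or 3 children, found {len(kids)} (polytomy?)"
    )


def parse_newick_string(s: str) -> Topology:
    import dendropy

    tree = dendropy.Tree.get(
        data=s,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.suppress_unifurcations()
    topo = Topology.from_spec(_dendropy_to_spec(tree))
    if topo.n_leaves < 4:
        raise TreeFormatError(f"placement needs >= 4 leaves, found {topo.n_leaves}")
    return topo


def read_newick(path, leaf_labels=None) -> Topology:
    """Read a Newick tree; optionally check the leaf set against an alignment.

    Rooted (bifurcating) inputs are silently unrooted by suppressing the
    degree-2 root, since ME placement is defined on unrooted topologies.
    """
    with open(path) as fh:
        topo = parse_newick_string(fh.read())
    if leaf_labels is not None:
        tset, aset = set(topo.leaf_labels), set(leaf_labels)
        if tset != aset:
            only_t = sorted(tset - aset)
            only_a = sorted(aset - tset)
            raise TreeFormatError(
                "tree/alignment leaf mismatch: "
                f"only in tree: {only_t}; only in alignment: {only_a}"
            )
    return topo


# ---------------------------------------------------------------------------
# jplace
# ---------------------------------------------------------------------------


def write_jplace(results, topology: Topology, path_or_file, metadata=None) -> None:
    """Write placements as a jplace version 3 document.

    ``likelihood`` carries the negated insertion cost (−S, larger is better)
    and ``like_weight_ratio`` carries bootstrap support in [0, 1].
    """
    placements = []
    n_edges = topology.n_edges
    for res in results:
        rows = []
        for p in res.placements():
            if not 0 <= p.edge_num < n_edges:
                raise KeyError(
                    f"read {res.read_id!r}: edge {p.edge_num} not in topology"
                )
            rows.append(
                [
                    int(p.edge_num),
                    -float(p.cost),
                    float(p.support) if p.support is not None else 0.0,
                    float(p.distal_length),
                    float(p.pendant_length),
                ]
            )
        placements.append({"p": rows, "n": [res.read_id]})
    doc = {
        "version": 3,
        "tree": topology.newick(edge_numbers=True),
        "fields": list(JPLACE_FIELDS),
        "placements": placements,
        "metadata": metadata or {"invocation": "meplace"},
    }
    if hasattr(path_or_file, "write"):
        json.dump(doc, path_or_file, indent=1)
    else:
        with open(path_or_file, "w") as fh:
            json.dump(doc, fh, indent=1)


def _strip_edge_numbers(tree_str: str) -> tuple[str, list[int]]:
    nums = [int(m) for m in re.findall(r"\{(\d+)\}", tree_str)]
    return re.sub(r"\{\d+\}", "", tree_str), nums


def read_jplace(path_or_file):
    """Read a jplace document -> (Topology, placements dict, edge map).

    Edge numbers in the file are mapped onto this package's internal numbering
    via the order of ``{num}`` tokens in the tree string (postorder).  Returns
    ``(topology, {read_id: list-of-row-dicts}, file_num -> internal_edge)``.
    """
    if hasattr(path_or_file, "read"):
        doc = json.load(path_or_file)
    else:
        with open(path_or_file) as fh:
            doc = json.load(fh)
    tree_str, nums = _strip_edge_numbers(doc["tree"])
    topo = parse_newick_string(tree_str)
    post_edges = [v - 1 for v in topo.postorder() if v != 0]
    if len(nums) != len(post_edges):
        raise TreeFormatError(
            f"jplace tree has {len(nums)} edge numbers for {len(post_edges)} edges"
        )
    edge_map = dict(zip(nums, post_edges))
    fields = doc["fields"]
    placements = {}
    for entry in doc["placements"]:
        names = entry.get("n") or [nm for nm, _ in entry.get("nm", [])]
        rows = [dict(zip(fields, row)) for row in entry["p"]]
        for nm in names:
            placements[nm] = rows
    return topo, placements, edge_map


def write_placement_tsv(results, path_or_file, truth=None) -> None:
    """Flat TSV: read_id, edge_num, S_cost, support, S_N_if_known."""
    close = False
    if hasattr(path_or_file, "write"):
        fh = path_or_file
    else:
        fh = open(path_or_file, "w")
        close = True
    try:
        fh.write("read_id\tedge_num\tS_cost\tsupport\tS_N_if_known\n")
        for res in results:
            sup = "" if res.best_support is None else f"{res.best_support:.6g}"
            sn = ""
            if truth is not None and res.read_id in truth:
                sn = str(truth[res.read_id])
            fh.write(
                f"{res.read_id}\t{res.best_edge}\t{res.s_min:.10g}\t{sup}\t{sn}\n"
            )
    finally:
        if close:
            fh.close()
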