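"""Minimum-evolution core: OLS branch lengths and the exact insertion scan.

Given a fixed unrooted binary topology T on n leaves and a distance matrix D,
the placement cost of a read r on edge b is S_{b,r}: the total OLS tree
length of the (n+1)-leaf tree with r attached mid-edge on b, with *all*
branch lengths re-estimated by ordinary least squares.  The best placement
minimises S_{b,r} over all 2n-3 edges.

Per-edge OLS estimates (exact, classical):

    external edge of leaf i, neighbour splitting the rest into A, B:
        l_i = (d_iA + d_iB - d_AB) / 2
    internal edge separating A, B | C, D:
        l = [lam (d_AC + d_BD) + (1-lam)(d_AD + d_BC) - d_AB - d_CD] / 2
        lam = (|A||D| + |B||C|) / ((|A|+|B|)(|C|+|D|))

where d_XY is the plain average of leaf-pair distances between the sets.
These formulas reproduce the normal-equation (lstsq) solution exactly; the
test suite asserts this.

Because d(X u {r}, Y) does not depend on *where* r sits inside X, the length
of any edge not incident to the insertion node is identical for insertions
on adjacent edges.  Scanning all edges therefore needs one O(n) evaluation
for a starting edge plus an O(1) update per adjacent-edge move; building the
subtree-average tables is an O(n^2) one-time cost shared by all reads.

A slower brute-force oracle (explicit (n+1)-leaf tree, full OLS) is provided
for verification, plus a balanced variant (equal subtree weighting, the BME
criterion whose total length is Pauplin's formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Topology

__all__ = [
    "PlacementEngine",
    "InsertionScan",
    "ols_branch_lengths",
    "tree_length",
    "oracle_insertion_cost",
    "insertion_scan",
    "best_placement",
]


def _ext(d_iA, d_iB, d_AB):
    return 0.5 * (d_iA + d_iB - d_AB)


def _int(nA, nB, nC, nD, dAC, dBD, dAD, dBC, dAB, dCD):
    lam = (nA * nD + nB * nC) / ((nA + nB) * (nC + nD))
    return 0.5 * (lam * (dAC + dBD) + (1.0 - lam) * (dAD + dBC) - dAB - dCD)


class PlacementEngine:
    """Precomputed subtree averages for one (topology, D) pair.

    Subtrees are addressed by directed-subtree ids: ``v`` for the leaves
    below node v, ``M + v`` for the complement (M = number of nodes).  The
    engine is built once per reference and reused for every read and every
    bootstrap replicate; ``PlacementEngine.build_count`` counts builds so
    batch code can assert the setup really is shared.
    """

    build_count = 0  # instrumentation hook

    def __init__(
        self,
        topology: Topology,
        D: np.ndarray,
        leaf_order: list[str] | None = None,
        clamp_negative: bool = False,
        balanced: bool = False,
    ):
        PlacementEngine.build_count += 1
        self.topology = topology
        self.clamp_negative = clamp_negative
        self.balanced = balanced
        D = np.asarray(D, dtype=float)
        n = topology.n_leaves
        if D.shape != (n, n):
            raise ValueError(f"D has shape {D.shape}, topology has {n} leaves")
        self.D = D
        if leaf_order is None:
            leaf_order = topology.leaf_labels
        self.leaf_order = list(leaf_order)
        pos = {lab: k for k, lab in enumerate(self.leaf_order)}
        if set(pos) != set(topology.leaf_labels):
            raise ValueError("leaf_order does not match topology leaves")

        t = topology
        M = t.n_nodes
        self.M = M
        self.n = n
        self.rank = np.full(M, -1, dtype=np.intp)
        for v in range(M):
            if t.is_leaf(v):
                self.rank[v] = pos[t.label[v]]
        post = t.postorder()
        self._post = post

        # subtree sizes and leaf index lists (below side)
        size = np.zeros(M, dtype=np.intp)
        idx: list[np.ndarray | None] = [None] * M
        for v in post:
            if t.is_leaf(v):
                size[v] = 1
                idx[v] = np.array([self.rank[v]], dtype=np.intp)
            else:
                size[v] = sum(size[c] for c in t.children[v])
                idx[v] = np.concatenate([idx[c] for c in t.children[v]])
        self.size_below = size
        self.idx_below = idx

        if balanced:
            # per-leaf weights 2^(-depth within subtree); each vector sums to 1
            wts: list[np.ndarray | None] = [None] * M
            for v in post:
                if t.is_leaf(v):
                    wts[v] = np.array([1.0])
                else:
                    wts[v] = np.concatenate([0.5 * wts[c] for c in t.children[v]])
            self.wt_below = wts
            Sb = np.empty((M, n))
            for v in post:
                if t.is_leaf(v):
                    Sb[v] = D[self.rank[v]]
                else:  # root row (3 children) is never used as a subtree
                    Sb[v] = sum(Sb[c] for c in t.children[v]) / len(t.children[v])
            Sa = np.empty((M, n))
            for v in range(1, M):  # preorder
                u = t.parent[v]
                if u == 0:
                    o1, o2 = [c for c in t.children[0] if c != v]
                    Sa[v] = 0.5 * (Sb[o1] + Sb[o2])
                else:
                    s = next(c for c in t.children[u] if c != v)
                    Sa[v] = 0.5 * Sa[u] + 0.5 * Sb[s]
            self.S_below, self.S_above = Sb, Sa
        else:
            S = np.empty((M, n))
            for v in post:
                if t.is_leaf(v):
                    S[v] = D[self.rank[v]]
                else:
                    S[v] = sum(S[c] for c in t.children[v])
            tot = D.sum(axis=0)
            self.S_below = S
            self.S_above = tot[None, :] - S

        self._avg_cache: dict[tuple[int, int], float] = {}
        self._build_edge_records()
        self._build_frames()
        self._build_neighbors()

    # -- subtree bookkeeping -------------------------------------------------

    def _size(self, zid: int) -> int:
        if zid < self.M:
            return int(self.size_below[zid])
        return self.n - int(self.size_below[zid - self.M])

    def _svec(self, zid: int) -> np.ndarray:
        if zid < self.M:
            return self.S_below[zid]
        return self.S_above[zid - self.M]

    def _avg(self, x: int, y: int) -> float:
        """Average distance between two disjoint directed subtrees."""
        key = (x, y) if x <= y else (y, x)
        val = self._avg_cache.get(key)
        if val is not None:
            return val
        if x < self.M:
            below, other = x, y
        elif y < self.M:
            below, other = y, x
        else:
            raise AssertionError("avg of two complement subtrees is never needed")
        if self.balanced:
            val = float(
                np.dot(self.wt_below[below], self._svec(other)[self.idx_below[below]])
            )
        else:
            val = float(self._svec(other)[self.idx_below[below]].sum()) / (
                self._size(x) * self._size(y)
            )
        self._avg_cache[key] = val
        return val

    # -- static per-edge records ---------------------------------------------

    def _build_edge_records(self):
        """For every edge (node v >= 1): the 2+2 adjacent subtrees and their
        pairwise average distances.

        Record: (P, Q, leafdown, C, Dd, dPQ, dPC, dPD, dQC, dQD, dCD) where
        P, Q sit at the parent end (Q is above(u) whenever u is not the root)
        and C, Dd at the child end; for a leaf edge C is the leaf's own id.
        """
        t, M = self.topology, self.M
        self._erec = [None] * M
        for v in range(1, M):
            u = t.parent[v]
            if u == 0:
                P, Q = [c for c in t.children[0] if c != v]
            else:
                P = next(c for c in t.children[u] if c != v)
                Q = M + u
            if t.is_leaf(v):
                C, Dd = v, -1
                dPQ = self._avg(P, Q)
                rec = (P, Q, True, C, Dd, dPQ, self._avg(P, C), 0.0, self._avg(Q, C), 0.0, 0.0)
            else:
                C, Dd = t.children[v]
                rec = (
                    P, Q, False, C, Dd,
                    self._avg(P, Q), self._avg(P, C), self._avg(P, Dd),
                    self._avg(Q, C), self._avg(Q, Dd), self._avg(C, Dd),
                )
            self._erec[v] = rec

    def _decomp(self, zid: int):
        """Far-side decomposition of a directed subtree.

        Returns (is_leaf, W1, W2, map) where map[(W, other_id)] gives the
        stored average; W1/W2 are directed-subtree ids (for a leaf, W1 is the
        leaf id itself).
        """
        M = self.M
        if zid < M:
            v = zid
            P, Q, leafdown, C, Dd, dPQ, dPC, dPD, dQC, dQD, dCD = self._erec[v]
            if leafdown:
                return True, C, -1, dCD, {}
            # others around the parent of this frame are P and Q
            return (
                False, C, Dd, dCD,
                {(C, P): dPC, (C, Q): dQC, (Dd, P): dPD, (Dd, Q): dQD},
            )
        w = zid - M
        P, Q, leafdown, C, Dd, dPQ, dPC, dPD, dQC, dQD, dCD = self._erec[w]
        # above(w) decomposes at parent(w) into P and Q; the other subtrees
        # around w are its children C and Dd
        return (
            False, P, Q, dPQ,
            {(P, C): dPC, (P, Dd): dPD, (Q, C): dQC, (Q, Dd): dQD},
        )

    def _build_frames(self):
        """Static tuples for terms(w, e): insertion on edge e seen from node w."""
        t, M = self.topology, self.M
        frames: dict[tuple[int, int], tuple] = {}
        for w in range(M):
            if t.is_leaf(w):
                continue
            inc = [(c - 1, c) for c in t.children[w]]
            if w != 0:
                inc.append((w - 1, M + w))
            for i, (eid, z1) in enumerate(inc):
                (e2, z2), (e3, z3) = [inc[j] for j in range(3) if j != i]
                n1, n2, n3 = self._size(z1), self._size(z2), self._size(z3)
                d12, d13, d23 = self._avg(z1, z2), self._avg(z1, z3), self._avg(z2, z3)
                leaf1, W1, W2, dW1W2, cross1 = self._decomp(z1)
                leaf2, V1, V2, dV1V2, cross2 = self._decomp(z2)
                leaf3, U1, U2, dU1U2, cross3 = self._decomp(z3)
                frames[(w, eid)] = (
                    z1, z2, z3, n1, n2, n3, d12, d13, d23,
                    leaf1, W1, W2,
                    0 if leaf1 else self._size(W1), 0 if leaf1 else self._size(W2),
                    dW1W2,
                    0.0 if leaf1 else cross1[(W1, z2)], 0.0 if leaf1 else cross1[(W1, z3)],
                    0.0 if leaf1 else cross1[(W2, z2)], 0.0 if leaf1 else cross1[(W2, z3)],
                    leaf2, V1, V2,
                    0 if leaf2 else self._size(V1), 0 if leaf2 else self._size(V2),
                    dV1V2,
                    0.0 if leaf2 else cross2[(V1, z1)], 0.0 if leaf2 else cross2[(V1, z3)],
                    0.0 if leaf2 else cross2[(V2, z1)], 0.0 if leaf2 else cross2[(V2, z3)],
                    leaf3, U1, U2,
                    0 if leaf3 else self._size(U1), 0 if leaf3 else self._size(U2),
                    dU1U2,
                    0.0 if leaf3 else cross3[(U1, z1)], 0.0 if leaf3 else cross3[(U1, z2)],
                    0.0 if leaf3 else cross3[(U2, z1)], 0.0 if leaf3 else cross3[(U2, z2)],
                )
        self._frames = frames

    def _build_neighbors(self):
        t = self.topology
        nbrs: list[list[tuple[int, int]]] = []
        for e in range(t.n_edges):
            v = e + 1
            u = t.parent[v]
            lst = [(c - 1, v) for c in t.children[v]]
            lst.extend((s - 1, u) for s in t.children[u] if s != v)
            if u != 0:
                lst.append((u - 1, u))
            nbrs.append(lst)
        self._nbrs = nbrs

    # -- branch lengths on the reference tree --------------------------------

    def branch_lengths(self) -> np.ndarray:
        """OLS (or balanced) estimate for every edge of the reference tree."""
        M = self.M
        out = np.empty(M - 1)
        for v in range(1, M):
            P, Q, leafdown, C, Dd, dPQ, dPC, dPD, dQC, dQD, dCD = self._erec[v]
            if leafdown:
                out[v - 1] = _ext(dPC, dQC, dPQ)
            elif self.balanced:
                out[v - 1] = 0.5 * (0.5 * (dPC + dQD + dPD + dQC) - dPQ - dCD)
            else:
                out[v - 1] = _int(
                    self._size(P), self._size(Q), self._size(C), self._size(Dd),
                    dPC, dQD, dPD, dQC, dPQ, dCD,
                )
        return out

    def tree_length(self) -> float:
        bl = self.branch_lengths()
        if self.clamp_negative:
            bl = np.maximum(bl, 0.0)
        return float(bl.sum())

    # -- per-read machinery ---------------------------------------------------

    def read_averages(self, d_r: np.ndarray) -> np.ndarray:
        """Average distance from the read to every directed subtree (2M,)."""
        t, M = self.topology, self.M
        d_r = np.asarray(d_r, dtype=float)
        if d_r.shape != (self.n,):
            raise ValueError(f"read distance vector has shape {d_r.shape}")
        if not np.isfinite(d_r).all():
            raise ValueError("read distances must be finite")
        rb = np.empty(M)
        if self.balanced:
            for v in self._post:
                if t.is_leaf(v):
                    rb[v] = d_r[self.rank[v]]
                else:
                    rb[v] = sum(rb[c] for c in t.children[v]) / len(t.children[v])
            ra = np.empty(M)
            ra[0] = np.nan
            for v in range(1, M):
                u = t.parent[v]
                if u == 0:
                    o1, o2 = [c for c in t.children[0] if c != v]
                    ra[v] = 0.5 * (rb[o1] + rb[o2])
                else:
                    s = next(c for c in t.children[u] if c != v)
                    ra[v] = 0.5 * ra[u] + 0.5 * rb[s]
            return np.concatenate([rb, ra])
        for v in self._post:
            if t.is_leaf(v):
                rb[v] = d_r[self.rank[v]]
            else:
                rb[v] = sum(rb[c] for c in t.children[v])
        tot = rb[0]
        sz = self.size_below
        with np.errstate(invalid="ignore", divide="ignore"):
            a_below = rb / sz
            a_above = (tot - rb) / (self.n - sz)
        return np.concatenate([a_below, a_above])

    def _terms(self, w: int, eid: int, a: np.ndarray) -> float:
        """Sum of the edge lengths that depend on which of w's incident edges
        carries the insertion: the pendant, the two pieces of the split edge,
        and the two other w-incident edges."""
        (
            z1, z2, z3, n1, n2, n3, d12, d13, d23,
            leaf1, W1, W2, nW1, nW2, dW1W2, dW1_2, dW1_3, dW2_2, dW2_3,
            leaf2, V1, V2, nV1, nV2, dV1V2, dV1_1, dV1_3, dV2_1, dV2_3,
            leaf3, U1, U2, nU1, nU2, dU1U2, dU1_1, dU1_2, dU2_1, dU2_2,
        ) = self._frames[(w, eid)]
        a1, a2, a3 = a[z1], a[z2], a[z3]
        ncomp = n2 + n3
        acomp = (n2 * a2 + n3 * a3) / ncomp
        d1comp = (n2 * d12 + n3 * d13) / ncomp
        pend = _ext(a1, acomp, d1comp)
        piece_w = _int(n1, 1, n2, n3, d12, a3, d13, a2, a1, d23)
        if leaf1:
            piece_far = _ext(a1, d1comp, acomp)
        else:
            dW1c = (n2 * dW1_2 + n3 * dW1_3) / ncomp
            dW2c = (n2 * dW2_2 + n3 * dW2_3) / ncomp
            piece_far = _int(
                nW1, nW2, 1, ncomp, a[W1], dW2c, dW1c, a[W2], dW1W2, acomp
            )
        nC1 = n1 + 1
        dC3 = (n1 * d13 + a3) / nC1
        if leaf2:
            l2 = _ext((n1 * d12 + a2) / nC1, d23, dC3)
        else:
            l2 = _int(
                nV1, nV2, nC1, n3,
                (n1 * dV1_1 + a[V1]) / nC1, dV2_3, dV1_3, (n1 * dV2_1 + a[V2]) / nC1,
                dV1V2, dC3,
            )
        dC2 = (n1 * d12 + a2) / nC1
        if leaf3:
            l3 = _ext((n1 * d13 + a3) / nC1, d23, dC2)
        else:
            l3 = _int(
                nU1, nU2, nC1, n2,
                (n1 * dU1_1 + a[U1]) / nC1, dU2_2, dU1_2, (n1 * dU2_1 + a[U2]) / nC1,
                dU1U2, dC2,
            )
        if self.clamp_negative:
            return (
                max(pend, 0.0) + max(piece_w, 0.0) + max(piece_far, 0.0)
                + max(l2, 0.0) + max(l3, 0.0)
            )
        return pend + piece_w + piece_far + l2 + l3

    def _base_far_sum(self, a: np.ndarray) -> float:
        """Sum of l_g over edges g not incident to the root, for insertion on
        edge 0 (so the r-augmented adjacent subtree of each g is above(u))."""
        t, M = self.topology, self.M
        clamp = self.clamp_negative
        total = 0.0
        for v in range(1, M):
            u = t.parent[v]
            if u == 0:
                continue
            P, Q, leafdown, C, Dd, dPQ, dPC, dPD, dQC, dQD, dCD = self._erec[v]
            # Q is above(u); augment it with the read
            nQ = self._size(Q)
            wq = nQ / (nQ + 1.0)
            dPQ_ = wq * dPQ + a[P] / (nQ + 1.0)
            if leafdown:
                dQC_ = wq * dQC + a[C] / (nQ + 1.0)
                l = _ext(dPC, dQC_, dPQ_)
            else:
                dQC_ = wq * dQC + a[C] / (nQ + 1.0)
                dQD_ = wq * dQD + a[Dd] / (nQ + 1.0)
                l = _int(
                    self._size(P), nQ + 1, self._size(C), self._size(Dd),
                    dPC, dQD_, dPD, dQC_, dPQ_, dCD,
                )
            total += max(l, 0.0) if clamp else l
        return total

    def scan(self, d_r: np.ndarray) -> "InsertionScan":
        """S_{b,r} for every edge b (exact, incremental)."""
        a = self.read_averages(d_r)
        if self.balanced:
            S = self._scan_balanced(a)
        else:
            n_edges = self.topology.n_edges
            S = np.empty(n_edges)
            tcache: dict[tuple[int, int], float] = {}

            def T(w, e):
                key = (w, e)
                val = tcache.get(key)
                if val is None:
                    val = self._terms(w, e, a)
                    tcache[key] = val
                return val

            S[0] = self._base_far_sum(a) + T(0, 0)
            seen = np.zeros(n_edges, dtype=bool)
            seen[0] = True
            stack = [0]
            while stack:
                e = stack.pop()
                for f, w in self._nbrs[e]:
                    if not seen[f]:
                        S[f] = S[e] + T(w, f) - T(w, e)
                        seen[f] = True
                        stack.append(f)
        return InsertionScan(S=S, engine=self, read_averages=a)

    def _scan_balanced(self, a: np.ndarray) -> np.ndarray:
        t, M = self.topology, self.M
        n_edges = t.n_edges
        S = np.empty(n_edges)
        L0 = self.tree_length()
        # starting edge 0 (node 1): split below(1) | above(1)
        x, y = 1, M + 1
        S[0] = L0 - 0.5 * self._avg(x, y) + 0.5 * (a[x] + a[y])
        seen = np.zeros(n_edges, dtype=bool)
        seen[0] = True
        stack = [0]
        while stack:
            e = stack.pop()
            for f, w in self._nbrs[e]:
                if not seen[f]:
                    ze = self._edge_subtree_from(w, e)
                    zf = self._edge_subtree_from(w, f)
                    z3 = next(
                        z
                        for z in self._around(w)
                        if z not in (ze, zf)
                    )
                    S[f] = S[e] + 0.25 * (
                        a[zf] + self._avg(ze, z3) - a[ze] - self._avg(zf, z3)
                    )
                    seen[f] = True
                    stack.append(f)
        return S

    def _around(self, w: int) -> list[int]:
        out = [c for c in self.topology.children[w]]
        if w != 0:
            out.append(self.M + w)
        return out

    def _edge_subtree_from(self, w: int, e: int) -> int:
        v = e + 1
        return v if self.topology.parent[v] == w else self.M + w

    def attachment(self, e: int, a: np.ndarray) -> tuple[float, float, float]:
        """(pendant, distal, proximal) lengths for insertion on edge e.

        distal is the piece toward the edge's child end, proximal toward the
        parent end; raw estimates (may be negative; callers clamp for output).
        """
        v = e + 1
        w = self.topology.parent[v]
        if self.balanced:
            z1 = v
            others = [z for z in self._around(w) if z != z1]
            z2, z3 = others
            acomp = 0.5 * (a[z2] + a[z3])
            d1comp = 0.5 * (self._avg(z1, z2) + self._avg(z1, z3))
            pend = _ext(a[z1], acomp, d1comp)
            prox = 0.5 * (0.5 * (self._avg(z1, z2) + a[z3] + self._avg(z1, z3) + a[z2]) - a[z1] - self._avg(z2, z3))
            leaf1, W1, W2, dW1W2, cross = self._decomp(z1)
            if leaf1:
                dist = _ext(a[z1], d1comp, acomp)
            else:
                dW1c = 0.5 * (cross[(W1, z2)] + cross[(W1, z3)])
                dW2c = 0.5 * (cross[(W2, z2)] + cross[(W2, z3)])
                dist = 0.5 * (0.5 * (a[W1] + dW2c + dW1c + a[W2]) - dW1W2 - acomp)
            return pend, dist, prox
        frame = self._frames[(w, e)]
        (
            z1, z2, z3, n1, n2, n3, d12, d13, d23,
            leaf1, W1, W2, nW1, nW2, dW1W2, dW1_2, dW1_3, dW2_2, dW2_3,
        ) = frame[:19]
        a1, a2, a3 = a[z1], a[z2], a[z3]
        ncomp = n2 + n3
        acomp = (n2 * a2 + n3 * a3) / ncomp
        d1comp = (n2 * d12 + n3 * d13) / ncomp
        pend = _ext(a1, acomp, d1comp)
        prox = _int(n1, 1, n2, n3, d12, a3, d13, a2, a1, d23)
        if leaf1:
            dist = _ext(a1, d1comp, acomp)
        else:
            dW1c = (n2 * dW1_2 + n3 * dW1_3) / ncomp
            dW2c = (n2 * dW2_2 + n3 * dW2_3) / ncomp
            dist = _int(nW1, nW2, 1, ncomp, a[W1], dW2c, dW1c, a[W2], dW1W2, acomp)
        return pend, dist, prox


@dataclass
class InsertionScan:
    """Insertion costs S_{b,r} over all edges, plus attachment geometry."""

    S: np.ndarray
    engine: PlacementEngine = field(repr=False)
    read_averages: np.ndarray = field(repr=False)

    def best(self) -> tuple[int, float]:
        """Edge with minimal S; ties broken by smallest edge number."""
        e = int(np.argmin(self.S))
        return e, float(self.S[e])

    def ranked(self, k: int | None = None):
        order = np.argsort(self.S, kind="stable")
        if k is not None:
            order = order[:k]
        return [(int(e), float(self.S[e])) for e in order]

    def attachment(self, e: int) -> tuple[float, float, float]:
        return self.engine.attachment(e, self.read_averages)


# -- functional API ----------------------------------------------------------


def ols_branch_lengths(
    topology: Topology, D, leaf_order=None, balanced: bool = False
) -> np.ndarray:
    """Per-edge OLS branch lengths on a fixed topology (raw; may be negative)."""
    return PlacementEngine(topology, D, leaf_order, balanced=balanced).branch_lengths()


def tree_length(
    topology: Topology, D, leaf_order=None, clamp_negative=False, balanced=False
) -> float:
    """Total OLS tree length: the ME criterion value of the fixed topology."""
    return PlacementEngine(
        topology, D, leaf_order, clamp_negative=clamp_negative, balanced=balanced
    ).tree_length()


def insertion_scan(topology: Topology, D, d_r, leaf_order=None, **kw) -> InsertionScan:
    return PlacementEngine(topology, D, leaf_order, **kw).scan(d_r)


def best_placement(scan: InsertionScan) -> tuple[int, float]:
    if scan.S.size == 0:
        raise ValueError("empty insertion scan")
    return scan.best()


def oracle_insertion_cost(
    topology: Topology,
    D,
    d_r,
    edge_num: int,
    leaf_order=None,
    clamp_negative: bool = False,
    balanced: bool = False,
    query_label: str = "__query__",
) -> float:
    """S_{b,r} by explicit construction: attach the read mid-edge, build the
    full (n+1)x(n+1) matrix, re-estimate every branch by OLS and sum.

    O(n^2) per edge; used for verification and ``--oracle`` runs.
    """
    D = np.asarray(D, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    if leaf_order is None:
        leaf_order = topology.leaf_labels
    t2 = topology.insert_on_edge(edge_num, query_label)
    n = len(leaf_order)
    D2 = np.zeros((n + 1, n + 1))
    D2[:n, :n] = D
    D2[n, :n] = d_r
    D2[:n, n] = d_r
    eng = PlacementEngine(
        t2,
        D2,
        list(leaf_order) + [query_label],
        clamp_negative=clamp_negative,
        balanced=balanced,
    )
    return eng.tree_length()
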