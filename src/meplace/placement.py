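"""Per-read placement orchestration: distances, scan, bootstrap, consensus.

The expensive work — the reference distance matrix and the subtree-average
tables — is done once per reference in :class:`Placer` and shared by every
read and every bootstrap replicate.  Bootstrap support follows the frozen-
reference scheme: only the read-to-reference pair counts are resampled
(multinomially, per pair), the reference part of the matrix and the topology
never change across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import distances as dst
from . import me_core
from .seqio import AlignedQuery, ReferenceAlignment, Topology

__all__ = [
    "PlacementOptions",
    "PlacementRow",
    "PlacementResult",
    "ConsensusReport",
    "Placer",
    "place_read",
    "place_batch",
    "bootstrap_support",
    "consensus",
]


@dataclass(frozen=True)
class PlacementOptions:
    measure: str = "p"  # p | tn93 | tn93g
    gamma_alpha: float = dst.DEFAULT_GAMMA_ALPHA
    min_overlap: int = dst.DEFAULT_MIN_OVERLAP
    impute_max: bool = False
    clamp_negative: bool = False
    balanced: bool = False
    oracle: bool = False
    bootstrap: int = 0  # replicates; 0 disables support
    seed: int = 0
    top_k: int = 5


@dataclass
class PlacementRow:
    edge_num: int
    cost: float
    support: float | None
    distal_length: float
    pendant_length: float


@dataclass
class PlacementResult:
    read_id: str
    rows: list[PlacementRow]
    support_by_edge: dict[int, float] | None
    n_valid_sites: dict[str, float]

    @property
    def best_edge(self) -> int:
        return self.rows[0].edge_num

    @property
    def s_min(self) -> float:
        return self.rows[0].cost

    @property
    def best_support(self) -> float | None:
        return self.rows[0].support

    def placements(self) -> list[PlacementRow]:
        return self.rows


class Placer:
    """Batch placement context: one reference, many reads.

    Building a Placer computes the reference distance matrix and one
    :class:`~meplace.me_core.PlacementEngine`; placing a read then costs
    O(n) scan work plus O(nL) distance work.
    """

    def __init__(
        self,
        aln: ReferenceAlignment,
        topology: Topology,
        options: PlacementOptions = PlacementOptions(),
        ref_distances: dst.DistanceMatrix | None = None,
    ):
        tset, aset = set(topology.leaf_labels), set(aln.ids)
        if tset != aset:
            raise ValueError(
                "tree/alignment leaf mismatch: "
                f"only in tree: {sorted(tset - aset)}; "
                f"only in alignment: {sorted(aset - tset)}"
            )
        self.aln = aln
        self.topology = topology
        self.options = options
        if ref_distances is None:
            ref_distances = dst.ref_distance_matrix(
                aln, options.measure, options.gamma_alpha, options.min_overlap
            )
        if list(ref_distances.ids) != list(aln.ids):
            raise ValueError("reference distance matrix ids do not match alignment")
        self.ref_distances = ref_distances
        self.engine = me_core.PlacementEngine(
            topology,
            ref_distances.D,
            leaf_order=aln.ids,
            clamp_negative=options.clamp_negative,
            balanced=options.balanced,
        )

    # -- internals -----------------------------------------------------------

    def _read_vector(self, counts16: np.ndarray, qid: str) -> np.ndarray:
        o = self.options
        return dst.distances_from_query_counts(
            counts16, self.aln.ids, qid, o.measure, o.gamma_alpha,
            o.min_overlap, o.impute_max,
        )

    def _scan(self, d_r: np.ndarray) -> me_core.InsertionScan:
        if self.options.oracle:
            S = np.array(
                [
                    me_core.oracle_insertion_cost(
                        self.topology,
                        self.ref_distances.D,
                        d_r,
                        e,
                        leaf_order=self.aln.ids,
                        clamp_negative=self.options.clamp_negative,
                        balanced=self.options.balanced,
                    )
                    for e in range(self.topology.n_edges)
                ]
            )
            return me_core.InsertionScan(
                S=S, engine=self.engine, read_averages=self.engine.read_averages(d_r)
            )
        return self.engine.scan(d_r)

    # -- public API ----------------------------------------------------------

    def place(self, q: AlignedQuery, read_index: int = 0) -> PlacementResult:
        o = self.options
        counts16 = dst.query_pair_counts(q, self.aln)
        d_r = self._read_vector(counts16, q.id)
        scan = self._scan(d_r)
        support = None
        if o.bootstrap > 0:
            support = self._bootstrap(counts16, q.id, read_index)
        rows = []
        for e, cost in scan.ranked(o.top_k):
            pend, dist, _prox = scan.attachment(e)
            rows.append(
                PlacementRow(
                    edge_num=e,
                    cost=cost,
                    support=None if support is None else support.get(e, 0.0),
                    distal_length=max(dist, 0.0),
                    pendant_length=max(pend, 0.0),
                )
            )
        N = counts16.sum(axis=1)
        return PlacementResult(
            read_id=q.id,
            rows=rows,
            support_by_edge=support,
            n_valid_sites={
                "min": float(N.min()),
                "median": float(np.median(N)),
                "max": float(N.max()),
            },
        )

    def _bootstrap(self, counts16, qid, read_index) -> dict[int, float]:
        o = self.options
        rng = np.random.default_rng((int(o.seed), int(read_index)))
        freq: dict[int, int] = {}
        for _rep in range(o.bootstrap):
            c = dst.bootstrap_query_counts(counts16, rng)
            d_r = self._read_vector(c, qid)
            scan = self.engine.scan(d_r)
            e, _ = scan.best()
            freq[e] = freq.get(e, 0) + 1
        return {e: k / o.bootstrap for e, k in sorted(freq.items())}

    def place_batch(self, queries) -> tuple[list[PlacementResult], dict[str, str]]:
        """Place many reads; per-read failures are collected, not fatal."""
        results, errors = [], {}
        for k, q in enumerate(queries):
            try:
                results.append(self.place(q, read_index=k))
            except (dst.UndefinedDistanceError, dst.SaturationError, ValueError) as exc:
                errors[q.id] = str(exc)
        return results, errors


def place_read(
    q: AlignedQuery,
    aln: ReferenceAlignment,
    topology: Topology,
    options: PlacementOptions = PlacementOptions(),
) -> PlacementResult:
    return Placer(aln, topology, options).place(q)


def place_batch(
    queries,
    aln: ReferenceAlignment,
    topology: Topology,
    options: PlacementOptions = PlacementOptions(),
):
    return Placer(aln, topology, options).place_batch(queries)


def bootstrap_support(
    q: AlignedQuery,
    aln: ReferenceAlignment,
    topology: Topology,
    B: int,
    seed: int = 0,
    options: PlacementOptions = PlacementOptions(),
    read_index: int = 0,
) -> dict[int, float]:
    """Per-edge bootstrap support for one read (edge -> replicate fraction)."""
    if B < 1:
        raise ValueError("bootstrap needs B >= 1")
    opt = replace(options, bootstrap=B, seed=seed)
    res = Placer(aln, topology, opt).place(q, read_index=read_index)
    return res.support_by_edge


@dataclass
class ConsensusReport:
    """Agreement between two placement result sets over the same reads."""

    read_ids: list[str]
    agree: dict[str, bool]
    n_reads: int
    n_agree: int
    agreement_fraction: float
    accuracy_a: float | None = None
    accuracy_b: float | None = None
    accuracy_agree: float | None = None
    details: dict = field(default_factory=dict)


def consensus(
    results_a,
    results_b,
    truth: dict[str, int] | None = None,
    topology: Topology | None = None,
    max_node_separation: int = 0,
) -> ConsensusReport:
    """Compare best edges of two methods read-by-read.

    Agreement means identical best ``edge_num`` (both sets must be numbered
    against the same tree).  With ``max_node_separation`` > 0 a relaxed
    criterion (within that many nodes; needs ``topology``) is used.  With a
    ``truth`` map of read -> correct edge, accuracies overall and within the
    agreement subset are reported.
    """
    a = {r.read_id: r.best_edge for r in results_a}
    b = {r.read_id: r.best_edge for r in results_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise ValueError(
            f"result sets cover different reads: only in A: {only_a}; "
            f"only in B: {only_b}"
        )
    ids = sorted(a)
    if max_node_separation > 0:
        if topology is None:
            raise ValueError("relaxed agreement needs the shared topology")
        agree = {
            r: topology.node_separation(a[r], b[r]) <= max_node_separation
            for r in ids
        }
    else:
        agree = {r: a[r] == b[r] for r in ids}
    n_agree = sum(agree.values())
    rep = ConsensusReport(
        read_ids=ids,
        agree=agree,
        n_reads=len(ids),
        n_agree=n_agree,
        agreement_fraction=n_agree / len(ids) if ids else 0.0,
    )
    if truth is not None:
        missing = [r for r in ids if r not in truth]
        if missing:
            raise ValueError(f"truth missing for reads: {missing[:5]}")
        ok_a = [a[r] == truth[r] for r in ids]
        ok_b = [b[r] == truth[r] for r in ids]
        rep.accuracy_a = float(np.mean(ok_a)) if ids else None
        rep.accuracy_b = float(np.mean(ok_b)) if ids else None
        agreeing = [r for r in ids if agree[r]]
        if agreeing:
            rep.accuracy_agree = float(
                np.mean([a[r] == truth[r] for r in agreeing])
            )
        rep.details = {"n_agreeing_correct": sum(a[r] == truth[r] for r in agreeing)}
    return rep
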