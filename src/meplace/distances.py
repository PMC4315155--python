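"""Pair counts and evolutionary distances.

The sufficient statistic for every distance here is the 4x4 matrix of
nucleotide-pair counts over columns where both sequences carry an
unambiguous base (pairwise deletion).  The same counts drive the
multinomial bootstrap used for placement support: each read-reference
pair's counts are resampled from Multinomial(N, c/N) while the
reference-reference distances stay frozen.

Distances: p-distance (default; fraction of differing sites) and
Tamura-Nei 1993, optionally with a gamma rate-variation correction of
shape ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import AlignedQuery, MISSING, ReferenceAlignment, encode_sequence

DEFAULT_MIN_OVERLAP = 20
DEFAULT_GAMMA_ALPHA = 0.7

_PURINE = (0, 2)  # A, G


class UndefinedDistanceError(ValueError):
    """Too few shared unambiguous sites to define a distance."""

    def __init__(self, msg, pair=None):
        super().__init__(msg)
        self.pair = pair


class SaturationError(ValueError):
    """A correction's logarithm/power argument is non-positive."""

    def __init__(self, msg, pair=None):
        super().__init__(msg)
        self.pair = pair


@dataclass
class PairCounts:
    """4x4 counts of (baseA, baseB) over jointly unambiguous columns."""

    c: np.ndarray
    ids: tuple | None = None

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.int64).reshape(4, 4)
        if (self.c < 0).any():
            raise ValueError("negative pair counts")

    @property
    def N(self) -> int:
        return int(self.c.sum())

    @property
    def n_matches(self) -> int:
        return int(np.trace(self.c))


@dataclass
class DistanceMatrix:
    ids: list[str]
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix not symmetric")
        if not np.isfinite(D).all() or (np.diag(D) != 0).any() or (D < 0).any():
            raise ValueError("distances must be finite, >= 0, zero diagonal")
        self.D = D

    def to_phylip(self, path_or_file) -> None:
        close = not hasattr(path_or_file, "write")
        fh = open(path_or_file, "w") if close else path_or_file
        try:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.10f}" for x in self.D[i])
                fh.write(f"{name:<10s} {row}\n")
        finally:
            if close:
                fh.close()

    def to_tsv(self, path_or_file) -> None:
        import pandas as pd

        pd.DataFrame(self.D, index=self.ids, columns=self.ids).to_csv(
            path_or_file, sep="\t"
        )


def pair_counts(seq_a, seq_b, ids=None) -> PairCounts:
    """Pair counts for two equal-length aligned sequences (strings or codes)."""
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in aligned length")
    valid = (a != MISSING) & (b != MISSING)
    c = np.bincount(a[valid].astype(np.int64) * 4 + b[valid], minlength=16)
    return PairCounts(c.reshape(4, 4), ids=ids)


def p_distance(pc: PairCounts, min_overlap: int = 1) -> float:
    """(sites different)/(sites compared); pairwise deletion."""
    N = pc.N
    if N < max(min_overlap, 1):
        raise UndefinedDistanceError(
            f"only {N} shared unambiguous sites (< {max(min_overlap, 1)}) "
            f"for pair {pc.ids}",
            pair=pc.ids,
        )
    return (N - pc.n_matches) / N


def tn93_distance(
    pc: PairCounts, gamma_alpha: float | None = None, min_overlap: int = 1
) -> float:
    """Tamura-Nei (1993) distance, optionally gamma-corrected.

    Base frequencies are estimated from the pair itself (average of the two
    sequences).  Raises :class:`SaturationError` when a log/power argument is
    non-positive, which happens for highly diverged pairs — the practical
    reason the package defaults to p-distance.
    """
    N = pc.N
    if N < max(min_overlap, 1):
        raise UndefinedDistanceError(
            f"only {N} shared unambiguous sites (< {max(min_overlap, 1)}) "
            f"for pair {pc.ids}",
            pair=pc.ids,
        )
    c = pc.c
    pi = (c.sum(axis=0) + c.sum(axis=1)) / (2.0 * N)
    piA, piC, piG, piT = pi
    gR, gY = piA + piG, piC + piT
    P1 = (c[0, 2] + c[2, 0]) / N  # A<->G transitions
    P2 = (c[1, 3] + c[3, 1]) / N  # C<->T transitions
    q_mask = np.zeros((4, 4), dtype=bool)
    for i in _PURINE:
        for j in (1, 3):
            q_mask[i, j] = q_mask[j, i] = True
    Q = c[q_mask].sum() / N  # transversions

    terms = []  # (coefficient k, log argument w)
    if piA * piG > 0 and gR > 0:
        terms.append((2 * piA * piG / gR, 1 - gR * P1 / (2 * piA * piG) - Q / (2 * gR)))
    elif P1 > 0:
        raise SaturationError("A/G transitions with zero A/G frequency", pair=pc.ids)
    if piC * piT > 0 and gY > 0:
        terms.append((2 * piC * piT / gY, 1 - gY * P2 / (2 * piC * piT) - Q / (2 * gY)))
    elif P2 > 0:
        raise SaturationError("C/T transitions with zero C/T frequency", pair=pc.ids)
    if gR * gY > 0:
        k3 = 2 * (gR * gY - piA * piG * gY / gR - piC * piT * gR / gY)
        terms.append((k3, 1 - Q / (2 * gR * gY)))
    elif Q > 0:
        raise SaturationError("transversions with degenerate frequencies", pair=pc.ids)

    d = 0.0
    for k, w in terms:
        if w <= 0:
            raise SaturationError(
                f"saturated pair {pc.ids}: TN93 log argument {w:.4g} <= 0",
                pair=pc.ids,
            )
        if k == 0:
            continue
        if gamma_alpha is None:
            d += -k * np.log(w)
        else:
            d += k * gamma_alpha * (w ** (-1.0 / gamma_alpha) - 1.0)
    return max(float(d), 0.0)


def _distance_from_counts(c16: np.ndarray, measure, gamma_alpha, min_overlap, ids):
    pc = PairCounts(c16, ids=ids)
    if measure == "p":
        return p_distance(pc, min_overlap)
    if measure == "tn93":
        return tn93_distance(pc, None, min_overlap)
    if measure == "tn93g":
        return tn93_distance(pc, gamma_alpha, min_overlap)
    raise ValueError(f"unknown distance measure {measure!r}")


def ref_distance_matrix(
    aln: ReferenceAlignment,
    measure: str = "p",
    gamma_alpha: float = DEFAULT_GAMMA_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All pairwise distances among reference sequences.

    Computed once per analysis; every read and every bootstrap replicate
    reuses it unchanged.
    """
    codes = aln.codes()
    n = aln.n_seqs
    if n < 4:
        raise ValueError("need at least 4 reference sequences")
    D = np.zeros((n, n))
    if measure == "p":
        ok = codes != MISSING
        for i in range(n - 1):
            valid = ok[i] & ok[i + 1 :]
            N = valid.sum(axis=1)
            too_few = N < max(min_overlap, 1)
            if too_few.any():
                j = i + 1 + int(np.flatnonzero(too_few)[0])
                raise UndefinedDistanceError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) shares only "
                    f"{int(N[j - i - 1])} unambiguous sites",
                    pair=(aln.ids[i], aln.ids[j]),
                )
            diff = (valid & (codes[i] != codes[i + 1 :])).sum(axis=1)
            D[i, i + 1 :] = diff / N
        D = D + D.T
    else:
        for i in range(n - 1):
            for j in range(i + 1, n):
                c = _pair_counts_codes(codes[i], codes[j])
                D[i, j] = D[j, i] = _distance_from_counts(
                    c, measure, gamma_alpha, min_overlap, (aln.ids[i], aln.ids[j])
                )
    return DistanceMatrix(list(aln.ids), D)


def _pair_counts_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    valid = (a != MISSING) & (b != MISSING)
    return np.bincount(a[valid].astype(np.int64) * 4 + b[valid], minlength=16)


def query_pair_counts(q: AlignedQuery, aln: ReferenceAlignment) -> np.ndarray:
    """(n_refs, 16) pair counts of (reference base, read base) per reference."""
    if q.n_covered == 0:
        raise UndefinedDistanceError(f"read {q.id!r} covers no columns", pair=(q.id,))
    refsub = aln.codes()[:, q.cols]
    qc = q.codes()
    n = aln.n_seqs
    out = np.zeros((n, 16), dtype=np.int64)
    for k in range(n):
        valid = refsub[k] != MISSING
        out[k] = np.bincount(
            refsub[k, valid].astype(np.int64) * 4 + qc[valid], minlength=16
        )
    return out


def distances_from_query_counts(
    counts16: np.ndarray,
    ids,
    qid,
    measure: str = "p",
    gamma_alpha: float = DEFAULT_GAMMA_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    impute_max: bool = False,
) -> np.ndarray:
    """Read-to-reference distance vector from per-reference pair counts."""
    n = counts16.shape[0]
    d = np.empty(n)
    if measure == "p":
        N = counts16.sum(axis=1)
        match = counts16[:, (0, 5, 10, 15)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(N > 0, (N - match) / np.maximum(N, 1), np.nan)
        bad = N < max(min_overlap, 1)
    else:
        bad = np.zeros(n, dtype=bool)
        for k in range(n):
            try:
                d[k] = _distance_from_counts(
                    counts16[k], measure, gamma_alpha, min_overlap, (ids[k], qid)
                )
            except (UndefinedDistanceError, SaturationError):
                d[k] = np.nan
                bad[k] = True
    if bad.any():
        if not impute_max:
            k = int(np.flatnonzero(bad)[0])
            raise UndefinedDistanceError(
                f"read {qid!r} vs reference {ids[k]!r}: distance undefined "
                f"(insufficient overlap or saturation); use impute_max to proceed",
                pair=(ids[k], qid),
            )
        finite = d[~bad]
        if finite.size == 0:
            raise UndefinedDistanceError(
                f"read {qid!r}: no reference pair yields a defined distance",
                pair=(qid,),
            )
        d[bad] = finite.max()
    return d


def query_distances(
    q: AlignedQuery,
    aln: ReferenceAlignment,
    measure: str = "p",
    gamma_alpha: float = DEFAULT_GAMMA_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    impute_max: bool = False,
) -> np.ndarray:
    """Distances from one read to every reference sequence (read columns only)."""
    counts = query_pair_counts(q, aln)
    return distances_from_query_counts(
        counts, aln.ids, q.id, measure, gamma_alpha, min_overlap, impute_max
    )


def bootstrap_pair_counts(pc: PairCounts, rng: np.random.Generator) -> PairCounts:
    """One multinomial resample of a pair-count matrix (N preserved)."""
    N = pc.N
    if N == 0:
        raise UndefinedDistanceError("cannot resample empty pair counts", pair=pc.ids)
    p = pc.c.ravel() / N
    return PairCounts(rng.multinomial(N, p).reshape(4, 4), ids=pc.ids)


def bootstrap_query_counts(
    counts16: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Resample every read-reference pair-count row at once."""
    N = counts16.sum(axis=1)
    if (N == 0).any():
        raise UndefinedDistanceError("cannot resample a pair with zero overlap")
    p = counts16 / N[:, None]
    return rng.multinomial(N, p)
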