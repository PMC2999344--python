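"""Optimal global alignment of three profiles.

The aligner inserts all-gap columns into three fixed group alignments so
that the summed objective over the three pairwise projections is maximal:

* every column contributes the weighted sum-of-pairs substitution score
  Sp(1,2) + Sp(1,3) + Sp(2,3) for the projections where both profiles
  contribute a residue column, and
* affine gap costs are charged independently per pairwise projection — GOP
  when a projection enters a residue-versus-gap run, GEP for each further
  column of the run (quasi-natural convention: a projected gap-versus-gap
  column scores 0 and pays nothing, but a run resuming after one pays a
  fresh GOP; openings are therefore decided by the previous column alone).

Each alignment column has one of seven shapes — rrr, rr-, r-r, -rr, r--,
-r-, --r, where 'r' means the profile contributes a column — and the
dynamic program keeps one score layer per shape, the classical seven-matrix
three-way affine recursion. The hot loop is compiled with numba; a
brute-force enumerator over all legal column-shape sequences serves as an
independent oracle on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .errors import AlignmentError
from .matrices import SubstitutionMatrix
from .profile_io import GAP, Profile, weight_array

#: Column shapes in traceback-preference order, encoded as 3-bit integers
#: (bit 2 = profile 1 contributes, bit 1 = profile 2, bit 0 = profile 3).
SHAPE_ORDER = (0b111, 0b110, 0b101, 0b011, 0b100, 0b010, 0b001)

_BRUTE_FORCE_MAX_LEN = 6


def shape_string(shape: int) -> str:
    return "".join(
        "r" if (shape >> b) & 1 else "-" for b in (2, 1, 0)
    )


@dataclass(frozen=True)
class AlignParams:
    """Affine gap parameters and the substitution matrix.

    ``gap_open`` (GOP) is charged when a pairwise projection enters a
    residue-vs-gap run; ``gap_extend`` (GEP) per additional run column.
    With ``end_gaps_free`` set, runs touching either end of a projection
    cost nothing.
    """

    matrix: SubstitutionMatrix
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise AlignmentError(
                f"gap penalties must satisfy gap_open >= gap_extend >= 0, "
                f"got GOP={self.gap_open}, GEP={self.gap_extend}"
            )


@dataclass(frozen=True)
class ThreeAlignment:
    """Three mutually aligned profiles sharing one column count."""

    profiles: tuple[Profile, Profile, Profile]
    score: float
    column_types: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {p.length for p in self.profiles}
        if len(lengths) != 1:
            raise AlignmentError(
                f"aligned profiles disagree on column count: {sorted(lengths)}"
            )
        if len(self.column_types) != self.profiles[0].length:
            raise AlignmentError("column_types length does not match alignment")
        if any(ct == "---" for ct in self.column_types):
            raise AlignmentError("alignment contains an all-gap '---' column")

    @property
    def length(self) -> int:
        return self.profiles[0].length


def profile_pair_score(
    px_col: Sequence[str],
    py_col: Sequence[str],
    wx: Sequence[float],
    py_w: Sequence[float],
    matrix: SubstitutionMatrix,
) -> float:
    """Weighted sum-of-pairs substitution score of two profile columns.

    Sp = sum over sequence pairs (a, b) of W_a * W_b * M[r_x(a), r_y(b)];
    any pair involving a gap symbol inside a profile column contributes 0
    (alignment-level gap columns are costed by GOP/GEP, so intra-profile
    gaps must not be charged again).
    """
    total = 0.0
    for a, wa in zip(px_col, wx):
        if a == GAP:
            continue
        for b, wb in zip(py_col, py_w):
            if b == GAP:
                continue
            total += wa * wb * matrix.score(a, b)
    return total


def _encode_profile(profile: Profile, matrix: SubstitutionMatrix) -> np.ndarray:
    """(m, L) symbol-index array; gaps get index len(alphabet)."""
    nsym = len(matrix.alphabet)
    out = np.empty((profile.n_sequences, profile.length), dtype=np.int64)
    for a, seq in enumerate(profile.sequences):
        for i, sym in enumerate(seq):
            out[a, i] = nsym if sym == GAP else matrix.index_of(sym)
    return out


def _weighted_column_counts(
    profile: Profile, matrix: SubstitutionMatrix
) -> np.ndarray:
    """(L, nsym+1) weighted symbol counts per column (gap in last slot)."""
    nsym = len(matrix.alphabet)
    enc = _encode_profile(profile, matrix)
    w = weight_array(profile)
    counts = np.zeros((profile.length, nsym + 1), dtype=np.float64)
    cols = np.arange(profile.length)
    for a in range(profile.n_sequences):
        np.add.at(counts, (cols, enc[a]), w[a])
    return counts


def pair_score_tensor(
    px: Profile, py: Profile, matrix: SubstitutionMatrix
) -> np.ndarray:
    """All-against-all column Sp scores, SP[i, j] = Sp(px col i, py col j)."""
    nsym = len(matrix.alphabet)
    m_ext = np.zeros((nsym + 1, nsym + 1), dtype=np.float64)
    m_ext[:nsym, :nsym] = matrix.scores
    ax = _weighted_column_counts(px, matrix)
    ay = _weighted_column_counts(py, matrix)
    return ax @ m_ext @ ay.T


def _pair_gap_cost(
    bx: int,
    by: int,
    tbx: int,
    tby: int,
    has_prev: bool,
    cx: int,
    lx: int,
    cy: int,
    ly: int,
    gop: float,
    gep: float,
    free_end: bool,
) -> float:
    """Gap charge of one pairwise projection for one new column.

    ``bx/by``: residue bits of the new column for the two profiles;
    ``tbx/tby``: same for the previous column; ``cx/cy``: columns of each
    profile consumed up to and including the new column.
    """
    if bx == by:
        return 0.0
    if bx == 1:  # gap in profile y
        if free_end and (cy == 0 or cy == ly):
            return 0.0
        if has_prev and tbx == 1 and tby == 0:
            return gep
        return gop
    # gap in profile x
    if free_end and (cx == 0 or cx == lx):
        return 0.0
    if has_prev and tbx == 0 and tby == 1:
        return gep
    return gop


def _column_gap_cost(
    shape: int,
    prev_shape: int,
    counts: tuple[int, int, int],
    lengths: tuple[int, int, int],
    params: AlignParams,
) -> float:
    """Total gap charge of one column over the three pairwise projections.

    ``prev_shape`` is 0 when this is the first column. ``counts`` are the
    consumed column counts after this column.
    """
    b1, b2, b3 = (shape >> 2) & 1, (shape >> 1) & 1, shape & 1
    t1, t2, t3 = (prev_shape >> 2) & 1, (prev_shape >> 1) & 1, prev_shape & 1
    has_prev = prev_shape != 0
    i, j, k = counts
    l1, l2, l3 = lengths
    gop, gep, free = params.gap_open, params.gap_extend, params.end_gaps_free
    cost = _pair_gap_cost(b1, b2, t1, t2, has_prev, i, l1, j, l2, gop, gep, free)
    cost += _pair_gap_cost(b1, b3, t1, t3, has_prev, i, l1, k, l3, gop, gep, free)
    cost += _pair_gap_cost(b2, b3, t2, t3, has_prev, j, l2, k, l3, gop, gep, free)
    return cost


@njit(cache=False)
def _dp_kernel(sp12, sp13, sp23, gop, gep, free_end, l1, l2, l3):  # pragma: no cover - exercised via align_three
    neg = -1e30
    v = np.full((8, l1 + 1, l2 + 1, l3 + 1), neg)
    ptr = np.full((8, l1 + 1, l2 + 1, l3 + 1), -1, dtype=np.int8)
    v[0, 0, 0, 0] = 0.0
    order = np.array([7, 6, 5, 3, 4, 2, 1], dtype=np.int64)
    taus = np.array([0, 7, 6, 5, 3, 4, 2, 1], dtype=np.int64)
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            for k in range(l3 + 1):
                if i == 0 and j == 0 and k == 0:
                    continue
                for si in range(7):
                    s = order[si]
                    b1 = (s >> 2) & 1
                    b2 = (s >> 1) & 1
                    b3 = s & 1
                    if i < b1 or j < b2 or k < b3:
                        continue
                    pi = i - b1
                    pj = j - b2
                    pk = k - b3
                    sub = 0.0
                    if b1 == 1 and b2 == 1:
                        sub += sp12[i - 1, j - 1]
                    if b1 == 1 and b3 == 1:
                        sub += sp13[i - 1, k - 1]
                    if b2 == 1 and b3 == 1:
                        sub += sp23[j - 1, k - 1]
                    best = neg
                    bestp = -1
                    for ti in range(8):
                        t = taus[ti]
                        prev = v[t, pi, pj, pk]
                        if prev <= neg / 2:
                            continue
                        has_prev = t != 0
                        tb1 = (t >> 2) & 1
                        tb2 = (t >> 1) & 1
                        tb3 = t & 1
                        cost = 0.0
                        if b1 != b2:
                            if b1 == 1:
                                if free_end and (j == 0 or j == l2):
                                    pass
                                elif has_prev and tb1 == 1 and tb2 == 0:
                                    cost += gep
                                else:
                                    cost += gop
                            else:
                                if free_end and (i == 0 or i == l1):
                                    pass
                                elif has_prev and tb1 == 0 and tb2 == 1:
                                    cost += gep
                                else:
                                    cost += gop
                        if b1 != b3:
                            if b1 == 1:
                                if free_end and (k == 0 or k == l3):
                                    pass
                                elif has_prev and tb1 == 1 and tb3 == 0:
                                    cost += gep
                                else:
                                    cost += gop
                            else:
                                if free_end and (i == 0 or i == l1):
                                    pass
                                elif has_prev and tb1 == 0 and tb3 == 1:
                                    cost += gep
                                else:
                                    cost += gop
                        if b2 != b3:
                            if b2 == 1:
                                if free_end and (k == 0 or k == l3):
                                    pass
                                elif has_prev and tb2 == 1 and tb3 == 0:
                                    cost += gep
                                else:
                                    cost += gop
                            else:
                                if free_end and (j == 0 or j == l2):
                                    pass
                                elif has_prev and tb2 == 0 and tb3 == 1:
                                    cost += gep
                                else:
                                    cost += gop
                        cand = prev + sub - cost
                        if cand > best:
                            best = cand
                            bestp = t
                    v[s, i, j, k] = best
                    ptr[s, i, j, k] = bestp
    return v, ptr


def _build_alignment(
    p1: Profile,
    p2: Profile,
    p3: Profile,
    shapes: Sequence[int],
    score: float,
) -> ThreeAlignment:
    """Insert all-gap columns per the shape sequence and package the result."""
    profiles = []
    for idx, p in enumerate((p1, p2, p3)):
        bit = 2 - idx
        rows = ["" for _ in range(p.n_sequences)]
        consumed = 0
        for s in shapes:
            if (s >> bit) & 1:
                for a in range(p.n_sequences):
                    rows[a] += p.sequences[a][consumed]
                consumed += 1
            else:
                for a in range(p.n_sequences):
                    rows[a] += GAP
        if consumed != p.length:
            raise AlignmentError(
                f"shape sequence consumes {consumed} columns of profile "
                f"{p.label!r}, which has {p.length}"
            )
        profiles.append(
            Profile(
                p.ids,
                tuple(rows),
                p.weights,
                label=p.label,
                allow_gap_columns=True,
            )
        )
    return ThreeAlignment(
        profiles=tuple(profiles),
        score=float(score),
        column_types=tuple(shape_string(s) for s in shapes),
    )


def align_three(
    p1: Profile, p2: Profile, p3: Profile, params: AlignParams
) -> ThreeAlignment:
    """Globally align three profiles by seven-state affine dynamic programming.

    Returns the optimal :class:`ThreeAlignment` under the module objective.
    Ties are broken deterministically, preferring column shapes in the order
    rrr > rr- > r-r > -rr > r-- > -r- > --r.
    """
    sp12 = pair_score_tensor(p1, p2, params.matrix)
    sp13 = pair_score_tensor(p1, p3, params.matrix)
    sp23 = pair_score_tensor(p2, p3, params.matrix)
    l1, l2, l3 = p1.length, p2.length, p3.length
    v, ptr = _dp_kernel(
        sp12,
        sp13,
        sp23,
        float(params.gap_open),
        float(params.gap_extend),
        params.end_gaps_free,
        l1,
        l2,
        l3,
    )
    best_shape = -1
    best = -np.inf
    for s in SHAPE_ORDER:
        val = v[s, l1, l2, l3]
        if val > best:
            best = val
            best_shape = s
    if best <= -1e29:
        raise AlignmentError("dynamic program found no complete alignment")
    shapes: list[int] = []
    i, j, k = l1, l2, l3
    cur = best_shape
    while cur != 0:
        shapes.append(cur)
        t = int(ptr[cur, i, j, k])
        i -= (cur >> 2) & 1
        j -= (cur >> 1) & 1
        k -= cur & 1
        cur = t
    if (i, j, k) != (0, 0, 0):
        raise AlignmentError("traceback did not reach the origin")
    shapes.reverse()
    return _build_alignment(p1, p2, p3, shapes, float(best))


def _score_shapes(
    shapes: Sequence[int],
    sp12: np.ndarray,
    sp13: np.ndarray,
    sp23: np.ndarray,
    lengths: tuple[int, int, int],
    params: AlignParams,
) -> float:
    """Objective value of a complete column-shape sequence."""
    i = j = k = 0
    prev = 0
    total = 0.0
    for s in shapes:
        b1, b2, b3 = (s >> 2) & 1, (s >> 1) & 1, s & 1
        i += b1
        j += b2
        k += b3
        if b1 and b2:
            total += sp12[i - 1, j - 1]
        if b1 and b3:
            total += sp13[i - 1, k - 1]
        if b2 and b3:
            total += sp23[j - 1, k - 1]
        total -= _column_gap_cost(s, prev, (i, j, k), lengths, params)
        prev = s
    if (i, j, k) != lengths:
        raise AlignmentError("shape sequence does not consume all profiles")
    return total


def brute_force_align(
    p1: Profile, p2: Profile, p3: Profile, params: AlignParams
) -> ThreeAlignment:
    """Exhaustive-enumeration reference aligner for tiny inputs.

    Enumerates every legal sequence of column shapes consuming all columns
    of all three profiles, scores each with the same objective as
    :func:`align_three`, and returns an argmax. Guarded to profile lengths
    of at most 6 columns.
    """
    lengths = (p1.length, p2.length, p3.length)
    if max(lengths) > _BRUTE_FORCE_MAX_LEN:
        raise AlignmentError(
            f"brute_force_align is limited to profiles of length "
            f"<= {_BRUTE_FORCE_MAX_LEN}, got {lengths}"
        )
    matrix = params.matrix
    sp12 = np.array(
        [
            [
                profile_pair_score(
                    p1.column(i), p2.column(j), p1.weights, p2.weights, matrix
                )
                for j in range(p2.length)
            ]
            for i in range(p1.length)
        ]
    ).reshape(p1.length, p2.length)
    sp13 = np.array(
        [
            [
                profile_pair_score(
                    p1.column(i), p3.column(k), p1.weights, p3.weights, matrix
                )
                for k in range(p3.length)
            ]
            for i in range(p1.length)
        ]
    ).reshape(p1.length, p3.length)
    sp23 = np.array(
        [
            [
                profile_pair_score(
                    p2.column(j), p3.column(k), p2.weights, p3.weights, matrix
                )
                for k in range(p3.length)
            ]
            for j in range(p2.length)
        ]
    ).reshape(p2.length, p3.length)
    l1, l2, l3 = lengths
    gop, gep, free = params.gap_open, params.gap_extend, params.end_gaps_free

    best_score = -np.inf
    best_path: list[int] | None = None
    path: list[int] = []

    def dfs(i: int, j: int, k: int, prev: int, acc: float) -> None:
        nonlocal best_score, best_path
        if i == l1 and j == l2 and k == l3:
            if acc > best_score:
                best_score = acc
                best_path = path.copy()
            return
        for s in SHAPE_ORDER:
            b1, b2, b3 = (s >> 2) & 1, (s >> 1) & 1, s & 1
            ni, nj, nk = i + b1, j + b2, k + b3
            if ni > l1 or nj > l2 or nk > l3:
                continue
            gain = 0.0
            if b1 and b2:
                gain += sp12[ni - 1, nj - 1]
            if b1 and b3:
                gain += sp13[ni - 1, nk - 1]
            if b2 and b3:
                gain += sp23[nj - 1, nk - 1]
            t1, t2, t3 = (prev >> 2) & 1, (prev >> 1) & 1, prev & 1
            has_prev = prev != 0
            gain -= _pair_gap_cost(
                b1, b2, t1, t2, has_prev, ni, l1, nj, l2, gop, gep, free
            )
            gain -= _pair_gap_cost(
                b1, b3, t1, t3, has_prev, ni, l1, nk, l3, gop, gep, free
            )
            gain -= _pair_gap_cost(
                b2, b3, t2, t3, has_prev, nj, l2, nk, l3, gop, gep, free
            )
            path.append(s)
            dfs(ni, nj, nk, s, acc + gain)
            path.pop()

    dfs(0, 0, 0, 0, 0.0)
    assert best_path is not None  # at least one legal sequence always exists
    return _build_alignment(p1, p2, p3, best_path, best_score)


def rescore(alignment: ThreeAlignment, params: AlignParams) -> float:
    """Recompute the alignment objective from the columns alone.

    Independent of any DP internals: the shape of each column is re-derived
    from its content (a profile contributes unless its column is all gaps),
    substitution terms use :func:`profile_pair_score`, and gap runs are
    re-charged by scanning the column sequence.
    """
    p1, p2, p3 = alignment.profiles
    lengths = {p.length for p in (p1, p2, p3)}
    if len(lengths) != 1:
        raise AlignmentError("malformed alignment: unequal column counts")
    n_cols = lengths.pop()
    col_bits: list[tuple[int, int, int]] = []
    for col in range(n_cols):
        cols = [p.column(col) for p in (p1, p2, p3)]
        bits = tuple(0 if all(sym == GAP for sym in c) else 1 for c in cols)
        if bits == (0, 0, 0):
            raise AlignmentError(
                f"malformed alignment: column {col + 1} is all gaps in every profile"
            )
        col_bits.append(bits)
    # Input profile lengths, recovered from content (columns each profile
    # actually contributes), so trailing end-gap detection needs no metadata.
    in_lengths = tuple(
        sum(b[idx] for b in col_bits) for idx in range(3)
    )
    consumed = [0, 0, 0]
    prev = 0
    total = 0.0
    for col in range(n_cols):
        cols = [p.column(col) for p in (p1, p2, p3)]
        bits = col_bits[col]
        shape = (bits[0] << 2) | (bits[1] << 1) | bits[2]
        for idx in range(3):
            consumed[idx] += bits[idx]
        if bits[0] and bits[1]:
            total += profile_pair_score(
                cols[0], cols[1], p1.weights, p2.weights, params.matrix
            )
        if bits[0] and bits[2]:
            total += profile_pair_score(
                cols[0], cols[2], p1.weights, p3.weights, params.matrix
            )
        if bits[1] and bits[2]:
            total += profile_pair_score(
                cols[1], cols[2], p2.weights, p3.weights, params.matrix
            )
        total -= _column_gap_cost(
            shape, prev, tuple(consumed), in_lengths, params
        )
        prev = shape
    return total
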