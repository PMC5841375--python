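"""Pairwise sequence alignment with free terminal gaps.

Implements semi-global (ends-free) affine-gap alignment — the identity
semantics used throughout clustering: terminal gap runs cost nothing and
are excluded from the identity denominator, so reads of unequal length
(e.g. an orphan forward read against a 250 bp centroid segment) are
compared only over the columns where both sequences are present.

Scoring: match +1, mismatch -2, gap open -10, gap extend -1 (the first
gapped base costs open + extend). The heavy gap penalties reflect that
substitution errors dominate indels on the target platform.

The dynamic program is numba-jitted; sequences are encoded as uint8
arrays before entering the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = -10
GAP_EXTEND = -1

NEG_INF = np.int32(-(10**8))

OP_DIAG = 0  # consume one base of each
OP_UP = 1    # gap in b (consume a)
OP_LEFT = 2  # gap in a (consume b)


@dataclass
class AlignmentResult:
    matches: int
    aligned_columns: int
    identity: float
    ops: np.ndarray        # int8 op codes, start -> end, internal columns only
    a_start: int           # offset of the first aligned base in a
    b_start: int
    score: int

    def __post_init__(self) -> None:
        if self.aligned_columns:
            assert abs(self.identity - self.matches / self.aligned_columns) < 1e-12
        assert self.matches <= self.aligned_columns


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP).decode("ascii")[::-1]


@njit(cache=True)
def _gotoh_endsfree(a, b):  # pragma: no cover - exercised via align_endsfree
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in b
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in a
    # free terminal gaps: any boundary cell is a valid, zero-cost start
    for i in range(n + 1):
        M[i, 0] = 0
    for j in range(m + 1):
        M[0, j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + s
            xo = M[i - 1, j] + GAP_OPEN + GAP_EXTEND
            if Y[i - 1, j] + GAP_OPEN + GAP_EXTEND > xo:
                xo = Y[i - 1, j] + GAP_OPEN + GAP_EXTEND
            if X[i - 1, j] + GAP_EXTEND > xo:
                xo = X[i - 1, j] + GAP_EXTEND
            X[i, j] = xo
            yo = M[i, j - 1] + GAP_OPEN + GAP_EXTEND
            if X[i, j - 1] + GAP_OPEN + GAP_EXTEND > yo:
                yo = X[i, j - 1] + GAP_OPEN + GAP_EXTEND
            if Y[i, j - 1] + GAP_EXTEND > yo:
                yo = Y[i, j - 1] + GAP_EXTEND
            Y[i, j] = yo
    # best end on the last row or column (trailing gaps free)
    best = NEG_INF
    bi = n
    bj = m
    for j in range(m + 1):
        v = M[n, j]
        if v >= best:
            best = v
            bi = n
            bj = j
    for i in range(n + 1):
        v = M[i, m]
        if v >= best:
            best = v
            bi = i
            bj = m
    # traceback through the M/X/Y states
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=M, 1=X, 2=Y
    matches = 0
    while i > 0 and j > 0:
        if state == 0:
            if M[i, j] == 0 and (i == 0 or j == 0):
                break
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if a[i - 1] == b[j - 1]:
                matches += 1
            ops[k] = OP_DIAG
            k += 1
            prev = M[i, j] - s
            if M[i - 1, j - 1] == prev:
                state = 0
            elif X[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
            # a zero-score boundary start ends the aligned region
            if state == 0 and (i == 0 or j == 0) and M[i, j] == 0:
                break
        elif state == 1:
            ops[k] = OP_UP
            k += 1
            if X[i - 1, j] + GAP_EXTEND == X[i, j]:
                state = 1
            elif M[i - 1, j] + GAP_OPEN + GAP_EXTEND == X[i, j]:
                state = 0
            else:
                state = 2
            i -= 1
        else:
            ops[k] = OP_LEFT
            k += 1
            if Y[i, j - 1] + GAP_EXTEND == Y[i, j]:
                state = 2
            elif M[i, j - 1] + GAP_OPEN + GAP_EXTEND == Y[i, j]:
                state = 0
            else:
                state = 1
            j -= 1
    return best, matches, k, i, j, ops[:k][::-1].copy()


def align_endsfree(a: str, b: str) -> AlignmentResult:
    """Optimal ends-free affine-gap alignment of two DNA strings.

    Identity is matches / internal columns; terminal gap runs are free and
    excluded. Raises on empty input.
    """
    if not a or not b:
        raise ValueError("align_endsfree requires nonempty sequences")
    ea, eb = encode(a), encode(b)
    score, matches, ncols, a_start, b_start, ops = _gotoh_endsfree(ea, eb)
    identity = matches / ncols if ncols else 0.0
    return AlignmentResult(
        matches=int(matches),
        aligned_columns=int(ncols),
        identity=float(identity),
        ops=ops,
        a_start=int(a_start),
        b_start=int(b_start),
        score=int(score),
    )


def match_profile(a: str, b: str) -> np.ndarray:
    """Boolean array over positions of ``a``: aligned to an equal base in ``b``.

    Positions of ``a`` inside terminal gaps (unaligned overhangs) are False.
    Equal-length inputs take a direct positionwise-comparison fast path,
    identical to the DP result when the optimal alignment is gapless.
    """
    if len(a) == len(b):
        return encode(a) == encode(b)
    res = align_endsfree(a, b)
    prof = np.zeros(len(a), dtype=bool)
    i = res.a_start
    j = res.b_start
    for op in res.ops:
        if op == OP_DIAG:
            prof[i] = a[i] == b[j]
            i += 1
            j += 1
        elif op == OP_UP:
            i += 1
        else:
            j += 1
    return prof


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Gapless identity of two equal-length encoded sequences."""
    if a.shape[0] != b.shape[0]:
        raise ValueError("hamming_identity requires equal lengths")
    return float(np.count_nonzero(a == b)) / a.shape[0]
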