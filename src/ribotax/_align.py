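"""Global nucleotide alignment with affine gaps and free end gaps.

This is the single scorer used for consensus similarity, OTU clustering and
species assignment, so determinism matters: among score-optimal alignments the
one with the most identical columns (then the fewest columns) is selected via
tiny lexicographic perturbations. Score contributions are multiples of 0.5
(match 5, mismatch -4, N -2, gap 10/0.5), the match bonus is 1e-4 and the
per-column penalty 1e-8, so the perturbation can never flip score optimality
for sequences up to several thousand bases.

A gap run of length L costs gap_open + (L-1) * gap_extend; runs touching either
end of the alignment are free when end_gaps_free is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MATCH_BONUS = 1e-4
_COL_PENALTY = 1e-8
_NEG = -1e30

# state codes
_M, _X, _Y = 0, 1, 2  # diagonal, gap-in-b (consumes a), gap-in-a (consumes b)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string; anything outside A/C/G/T behaves like N."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _fill(a, b, match, mismatch, n_score, gap_open, gap_extend, end_gaps_free,
          jlo, jhi):
    # Cells with j outside [i + jlo, i + jhi] are excluded (banded mode); with
    # jlo = -lb, jhi = lb the band covers everything. Matrices are allocated
    # uninitialized; every cell a transition can read is explicitly seeded.
    la = a.shape[0]
    lb = b.shape[0]
    M = np.empty((la + 1, lb + 1))
    X = np.empty((la + 1, lb + 1))
    Y = np.empty((la + 1, lb + 1))
    PM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    hi0 = min(lb, jhi + 1)
    for j in range(hi0 + 1):  # row 0
        M[0, j] = _NEG
        X[0, j] = _NEG
        Y[0, j] = _NEG
    M[0, 0] = 0.0
    for i in range(la + 1):  # column 0
        M[i, 0] = _NEG
        Y[i, 0] = _NEG
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        if end_gaps_free:
            X[i, 0] = -_COL_PENALTY * i
        else:
            X[i, 0] = -(gap_open + (i - 1) * gap_extend) - _COL_PENALTY * i
        PX[i, 0] = _M if i == 1 else _X
    for j in range(1, hi0 + 1):
        if end_gaps_free:
            Y[0, j] = -_COL_PENALTY * j
        else:
            Y[0, j] = -(gap_open + (j - 1) * gap_extend) - _COL_PENALTY * j
        PY[0, j] = _M if j == 1 else _Y
    for i in range(1, la + 1):
        ai = a[i - 1]
        lo = i + jlo
        hi = i + jhi
        if lo < 1:
            lo = 1
        if lo > lb + 1:
            lo = lb + 1  # row entirely outside: loop below is empty
        if hi > lb:
            hi = lb
        if lo > 1:  # seed the cell left of the band start
            M[i, lo - 1] = _NEG
            X[i, lo - 1] = _NEG
            Y[i, lo - 1] = _NEG
        if 0 <= hi < lb:  # seed the cell right of the band end (read by row i+1)
            M[i, hi + 1] = _NEG
            X[i, hi + 1] = _NEG
            Y[i, hi + 1] = _NEG
        for j in range(lo, hi + 1):
            bj = b[j - 1]
            if ai >= 4 or bj >= 4:
                s = n_score
            elif ai == bj:
                s = match
            else:
                s = mismatch
            if ai == bj:
                s = s + _MATCH_BONUS
            # M state: preference M, X, Y on ties
            pm = M[i - 1, j - 1]
            px = X[i - 1, j - 1]
            py = Y[i - 1, j - 1]
            best = pm
            arg = _M
            if px > best:
                best = px
                arg = _X
            if py > best:
                best = py
                arg = _Y
            M[i, j] = best + s - _COL_PENALTY
            PM[i, j] = arg
            # X state (gap in b): prefer extension, then M, then Y
            vx = X[i - 1, j] - gap_extend
            vm = M[i - 1, j] - gap_open
            vy = Y[i - 1, j] - gap_open
            best = vx
            arg = _X
            if vm > best:
                best = vm
                arg = _M
            if vy > best:
                best = vy
                arg = _Y
            X[i, j] = best - _COL_PENALTY
            PX[i, j] = arg
            # Y state (gap in a)
            vy = Y[i, j - 1] - gap_extend
            vm = M[i, j - 1] - gap_open
            vx = X[i, j - 1] - gap_open
            best = vy
            arg = _Y
            if vm > best:
                best = vm
                arg = _M
            if vx > best:
                best = vx
                arg = _X
            Y[i, j] = best - _COL_PENALTY
            PY[i, j] = arg
    return M, X, Y, PM, PX, PY


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _fill = njit(cache=True)(_fill)
except Exception:  # pragma: no cover
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise global alignment.

    identity_pct is 100 * n_matches / alignment_length, where alignment_length
    counts every column including gap columns (end gaps too).
    """

    score: float
    identity_pct: float
    alignment_length: int
    n_matches: int
    n_mismatches: int
    n_gap_columns: int
    n_end_gap_columns: int
    aligned_a: str
    aligned_b: str


def align(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    n_score: float = -2.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
    band: int | None = None,
) -> AlignmentResult:
    """Needleman-Wunsch with affine gap runs and (by default) free end gaps.

    With ``band=w`` the DP is restricted to diagonals within w of the main
    diagonal corridor (corrected for the length difference). Any alignment
    whose path leaves the band has more than w gap columns, so banded results
    are exact whenever the optimal alignment has at most w gap columns; scores
    of more-divergent pairs may be underestimated. Callers gating on an
    identity threshold t may therefore use w >= (1 - t) * min(len) + slack and
    keep exact threshold decisions.
    """
    if not a or not b:
        raise ValueError("alignment requires two nonempty sequences")
    ea, eb = encode(a), encode(b)
    la, lb = len(a), len(b)
    if band is None:
        jlo, jhi = -la, lb
    else:
        if band < 0:
            raise ValueError("band must be >= 0")
        jlo = -(band + max(0, la - lb))
        jhi = band + max(0, lb - la)
    M, X, Y, PM, PX, PY = _fill(
        ea, eb, float(match), float(mismatch), float(n_score),
        float(gap_open), float(gap_extend), bool(end_gaps_free),
        jlo, jhi,
    )
    mats = (M, X, Y)

    def in_band(i: int, j: int) -> bool:
        return j == 0 or (i + jlo <= j <= i + jhi)

    # pick the terminal cell
    best_val = _NEG
    best = None
    if end_gaps_free:
        for i in range(la + 1):
            if not in_band(i, lb):
                continue
            for st in (_M, _X, _Y):
                v = mats[st][i, lb] - _COL_PENALTY * (la - i)
                if v > best_val:
                    best_val = v
                    best = (i, lb, st)
        for j in range(lb + 1):
            if not in_band(la, j):
                continue
            for st in (_M, _X, _Y):
                v = mats[st][la, j] - _COL_PENALTY * (lb - j)
                if v > best_val:
                    best_val = v
                    best = (la, j, st)
    else:
        for st in (_M, _X, _Y):
            v = mats[st][la, lb]
            if v > best_val:
                best_val = v
                best = (la, lb, st)
    assert best is not None and best_val > 0.5 * _NEG
    i, j, state = best

    cols_a: list[str] = []
    cols_b: list[str] = []
    charges: list[float] = []  # per-column exact gap charge (0 for diagonal cols)
    diag: list[tuple[str, str]] = []
    # terminal free columns (only reachable when end_gaps_free)
    for k in range(la, i, -1):
        cols_a.append(a[k - 1])
        cols_b.append("-")
        charges.append(0.0)
    for k in range(lb, j, -1):
        cols_a.append("-")
        cols_b.append(b[k - 1])
        charges.append(0.0)
    while i > 0 or j > 0:
        if state == _M:
            if i == 0 or j == 0:
                raise AssertionError("traceback reached edge in M state")
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            charges.append(0.0)
            diag.append((a[i - 1], b[j - 1]))
            state = int(PM[i, j])
            i -= 1
            j -= 1
        elif state == _X:
            prev = int(PX[i, j])
            if end_gaps_free and j == 0:
                charge = 0.0
            else:
                charge = gap_extend if prev == _X else gap_open
            cols_a.append(a[i - 1])
            cols_b.append("-")
            charges.append(charge)
            state = prev
            i -= 1
        else:
            prev = int(PY[i, j])
            if end_gaps_free and i == 0:
                charge = 0.0
            else:
                charge = gap_extend if prev == _Y else gap_open
            cols_a.append("-")
            cols_b.append(b[j - 1])
            charges.append(charge)
            state = prev
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    charges.reverse()

    n_matches = 0
    n_mismatches = 0
    score = 0.0
    for ca, cb in diag:
        xa, xb = ca.upper(), cb.upper()
        if "ACGT".find(xa) < 0 or "ACGT".find(xb) < 0:
            score += n_score
        elif xa == xb:
            score += match
        else:
            score += mismatch
        if xa == xb:
            n_matches += 1
        else:
            n_mismatches += 1
    score -= sum(charges)

    alen = len(cols_a)
    lead = 0
    while lead < alen and (cols_a[lead] == "-" or cols_b[lead] == "-"):
        lead += 1
    trail = 0
    while trail < alen - lead and (
        cols_a[alen - 1 - trail] == "-" or cols_b[alen - 1 - trail] == "-"
    ):
        trail += 1
    n_gap = alen - n_matches - n_mismatches
    return AlignmentResult(
        score=score,
        identity_pct=100.0 * n_matches / alen if alen else 0.0,
        alignment_length=alen,
        n_matches=n_matches,
        n_mismatches=n_mismatches,
        n_gap_columns=n_gap,
        n_end_gap_columns=lead + trail,
        aligned_a="".join(cols_a),
        aligned_b="".join(cols_b),
    )
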