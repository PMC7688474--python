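"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the alignment oracle is an
exhaustive run-enumeration DP in exact integer arithmetic over lexicographic
(score, matches, -columns) tuples, and the component oracle is a transitive
closure over the full adjacency relation.
"""

from __future__ import annotations


def align_oracle(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    n_score: float = -2.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> tuple[float, int, int]:
    """Return (score, n_matches, alignment_columns) of the optimal alignment.

    Enumerates, at every cell, a diagonal step or a *complete* gap run of any
    length in either sequence (cost gap_open + (k-1)*gap_extend, zero for the
    run anchored at the very start when end gaps are free). Trailing free runs
    are applied when selecting the final cell. All arithmetic is exact
    (scores doubled to integers); tuples are compared lexicographically by
    (score, matches, -columns).
    """
    m2, x2, n2 = int(match * 2), int(mismatch * 2), int(n_score * 2)
    go2, ge2 = int(gap_open * 2), int(gap_extend * 2)
    la, lb = len(a), len(b)
    NEG = (-(10 ** 9), 0, 0)
    D = [[NEG] * (lb + 1) for _ in range(la + 1)]
    D[0][0] = (0, 0, 0)

    def run_cost(k: int, leading: bool) -> int:
        if leading and end_gaps_free:
            return 0
        return go2 + (k - 1) * ge2

    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            best = NEG
            if i > 0 and j > 0 and D[i - 1][j - 1] != NEG:
                ca, cb = a[i - 1].upper(), b[j - 1].upper()
                if ca not in "ACGT" or cb not in "ACGT":
                    s = n2
                elif ca == cb:
                    s = m2
                else:
                    s = x2
                sc, mt, nc = D[i - 1][j - 1]
                cand = (sc + s, mt + (1 if ca == cb else 0), nc - 1)
                if cand > best:
                    best = cand
            for k in range(1, i + 1):
                if D[i - k][j] == NEG:
                    continue
                sc, mt, nc = D[i - k][j]
                cand = (sc - run_cost(k, i - k == 0 and j == 0), mt, nc - k)
                if cand > best:
                    best = cand
            for k in range(1, j + 1):
                if D[i][j - k] == NEG:
                    continue
                sc, mt, nc = D[i][j - k]
                cand = (sc - run_cost(k, i == 0 and j - k == 0), mt, nc - k)
                if cand > best:
                    best = cand
            D[i][j] = best
    if end_gaps_free:
        final = NEG
        for i in range(la + 1):
            sc, mt, nc = D[i][lb]
            cand = (sc, mt, nc - (la - i))
            if cand > final:
                final = cand
        for j in range(lb + 1):
            sc, mt, nc = D[la][j]
            cand = (sc, mt, nc - (lb - j))
            if cand > final:
                final = cand
    else:
        final = D[la][lb]
    sc, mt, nc = final
    return sc / 2.0, mt, -nc


def components_oracle(nodes: list, edges: list[tuple]) -> set[frozenset]:
    """Connected components by brute-force transitive closure over all pairs."""
    nodes = list(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for u, v in edges:
        reach[index[u]][index[v]] = True
        reach[index[v]][index[u]] = True
    for _ in range(n):  # iterate closure to a fixed point
        changed = False
        for i in range(n):
            for j in range(n):
                if reach[i][j]:
                    continue
                for k in range(n):
                    if reach[i][k] and reach[k][j]:
                        reach[i][j] = True
                        changed = True
                        break
        if not changed:
            break
    return {
        frozenset(nodes[j] for j in range(n) if reach[i][j]) for i in range(n)
    }
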