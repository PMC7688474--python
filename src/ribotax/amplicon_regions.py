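"""In-silico hypervariable-region extraction by degenerate-primer matching.

Primer sites are located with a semi-global edit-distance DP (substitutions,
insertions, deletions; a substitution is free when the target base is in the
IUPAC expansion of the primer base). The fragment between the two primer loci
is returned with the primers excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Optional, Sequence

from ._dna import IUPAC_EXPANSION, reverse_complement
from .reference_io import LengthFilterPolicy, qc_filter

#: 337F / 806R, targeting V3-V4
DEFAULT_PRIMER_FORWARD = "CCTACGGGAGGCWGCAG"
DEFAULT_PRIMER_REVERSE = "GACTACHVGGGTMTCTAAT"


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; reverse is given 5'->3' on the reverse strand."""

    name: str = "V3V4"
    forward: str = DEFAULT_PRIMER_FORWARD
    reverse: str = DEFAULT_PRIMER_REVERSE
    max_error_rate: float = 0.2

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be nonempty")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        for primer in (self.forward, self.reverse):
            bad = set(primer.upper()) - set(IUPAC_EXPANSION)
            if bad:
                raise ValueError(f"invalid primer characters: {sorted(bad)}")


@dataclass(frozen=True)
class RegionFragment:
    source_id: str
    sequence: str
    fwd_edits: int
    rev_edits: int


@dataclass(frozen=True)
class PrimerHit:
    """Half-open locus [start, end) of the best primer match."""

    start: int
    end: int
    edits: int


def iupac_compatible(primer_base: str, target_base: str) -> bool:
    """True iff target_base is in the expansion of the (degenerate) primer base."""
    try:
        expansion = IUPAC_EXPANSION[primer_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {primer_base!r}") from None
    target = target_base.upper()
    target_exp = IUPAC_EXPANSION.get(target)
    if target_exp is None:
        raise ValueError(f"invalid target base {target_base!r}")
    # degenerate target bases match iff the expansions intersect
    return bool(expansion & target_exp)


def max_allowed_edits(primer: str, rate: float) -> int:
    if not 0.0 <= rate <= 1.0:
        raise ValueError("error rate must be in [0, 1]")
    return floor(rate * len(primer))


def find_primer(seq: str, primer: str, budget: int) -> Optional[PrimerHit]:
    """Locate the substring of seq closest to the primer in edit distance.

    Returns the best locus with distance <= budget, or None. Ties break by
    leftmost start, then shortest span.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    m, n = len(primer), len(seq)
    if n == 0 or m == 0:
        return None
    primer = primer.upper()
    seq = seq.upper()
    compat = [
        [iupac_compatible(p, c) for c in "ACGTN"] for p in primer
    ]
    base_idx = {c: i for i, c in enumerate("ACGTN")}
    seq_idx = [base_idx.get(c, 4) for c in seq]
    # dp[j] = (distance, start) of the best alignment of the primer prefix
    # processed so far against a suffix of seq[:j]
    dist = [0] * (n + 1)
    start = list(range(n + 1))
    for i in range(1, m + 1):
        prev_dist, prev_start = dist, start
        dist = [i] + [0] * n
        start = [0] * (n + 1)
        row_compat = compat[i - 1]
        for j in range(1, n + 1):
            sub = prev_dist[j - 1] + (0 if row_compat[seq_idx[j - 1]] else 1)
            ins = dist[j - 1] + 1       # consume seq base (gap in primer)
            dele = prev_dist[j] + 1     # skip primer base (gap in seq)
            # preference on ties: substitution/diagonal, then deletion, then
            # insertion; combined with start bookkeeping below this yields
            # leftmost-start / shortest-span tie-breaking at the end
            best, s = sub, prev_start[j - 1]
            if dele < best or (dele == best and prev_start[j] < s):
                best, s = dele, prev_start[j]
            if ins < best or (ins == best and start[j - 1] < s):
                best, s = ins, start[j - 1]
            dist[j], start[j] = best, s
    best_hit: Optional[PrimerHit] = None
    for j in range(n + 1):
        if dist[j] > budget:
            continue
        hit = PrimerHit(start=start[j], end=j, edits=dist[j])
        if best_hit is None:
            best_hit = hit
            continue
        key = (hit.edits, hit.start, hit.end - hit.start)
        best_key = (best_hit.edits, best_hit.start, best_hit.end - best_hit.start)
        if key < best_key:
            best_hit = hit
    return best_hit


def extract_region(record, pair: PrimerPair) -> Optional[RegionFragment]:
    """Extract the fragment strictly between the primer loci, primers excluded.

    The forward primer is matched as printed; the reverse primer is matched as
    its reverse complement downstream of the forward locus. Returns None when
    either site is missing or the ordering is violated.
    """
    seq = record.sequence
    fwd_budget = max_allowed_edits(pair.forward, pair.max_error_rate)
    rev_budget = max_allowed_edits(pair.reverse, pair.max_error_rate)
    fwd = find_primer(seq, pair.forward, fwd_budget)
    if fwd is None:
        return None
    downstream = seq[fwd.end:]
    rev = find_primer(downstream, reverse_complement(pair.reverse), rev_budget)
    if rev is None:
        return None
    return RegionFragment(
        source_id=record.id,
        sequence=downstream[: rev.start],
        fwd_edits=fwd.edits,
        rev_edits=rev.edits,
    )


def fragment_qc(fragments: Sequence[RegionFragment], k_sd: float = 2.0) -> list[RegionFragment]:
    """Two-sided k-sd length filter plus ambiguous-base filter; returns kept."""
    if len(fragments) < 2:
        raise ValueError("fragment QC requires at least 2 fragments")
    kept, _dropped = qc_filter(
        fragments, LengthFilterPolicy(k_sd=k_sd, mode="two_sided")
    )
    return kept
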