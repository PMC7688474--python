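"""Small shared nucleotide utilities (IUPAC tables, reverse complement)."""

from __future__ import annotations

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT.update({k.lower(): v.lower() for k, v in _COMPLEMENT.items()})

CANONICAL_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware. Unknown characters raise ValueError."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from None


def has_ambiguous(seq: str) -> bool:
    """True if the sequence contains anything outside A/C/G/T (case-insensitive)."""
    return bool(set(seq.upper()) - CANONICAL_BASES)
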