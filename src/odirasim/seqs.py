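"""Basic DNA sequence container and strand arithmetic.

All coordinates everywhere in the package are 0-based, half-open, on the
top strand, read 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

_ALPHABET = set("ACGTN")
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMP_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def revcomp(bases: str) -> str:
    """Reverse complement of a top-strand string (N maps to N)."""
    return bases.translate(_RC)[::-1]


def complement(bases: str) -> str:
    return bases.translate(_RC)


def is_wc_pair(a: str, b: str) -> bool:
    """True when two single bases form a Watson-Crick pair (N never pairs)."""
    return (a, b) in _COMP_PAIRS


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A, C, G, T, N}.

    ``bases`` is the top strand read 5'->3'.  N is a placeholder that never
    participates in any reported repeat match.
    """

    id: str
    bases: str

    def __post_init__(self):
        if not self.bases:
            raise ParameterError(f"sequence {self.id!r} is empty")
        stray = set(self.bases.upper()) - _ALPHABET
        if stray:
            raise ParameterError(
                f"sequence {self.id!r} contains non-DNA characters {sorted(stray)}"
            )
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, new_id: str | None = None) -> "Sequence":
        return Sequence(new_id or f"{self.id}_rc", revcomp(self.bases))
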