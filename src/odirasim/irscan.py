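"""Detection of short interrupted inverted repeats (IIRs).

An interrupted inverted repeat is a pair of short reverse-complementary
arms (a and a') separated by a non-complementary spacer on the same
strand.  Such elements are the substrate of the replication error modeled
by :mod:`odirasim.engine`: a fork that regresses at an IIR can ligate its
nascent leading strand to the nascent lagging strand, producing a "closed"
fork.  In the yeast genome, 7 bp arms spaced by fewer than 70 bp occur
roughly once every 240 bp, which is what makes the mechanism generic.

The scanner counts every (position, spacer) combination -- overlapping and
nested hits are all reported -- because each arm pair independently
licenses a closed-fork event.  This convention is what reproduces the
closed-form expectation of ``S * 4**-arm_len`` hits per bp on uniform
random sequence (S = number of admissible spacer lengths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import LicensingError, ParameterError
from .seqs import Sequence

__all__ = [
    "InterruptedInvertedRepeat",
    "DensityStats",
    "Origin",
    "scan_interrupted_inverted_repeats",
    "ir_density_stats",
    "pair_irs_flanking_origin",
    "expected_per_bp_rate",
    "expected_pair_count",
]


@dataclass(frozen=True, order=True)
class InterruptedInvertedRepeat:
    """A single arm/spacer/arm hit, 0-based half-open on the top strand."""

    seq_id: str
    left_arm_start: int
    spacer_len: int
    arm_len: int
    mismatches: int = 0

    @property
    def right_arm_start(self) -> int:
        return self.left_arm_start + self.arm_len + self.spacer_len

    @property
    def start(self) -> int:
        """Start of the whole arm-spacer-arm element."""
        return self.left_arm_start

    @property
    def end(self) -> int:
        """End (exclusive) of the whole element."""
        return self.right_arm_start + self.arm_len

    @property
    def left_arm_end(self) -> int:
        return self.left_arm_start + self.arm_len

    @property
    def spacer_interval(self) -> tuple[int, int]:
        return (self.left_arm_end, self.right_arm_start)


@dataclass(frozen=True)
class DensityStats:
    """Genome-wide IIR density summary.

    ``mean_spacing`` is ``None`` (undefined) when there are no hits.
    """

    hit_count: int
    sequence_len: int
    per_bp_rate: float
    mean_spacing: float | None

    def to_dict(self) -> dict:
        return {
            "hit_count": self.hit_count,
            "sequence_len": self.sequence_len,
            "per_bp_rate": self.per_bp_rate,
            "mean_spacing": self.mean_spacing,
        }


@dataclass(frozen=True)
class Origin:
    """A replication origin (ARS) interval; inactive models an ARS deletion."""

    seq_id: str
    start: int
    end: int
    name: str = ""
    active: bool = True

    def __post_init__(self):
        if not self.start < self.end:
            raise ParameterError(
                f"origin {self.name!r}: start must be < end ({self.start} >= {self.end})"
            )


_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i + 1  # 0 is reserved for N/unknown
_COMP = np.zeros(256, dtype=np.uint8)
for _b, _c in zip("ACGT", "TGCA"):
    _COMP[ord(_b)] = _CODE[ord(_c)]


def scan_interrupted_inverted_repeats(
    seq: Sequence,
    arm_len: int = 7,
    spacer_min: int = 1,
    spacer_max: int = 69,
    max_mismatches: int = 0,
) -> list[InterruptedInvertedRepeat]:
    """Find every interrupted inverted repeat in ``seq``.

    Returns all (left_arm_start, spacer_len) pairs for which the arm at
    ``left_arm_start`` equals the reverse complement of the arm starting
    ``arm_len + spacer_len`` further right, with at most ``max_mismatches``
    differences.  Windows containing N are excluded.  Hits are sorted by
    position, then spacer length.  A sequence too short to host a hit
    yields an empty list (not an error).
    """
    if arm_len < 4:
        raise ParameterError(f"arm_len must be >= 4, got {arm_len}")
    if not (0 <= spacer_min <= spacer_max):
        raise ParameterError(
            f"need 0 <= spacer_min <= spacer_max, got [{spacer_min}, {spacer_max}]"
        )
    if max_mismatches < 0:
        raise ParameterError("max_mismatches must be >= 0")
    if max_mismatches >= arm_len:
        raise ParameterError("max_mismatches must be smaller than arm_len")

    n = len(seq)
    raw = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
    x = _CODE[raw]        # 1..4 for ACGT, 0 for N
    cx = _COMP[raw]       # complement code, 0 for N
    has_n = x == 0
    ncum = np.concatenate([[0], np.cumsum(has_n)])

    hits: list[InterruptedInvertedRepeat] = []
    for s in range(spacer_min, spacer_max + 1):
        w = 2 * arm_len + s
        m = n - w + 1
        if m <= 0:
            break
        mm = np.zeros(m, dtype=np.int16)
        for k in range(arm_len):
            # left arm base i+k must complement right arm base i+w-1-k
            mm += x[k : k + m] != cx[w - 1 - k : w - 1 - k + m]
        ok = mm <= max_mismatches
        ok &= (ncum[w : w + m] - ncum[:m]) == 0  # no N anywhere in the window
        for i in np.nonzero(ok)[0]:
            hits.append(
                InterruptedInvertedRepeat(
                    seq_id=seq.id,
                    left_arm_start=int(i),
                    spacer_len=s,
                    arm_len=arm_len,
                    mismatches=int(mm[i]),
                )
            )
    hits.sort(key=lambda h: (h.left_arm_start, h.spacer_len))
    return hits


def ir_density_stats(
    hits: list[InterruptedInvertedRepeat], sequence_len: int
) -> DensityStats:
    """Summarize a hit list as a per-bp rate and a mean spacing."""
    if sequence_len <= 0:
        raise ParameterError("sequence_len must be positive")
    k = len(hits)
    if k == 0:
        return DensityStats(0, sequence_len, 0.0, None)
    return DensityStats(k, sequence_len, k / sequence_len, sequence_len / k)


def expected_per_bp_rate(arm_len: int, n_spacers: int) -> float:
    """Closed-form expected hit rate on uniform random sequence.

    Each (position, spacer) pair matches with probability ``4**-arm_len``
    under perfect matching, so the per-bp rate is ``n_spacers * 4**-arm_len``
    (edge effects excepted).  For 7 bp arms and 69 spacer choices this is
    one hit per ~237 bp.
    """
    return n_spacers * math.pow(4.0, -arm_len)


def expected_pair_count(
    n: int, arm_len: int, spacer_min: int, spacer_max: int
) -> int:
    """Exact number of (position, spacer) windows tested on an N-free sequence."""
    total = 0
    for s in range(spacer_min, spacer_max + 1):
        m = n - (2 * arm_len + s) + 1
        if m > 0:
            total += m
    return total


def pair_irs_flanking_origin(
    hits: list[InterruptedInvertedRepeat],
    origin: Origin,
    max_span: int,
) -> list[tuple[InterruptedInvertedRepeat, InterruptedInvertedRepeat]]:
    """Nominate (left, right) IIR pairs flanking an active origin.

    A pair is a candidate amplification substrate when the left IIR lies
    entirely left of the origin, the right IIR entirely right of it, and
    the outer span (left element start to right element end) is at most
    ``max_span``.  Inactive origins never license a pair: diverging forks
    must initiate between the two repeats for the mechanism to operate.
    """
    if not origin.active:
        raise LicensingError(
            f"origin {origin.name or origin.start!r} is inactive: dog-bone "
            "formation is origin-dependent and requires an active origin "
            "between the flanking inverted repeats"
        )
    if max_span <= 0:
        raise ParameterError("max_span must be positive")
    lefts = [h for h in hits if h.end <= origin.start]
    rights = [h for h in hits if h.left_arm_start >= origin.end]
    pairs = [
        (lh, rh)
        for lh in lefts
        for rh in rights
        if rh.end - lh.start <= max_span
    ]
    pairs.sort(key=lambda p: (p[0].left_arm_start, p[0].spacer_len,
                              p[1].left_arm_start, p[1].spacer_len))
    return pairs
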