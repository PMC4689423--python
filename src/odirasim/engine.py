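"""Generation of inverted-amplification products as explicit sequences.

The mechanism modeled here produces interstitial inverted triplications in
three steps.  (1) Two replication forks diverging from an origin each
suffer a closed-fork error at a short interrupted inverted repeat; the
self-complementary loop between the two errors is expelled as a linear
duplex capped by single-stranded hairpin loops -- a "dog bone".  The
hairpin loops are the repeat spacers; the duplex retains the
origin-proximal arm of each repeat at its ends.  (2) Replication from the
origin carried on the dog bone converts it into a circular plasmid whose
two halves are the amplified unit in inverted orientation, joined through
the former hairpin loops (head-to-head and tail-to-tail quasi-palindromic
junctions).  (3) Homologous integration of the plasmid back into the
chromosomal locus yields a triplication with the central copy inverted and
no loss of distal sequence; n tandem plasmid copies give 2n+1 unit copies.

A secondary rearrangement is also modeled: after the inversion, two
repeats that were in inverted orientation in the ancestor come to lie in
direct orientation across a junction, enabling intramolecular
recombination that deletes one palindrome arm and produces the
DUP-TRP/INV-DUP copy-number staircase (1 -> 2 -> 3).

Coordinate convention: 0-based half-open on the ancestral top strand.
Every product is represented as an ordered list of ancestral segments with
orientations plus inserted loop texts, so rendering is lossless and every
junction carries provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import cached_property

import numpy as np

from .errors import (
    HomologyError,
    LicensingError,
    ParameterError,
    PreconditionError,
)
from .irscan import (
    InterruptedInvertedRepeat,
    Origin,
    pair_irs_flanking_origin,
    scan_interrupted_inverted_repeats,
)
from .seqs import Sequence, revcomp

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "DogBone",
    "DimericPlasmid",
    "SegmentPiece",
    "LoopPiece",
    "JunctionRecord",
    "DerivedChromosome",
    "RepeatPair",
    "SimParams",
    "OdiraOutcome",
    "extrude_dog_bone",
    "replicate_dog_bone",
    "integrate_plasmid",
    "single_fork_outcome",
    "find_direct_repeat_pairs",
    "apply_arm_deletion",
    "simulate_odira",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DogBone:
    """Hairpin-capped linear duplex: unit ``U`` plus two terminal ss loops.

    The single covalent circuit is ``U + loop_right + rc(U) + loop_left``
    of length ``2*|U| + |loop_left| + |loop_right|``.
    """

    unit: str
    loop_left: str
    loop_right: str
    origins: tuple[Origin, ...]
    seq_id: str = ""
    unit_start: int | None = None  # ancestral interval of U, if derived
    unit_end: int | None = None
    arm_len: int | None = None
    small_loop: bool = False  # loops shorter than the empirically stable size

    @property
    def circuit_length(self) -> int:
        return 2 * len(self.unit) + len(self.loop_left) + len(self.loop_right)

    @property
    def covalent_circuit(self) -> str:
        """The closed single strand, starting at the first base of U."""
        return self.unit + self.loop_right + revcomp(self.unit) + self.loop_left


@dataclass(frozen=True)
class DimericPlasmid:
    """Circular duplex: unit and its reverse complement joined through loops."""

    unit: str
    loop_left: str
    loop_right: str
    seq_id: str = ""
    unit_start: int | None = None
    unit_end: int | None = None
    arm_len: int | None = None

    @property
    def circle(self) -> str:
        """Top strand of the circle: ``U + loop_right + rc(U) + loop_left``."""
        return self.unit + self.loop_right + revcomp(self.unit) + self.loop_left

    @property
    def circumference(self) -> int:
        return len(self.circle)

    @property
    def junctions(self) -> list[dict]:
        """The two quasi-palindromic junction centers with loop intervals."""
        u = len(self.unit)
        return [
            {
                "kind": "tail-to-tail",
                "loop_start": u,
                "loop_end": u + len(self.loop_right),
            },
            {
                "kind": "head-to-head",
                "loop_start": 2 * u + len(self.loop_right),
                "loop_end": self.circumference,
            },
        ]


@dataclass(frozen=True)
class SegmentPiece:
    """An ancestral interval carried into a product, with orientation."""

    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ParameterError(f"bad segment interval [{self.start}, {self.end})")

    def __len__(self):
        return self.end - self.start


@dataclass(frozen=True)
class LoopPiece:
    """A non-ancestral insertion at a junction (a former hairpin loop)."""

    text: str
    label: str = "loop"

    def __len__(self):
        return len(self.text)


@dataclass(frozen=True)
class JunctionRecord:
    """Provenance of one novel adjacency in a product.

    ``position`` is the product coordinate where the left-hand side ends;
    an inserted loop (possibly empty) sits at ``[position, position +
    len(loop))``.  ``novel_span`` is a product interval guaranteed to
    contain sequence absent from the ancestor on either strand: reads that
    fully cover it cannot map contiguously.
    """

    position: int
    kind: str  # 'inverted' or 'deletion'
    loop: str
    left_locus: tuple[int, str]   # ancestor coordinate + strand of last base
    right_locus: tuple[int, str]  # ancestor coordinate + strand of first base
    novel_span: tuple[int, int]

    def to_dict(self) -> dict:
        return asdict(self)


class DerivedChromosome:
    """An ordered list of ancestral segments and loops, renderable to sequence."""

    def __init__(
        self,
        ancestor: Sequence,
        pieces: list,
        name: str | None = None,
        is_acentric: bool = False,
        centromere_deleted: bool = False,
    ):
        if not pieces:
            raise ParameterError("a derived chromosome needs at least one piece")
        for p in pieces:
            if isinstance(p, SegmentPiece) and p.end > len(ancestor):
                raise ParameterError("segment extends past the ancestor")
        self.ancestor = ancestor
        self.pieces = _coalesce(pieces)
        self.name = name or f"{ancestor.id}_derived"
        self.is_acentric = is_acentric
        self.centromere_deleted = centromere_deleted

    # -- rendering ---------------------------------------------------------

    @cached_property
    def rendered(self) -> str:
        out = []
        anc = self.ancestor.bases
        for p in self.pieces:
            if isinstance(p, LoopPiece):
                out.append(p.text)
            elif p.strand == "+":
                out.append(anc[p.start : p.end])
            else:
                out.append(revcomp(anc[p.start : p.end]))
        return "".join(out)

    def __len__(self) -> int:
        return sum(len(p) for p in self.pieces)

    # -- provenance --------------------------------------------------------

    @cached_property
    def junction_records(self) -> list[JunctionRecord]:
        recs = []
        pos = 0
        pieces = self.pieces
        i = 0
        while i < len(pieces) - 1:
            a = pieces[i]
            pos_a_end = pos + len(a)
            # gather any loop(s) between this segment and the next one
            j = i + 1
            loop_text = ""
            while j < len(pieces) and isinstance(pieces[j], LoopPiece):
                loop_text += pieces[j].text
                j += 1
            if j >= len(pieces):
                break
            b = pieces[j]
            if isinstance(a, SegmentPiece) and isinstance(b, SegmentPiece):
                contiguous = (
                    not loop_text
                    and a.strand == b.strand
                    and (
                        (a.strand == "+" and a.end == b.start)
                        or (a.strand == "-" and a.start == b.end)
                    )
                )
                if not contiguous:
                    kind = "inverted" if a.strand != b.strand else "deletion"
                    left = (a.end - 1, "+") if a.strand == "+" else (a.start, "-")
                    right = (b.start, "+") if b.strand == "+" else (b.end - 1, "-")
                    recs.append(
                        JunctionRecord(
                            position=pos_a_end,
                            kind=kind,
                            loop=loop_text,
                            left_locus=left,
                            right_locus=right,
                            novel_span=self._novel_span(pos_a_end, len(loop_text)),
                        )
                    )
            pos = pos_a_end + len(loop_text)
            i = j
        return recs

    def _novel_span(self, pos: int, loop_len: int, cap: int = 300) -> tuple[int, int]:
        """Smallest symmetric window around a junction absent from the ancestor."""
        prod = self.rendered
        anc = self.ancestor.bases
        anc_rc = revcomp(anc)
        lo, hi = pos, pos + loop_len
        for _ in range(cap):
            lo = max(0, lo - 1)
            hi = min(len(prod), hi + 1)
            w = prod[lo:hi]
            if w not in anc and w not in anc_rc:
                return (lo, hi)
            if lo == 0 and hi == len(prod):
                break
        return (max(0, pos - cap), min(len(prod), pos + loop_len + cap))

    # -- copy number -------------------------------------------------------

    def coverage(self) -> np.ndarray:
        """Per-base copy number over ancestor coordinates (loops ignored)."""
        cov = np.zeros(len(self.ancestor) + 1, dtype=np.int64)
        for p in self.pieces:
            if isinstance(p, SegmentPiece):
                cov[p.start] += 1
                cov[p.end] -= 1
        return np.cumsum(cov[:-1])

    def centromere_copies(self, cen: tuple[int, int]) -> int:
        """How many product copies fully contain the centromere interval."""
        n = sum(
            1
            for p in self.pieces
            if isinstance(p, SegmentPiece) and p.start <= cen[0] and cen[1] <= p.end
        )
        return n - (1 if self.centromere_deleted and n > 0 else 0)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ancestor_id": self.ancestor.id,
            "ancestor_len": len(self.ancestor),
            "is_acentric": self.is_acentric,
            "centromere_deleted": self.centromere_deleted,
            "pieces": [
                {"type": "segment", "start": p.start, "end": p.end, "strand": p.strand}
                if isinstance(p, SegmentPiece)
                else {"type": "loop", "text": p.text, "label": p.label}
                for p in self.pieces
            ],
            "junctions": [r.to_dict() for r in self.junction_records],
        }

    @classmethod
    def from_dict(cls, d: dict, ancestor: Sequence) -> "DerivedChromosome":
        if d["ancestor_id"] != ancestor.id or d["ancestor_len"] != len(ancestor):
            raise ParameterError("ancestor does not match the serialized product")
        pieces = [
            SegmentPiece(p["start"], p["end"], p["strand"])
            if p["type"] == "segment"
            else LoopPiece(p["text"], p.get("label", "loop"))
            for p in d["pieces"]
        ]
        return cls(
            ancestor,
            pieces,
            name=d.get("name"),
            is_acentric=d.get("is_acentric", False),
            centromere_deleted=d.get("centromere_deleted", False),
        )


def _coalesce(pieces: list) -> list:
    """Merge adjacent contiguous same-strand segments."""
    out: list = []
    for p in pieces:
        if (
            out
            and isinstance(p, SegmentPiece)
            and isinstance(out[-1], SegmentPiece)
            and p.strand == out[-1].strand
        ):
            q = out[-1]
            if p.strand == "+" and q.end == p.start:
                out[-1] = SegmentPiece(q.start, p.end, "+")
                continue
            if p.strand == "-" and q.start == p.end:
                out[-1] = SegmentPiece(p.start, q.end, "-")
                continue
        out.append(p)
    return out


def _split_pieces_at(pieces: list, coord: int) -> tuple[list, list]:
    """Split a piece list at a product coordinate."""
    pos = 0
    for i, p in enumerate(pieces):
        if pos + len(p) <= coord:
            pos += len(p)
            continue
        off = coord - pos
        left = list(pieces[:i])
        right = list(pieces[i + 1 :])
        if off > 0:
            if isinstance(p, LoopPiece):
                left.append(LoopPiece(p.text[:off], p.label))
            elif p.strand == "+":
                left.append(SegmentPiece(p.start, p.start + off, "+"))
            else:
                left.append(SegmentPiece(p.end - off, p.end, "-"))
        if off < len(p):
            if isinstance(p, LoopPiece):
                right.insert(0, LoopPiece(p.text[off:], p.label))
            elif p.strand == "+":
                right.insert(0, SegmentPiece(p.start + off, p.end, "+"))
            else:
                right.insert(0, SegmentPiece(p.start, p.end - off, "-"))
        return left, right
    return list(pieces), []


# ---------------------------------------------------------------------------
# step 1: dog-bone extrusion
# ---------------------------------------------------------------------------

# Hairpin loops shorter than this were observed to be unstable in vivo;
# the smallest loop recovered from stable inverted junctions is 17 nt.
STABLE_LOOP_MIN = 17


def extrude_dog_bone(
    chrom: Sequence,
    left: InterruptedInvertedRepeat,
    right: InterruptedInvertedRepeat,
    origins: list[Origin],
) -> DogBone:
    """Excise the closed-loop intermediate licensed by an IIR pair.

    Each closed fork folds immediately after the origin-proximal arm of
    its repeat, so the amplified unit runs from the left IIR's right arm
    through the right IIR's left arm, and the two spacers become the
    terminal single-stranded loops.  This is the only fold convention
    under which the ancestral arm-spacer-arm string is preserved verbatim
    at both junctions of every downstream product.

    Requires at least one active origin strictly between the two repeats.
    """
    if left.seq_id != chrom.id or right.seq_id != chrom.id:
        raise ParameterError("IIRs must be on the given chromosome")
    if not left.end <= right.start:
        raise ParameterError("left IIR must lie entirely left of the right IIR")
    us = left.right_arm_start
    ue = right.left_arm_start + right.arm_len
    inside = [o for o in origins if o.seq_id == chrom.id and us <= o.start and o.end <= ue]
    if not any(o.active for o in inside):
        detail = (
            "only inactive origin(s) between the repeats"
            if inside
            else "no origin between the repeats"
        )
        raise LicensingError(
            f"cannot extrude dog bone: {detail}. Amplification is origin-"
            "dependent: an active origin must fire between the two inverted "
            "repeats so that diverging forks can both close."
        )
    loop_left = chrom.bases[left.left_arm_end : left.right_arm_start]
    loop_right = chrom.bases[ue : right.right_arm_start]
    return DogBone(
        unit=chrom.bases[us:ue],
        loop_left=loop_left,
        loop_right=loop_right,
        origins=tuple(o for o in inside if o.active),
        seq_id=chrom.id,
        unit_start=us,
        unit_end=ue,
        arm_len=left.arm_len,
        small_loop=min(len(loop_left), len(loop_right)) < STABLE_LOOP_MIN,
    )


# ---------------------------------------------------------------------------
# step 2: replication to the inverted dimeric plasmid
# ---------------------------------------------------------------------------

def replicate_dog_bone(db: DogBone) -> DimericPlasmid:
    """Replicate a dog bone into the circular inverted dimer.

    Replication from the internal origin runs around both hairpin ends,
    converting the molecule into a circle whose top strand is
    ``U + loop_right + rc(U) + loop_left`` -- circumference equal to the
    dog-bone covalent circuit.  Replication is error-free.
    """
    if not db.origins:
        raise LicensingError(
            "dog bone carries no active origin and cannot replicate"
        )
    return DimericPlasmid(
        unit=db.unit,
        loop_left=db.loop_left,
        loop_right=db.loop_right,
        seq_id=db.seq_id,
        unit_start=db.unit_start,
        unit_end=db.unit_end,
        arm_len=db.arm_len,
    )


# ---------------------------------------------------------------------------
# step 3: chromosomal integration
# ---------------------------------------------------------------------------

def integrate_plasmid(
    chrom: Sequence,
    p: DimericPlasmid,
    crossover: int | None = None,
    n_copies: int = 1,
) -> DerivedChromosome:
    """Integrate the dimeric plasmid at its unique chromosomal homology.

    A single crossover within the unit inserts the whole circle, giving
    ``prefix + U + loop_R + rc(U) + loop_L + U + suffix`` for one plasmid
    copy and ``2*n_copies + 1`` unit copies for ``n_copies`` tandem
    insertions (odd copy numbers: 3, 5, 7, ...).  Because the homology is
    exact, the crossover position does not change the rendered product.
    """
    if n_copies < 1:
        raise ParameterError("n_copies must be >= 1")
    u = p.unit
    first = chrom.bases.find(u)
    if first < 0:
        raise HomologyError(
            "integration refused: the plasmid unit has no homology in the "
            "chromosome (non-homologous host locus)"
        )
    if chrom.bases.find(u, first + 1) >= 0:
        raise HomologyError("integration target ambiguous: unit occurs more than once")
    us, ue = first, first + len(u)
    if crossover is None:
        crossover = us + len(u) // 2
    if not us <= crossover <= ue:
        raise ParameterError("crossover must fall within the homologous unit")

    # prefix + first unit copy are contiguous: represent as one segment
    pieces: list = [SegmentPiece(0, ue, "+")]
    for _ in range(n_copies):
        pieces.append(LoopPiece(p.loop_right, "tail-to-tail"))
        pieces.append(SegmentPiece(us, ue, "-"))
        pieces.append(LoopPiece(p.loop_left, "head-to-head"))
        pieces.append(SegmentPiece(us, ue, "+"))
    # last unit copy continues into the suffix
    if ue < len(chrom):
        pieces.append(SegmentPiece(ue, len(chrom), "+"))
    return DerivedChromosome(chrom, pieces, name=f"{chrom.id}_trp{2 * n_copies + 1}")


# ---------------------------------------------------------------------------
# single closed-fork outcomes
# ---------------------------------------------------------------------------

def single_fork_outcome(
    chrom: Sequence,
    iir: InterruptedInvertedRepeat,
    side: str,
    cen: tuple[int, int],
    tel: tuple[int, int],
) -> DerivedChromosome:
    """Outcome of one closed fork (no partner on the other side of an origin).

    ``side`` names where the closed fork sits relative to the centromere:
    a telomere-proximal closed fork yields an isochromosome (the
    centromere-containing part duplicated as a perfect palindrome around
    the repeat spacer, telomeric sequences lost); a centromere-proximal
    one yields an acentric inverted linear fragment.
    """
    if side not in ("telomere-proximal", "centromere-proximal"):
        raise ParameterError(
            "side must be 'telomere-proximal' or 'centromere-proximal'"
        )
    if iir.seq_id != chrom.id:
        raise ParameterError("IIR must be on the given chromosome")
    cen_left = cen[1] <= iir.start if cen[1] <= iir.start or tel[0] >= iir.end else None
    if cen_left is None:
        raise ParameterError("centromere/telomere intervals must flank the IIR")
    spacer = chrom.bases[iir.left_arm_end : iir.right_arm_start]

    if side == "telomere-proximal":
        # keep the centromere side; fold after the cen-proximal arm
        if cen_left:
            x = iir.left_arm_end
            pieces = [
                SegmentPiece(0, x, "+"),
                LoopPiece(spacer, "fold-point"),
                SegmentPiece(0, x, "-"),
            ]
        else:
            y = iir.right_arm_start
            pieces = [
                SegmentPiece(y, len(chrom), "-"),
                LoopPiece(spacer, "fold-point"),
                SegmentPiece(y, len(chrom), "+"),
            ]
        return DerivedChromosome(
            chrom, pieces, name=f"{chrom.id}_isochromosome", is_acentric=False
        )

    # centromere-proximal closed fork: the distal piece is expelled acentric
    if cen_left:
        y = iir.right_arm_start
        pieces = [
            SegmentPiece(y, len(chrom), "-"),
            LoopPiece(spacer, "fold-point"),
            SegmentPiece(y, len(chrom), "+"),
        ]
    else:
        x = iir.left_arm_end
        pieces = [
            SegmentPiece(0, x, "+"),
            LoopPiece(spacer, "fold-point"),
            SegmentPiece(0, x, "-"),
        ]
    return DerivedChromosome(
        chrom, pieces, name=f"{chrom.id}_acentric_fragment", is_acentric=True
    )


# ---------------------------------------------------------------------------
# secondary rearrangement: arm deletion between direct repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPair:
    """Two identical product substrings in direct orientation across a junction."""

    left_start: int   # product coordinate of the first copy
    right_start: int  # product coordinate of the second copy
    length: int
    junction_position: int

    @property
    def separation(self) -> int:
        return self.right_start - self.left_start


def find_direct_repeat_pairs(
    d: DerivedChromosome, min_len: int = 12, max_separation: int | None = None
) -> list[RepeatPair]:
    """Direct-orientation repeat pairs flanking each inverted junction.

    Repeats that are inverted relative to each other in the ancestor come
    to lie in direct orientation once the central copy is inverted; each
    such pair is a substrate for intramolecular homologous recombination
    that deletes one arm of the palindrome.
    """
    if min_len < 4:
        raise ParameterError("min_len must be >= 4")
    inv = [r for r in d.junction_records if r.kind == "inverted"]
    if not inv:
        raise PreconditionError("product has no inverted junction")
    prod = d.rendered
    bounds = sorted(
        {0, len(prod)}
        | {r.position for r in d.junction_records}
        | {r.position + len(r.loop) for r in d.junction_records}
    )
    pairs: list[RepeatPair] = []
    seen = set()
    for rec in inv:
        jpos = rec.position
        seg_lo = max((b for b in bounds if b < jpos), default=0)
        right_lo = jpos + len(rec.loop)
        seg_hi = min((b for b in bounds if b > right_lo), default=len(prod))
        # the palindrome arms: maximal reverse-complementary extent around
        # the junction loop, bounded by the neighboring junctions
        m = 0
        while (
            jpos - 1 - m >= seg_lo
            and right_lo + m < seg_hi
            and prod[jpos - 1 - m] == _COMP.get(prod[right_lo + m], "?")
        ):
            m += 1
        arm_l = prod[jpos - m : jpos]
        arm_r = prod[right_lo : right_lo + m]
        left_lo = jpos - m
        for a, b, ln in _common_substrings(arm_l, arm_r, min_len):
            ls, rs = left_lo + a, right_lo + b
            if max_separation is not None and rs - ls > max_separation:
                continue
            key = (ls, rs, ln)
            if key not in seen:
                seen.add(key)
                pairs.append(RepeatPair(ls, rs, ln, jpos))
    pairs.sort(key=lambda p: (p.left_start, p.right_start, -p.length))
    return pairs


def _common_substrings(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal common substrings >= min_len between two strings (seed+extend)."""
    k = min_len
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    out = set()
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            # extend to the maximal match around this seed
            li, lj = i, j
            while li > 0 and lj > 0 and a[li - 1] == b[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + k, j + k
            while ri < len(a) and rj < len(b) and a[ri] == b[rj]:
                ri += 1
                rj += 1
            out.add((li, lj, ri - li))
    return sorted(out)


def apply_arm_deletion(d: DerivedChromosome, pair: RepeatPair) -> DerivedChromosome:
    """Recombine between a direct repeat pair, deleting one palindrome arm.

    The sequence between the two copies (and one copy) is removed; the
    product shortens by exactly ``pair.separation``.  Over ancestor
    coordinates the result shows the DUP-TRP/INV-DUP staircase: copy
    number stepping 1 -> 2 -> 3 across the partially deleted arm.
    """
    prod = d.rendered
    w1 = prod[pair.left_start : pair.left_start + pair.length]
    w2 = prod[pair.right_start : pair.right_start + pair.length]
    if pair.separation <= 0 or w1 != w2:
        raise PreconditionError(
            "repeat pair is not in direct orientation at the stated positions"
        )
    left, _ = _split_pieces_at(d.pieces, pair.left_start)
    _, right = _split_pieces_at(d.pieces, pair.right_start)
    return DerivedChromosome(
        d.ancestor,
        left + right,
        name=f"{d.name}_armdel",
        is_acentric=d.is_acentric,
        centromere_deleted=d.centromere_deleted,
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Tunable parameters of the end-to-end simulation."""

    arm_len: int = 7
    spacer_min: int = 1
    spacer_max: int = 69
    max_mismatches: int = 0
    max_span: int = 30_000
    n_copies: int = 1
    secondary_deletion: str = "auto"  # 'auto' | 'off'
    min_repeat_len: int = 12
    max_separation: int | None = None


@dataclass
class OdiraOutcome:
    """Result of one simulated amplification attempt plus its event log."""

    product: DerivedChromosome | None
    events: list[dict] = field(default_factory=list)

    @property
    def no_substrate(self) -> bool:
        return self.product is None


def simulate_odira(
    chrom: Sequence,
    origins: list[Origin],
    params: SimParams | None = None,
    seed: int = 0,
) -> OdiraOutcome:
    """Sample an IIR pair around an active origin and run all three steps.

    Reproducible: the same seed yields a byte-identical product.  When no
    active origin has admissible flanking repeats the outcome is an
    explicit "no substrate" result, not an error.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    events: list[dict] = [{"event": "start", "seed": int(seed), "chrom": chrom.id}]

    hits = scan_interrupted_inverted_repeats(
        chrom,
        arm_len=params.arm_len,
        spacer_min=params.spacer_min,
        spacer_max=params.spacer_max,
        max_mismatches=params.max_mismatches,
    )
    events.append({"event": "scan", "hits": len(hits)})

    candidates = []
    for o in origins:
        if o.seq_id != chrom.id or not o.active:
            continue
        for lh, rh in pair_irs_flanking_origin(hits, o, params.max_span):
            candidates.append((o, lh, rh))
    if not candidates:
        events.append({"event": "no_odira_substrate",
                       "reason": "no active origin with flanking repeat pair"})
        return OdiraOutcome(None, events)

    o, lh, rh = candidates[int(rng.integers(len(candidates)))]
    events.append(
        {
            "event": "substrate",
            "origin": o.name,
            "left_iir": [lh.left_arm_start, lh.spacer_len],
            "right_iir": [rh.left_arm_start, rh.spacer_len],
        }
    )
    db = extrude_dog_bone(chrom, lh, rh, origins)
    events.append({"event": "dog_bone", "unit_len": len(db.unit),
                   "loops": [len(db.loop_left), len(db.loop_right)],
                   "small_loop": db.small_loop})
    plasmid = replicate_dog_bone(db)
    events.append({"event": "dimeric_plasmid", "circumference": plasmid.circumference})
    crossover = db.unit_start + int(rng.integers(len(db.unit) + 1))
    product = integrate_plasmid(chrom, plasmid, crossover=crossover,
                                n_copies=params.n_copies)
    events.append({"event": "integration", "crossover": crossover,
                   "unit_copy_number": 2 * params.n_copies + 1})

    if params.secondary_deletion == "auto":
        pairs = find_direct_repeat_pairs(
            product, params.min_repeat_len, params.max_separation
        )
        if pairs:
            pair = pairs[int(rng.integers(len(pairs)))]
            product = apply_arm_deletion(product, pair)
            events.append(
                {
                    "event": "arm_deletion",
                    "left_start": pair.left_start,
                    "right_start": pair.right_start,
                    "repeat_len": pair.length,
                    "deleted": pair.separation,
                }
            )
        else:
            events.append({"event": "arm_deletion_skipped", "reason": "no direct pair"})
    return OdiraOutcome(product, events)
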