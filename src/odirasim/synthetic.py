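"""Seeded random genomes and curated fixtures.

Everything in the test suite and the acceptance script runs on sequence
generated here: a random genome for density estimates, and a curated
"amplicon locus" fixture that emulates the architecture of a selectable
chromosomal region -- a unique background carrying one active origin
flanked by short interrupted inverted repeats with 2-4 nt spacers, a
planted palindromic restriction site placed so that the inverted-dimer
junction fragment has a known size, and a planted inverted word pair that
comes to lie in direct orientation after triplication (the substrate of
the secondary arm-deletion rearrangement).

The background is post-processed so the fixtures are oracle-friendly:
duplicate 15-mers (direct or inverted) are re-rolled genome-wide, as are
inverted duplicate 12-mers within the amplified unit, and all stray
copies of the planted restriction site are removed.  Planted features are
never touched.  Loop-size instability of very small hairpin loops is
recorded as a boolean flag on the dog bone (loops under 17 nt were not
stably inherited in vivo), not simulated as a stochastic process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DogBone, STABLE_LOOP_MIN
from .enzymes import resolve_enzyme
from .errors import DesignError, FixtureError, ParameterError
from .irscan import InterruptedInvertedRepeat, Origin
from .seqs import Sequence, revcomp

__all__ = [
    "FixtureSpec",
    "random_genome",
    "make_sul1_like_fixture",
    "HairpinAdapter",
    "design_hairpin_adapters",
    "cap_fragment_with_hairpins",
]

_ORD = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(length: int, gc: float = 0.5, seed: int = 0,
                  seq_id: str = "random") -> Sequence:
    """I.i.d. random sequence with the given GC fraction; seeded."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0 < gc < 1:
        raise ParameterError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    return Sequence(seq_id, _ORD[codes].tobytes().decode("ascii"))


@dataclass
class FixtureSpec:
    """Parameters of the curated amplicon-locus fixture.

    Defaults give a 24 kb ancestor with a 2,300 bp amplified unit (the
    size of the hairpin-capped construct whose replication product is the
    ~4.6 kb circular dimer), 4 and 3 nt repeat spacers, and a blunt
    palindromic site placed 1,348 bp from the unit end so the inverted
    junction fragment of any product digests to 2 * 1348 + 4 = 2,700 bp.
    """

    length: int = 24_000
    gc: float = 0.38  # yeast-like base composition
    seed: int = 7
    unit_len: int = 2_300
    unit_start: int | None = None
    arm_len: int = 7
    loop_left_len: int = 3
    loop_right_len: int = 4
    origin_len: int = 150
    origin_active: bool = True
    origin_name: str = "ARS-like"
    snapback_enzyme: str = "EcoRV"
    snapback_arm: int = 1_348
    repeat_word_len: int = 12
    repeat_word_offsets: tuple[int, int] = (400, 1_800)


@dataclass
class Fixture:
    """A generated ancestor plus its planted-feature annotations."""

    chrom: Sequence
    origins: list[Origin]
    iirs: list[InterruptedInvertedRepeat]
    repeat_pair: dict
    snapback_site: dict
    spec: FixtureSpec = field(repr=False, default=None)

    @property
    def unit_interval(self) -> tuple[int, int]:
        return (self.iirs[0].right_arm_start, self.iirs[1].left_arm_end)


def make_sul1_like_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Build the curated amplicon-locus ancestor.

    Plants, in order of position: left IIR (arm/4 nt spacer/arm ending at
    the unit start), the unit with an active origin at its center, a
    direct-repeat word pair in inverted orientation inside the unit, the
    palindromic restriction site, and the right IIR (arm/3 nt spacer/arm
    starting at the unit end).  Raises :class:`FixtureError` if the
    requested features cannot be placed without overlap.
    """
    spec = spec or FixtureSpec()
    ez = resolve_enzyme(spec.snapback_enzyme)
    n, ulen = spec.length, spec.unit_len
    arm = spec.arm_len
    us = spec.unit_start if spec.unit_start is not None else (n - ulen) // 2
    ue = us + ulen

    # feature intervals (ancestor coordinates)
    left_iir = InterruptedInvertedRepeat("fixture", us - arm - spec.loop_left_len,
                                         spec.loop_left_len, arm)
    right_iir = InterruptedInvertedRepeat("fixture", ue - arm,
                                          spec.loop_right_len, arm)
    o_start = us + ulen // 2 - spec.origin_len // 2
    origin = Origin("fixture", o_start, o_start + spec.origin_len,
                    spec.origin_name, spec.origin_active)
    site_cut = ue - spec.snapback_arm
    site_q = site_cut - ez.cut_top
    w1 = us + spec.repeat_word_offsets[0]
    w2 = us + spec.repeat_word_offsets[1]
    wl = spec.repeat_word_len

    intervals = sorted(
        [
            (left_iir.start, left_iir.end, "left_iir"),
            (origin.start, origin.end, "origin"),
            (w1, w1 + wl, "word1"),
            (w2, w2 + wl, "word2"),
            (site_q, site_q + len(ez.site), "snapback_site"),
            (right_iir.start, right_iir.end, "right_iir"),
        ]
    )
    for (a1, b1, n1), (a2, b2, n2) in zip(intervals, intervals[1:]):
        if b1 > a2:
            raise FixtureError(f"planted features {n1} and {n2} overlap")
    if intervals[0][0] < 0 or intervals[-1][1] > n:
        raise FixtureError("planted features fall outside the sequence")

    rng = np.random.default_rng(spec.seed)
    g = list(random_genome(n, spec.gc, int(rng.integers(2**31)), "fixture").bases)

    def plant(pos, text):
        g[pos : pos + len(text)] = list(text)

    arm_l = _rand(rng, arm)
    arm_r = _rand(rng, arm)
    plant(left_iir.left_arm_start, arm_l)
    plant(left_iir.right_arm_start, revcomp(arm_l))
    plant(right_iir.left_arm_start, arm_r)
    plant(right_iir.right_arm_start, revcomp(arm_r))
    word = _rand(rng, wl)
    plant(w1, word)
    plant(w2, revcomp(word))
    plant(site_q, ez.site)  # blunt palindromic site, plain ACGT for EcoRV

    protected = np.zeros(n, dtype=bool)
    for a, b, _ in intervals:
        protected[a:b] = True

    bases = _scrub(g, ez.site, protected, rng, us, ue, wl, spec)
    chrom = Sequence("fixture", bases)
    return Fixture(
        chrom=chrom,
        origins=[origin],
        iirs=[left_iir, right_iir],
        repeat_pair={"word": word, "pos1": w1, "pos2": w2, "len": wl},
        snapback_site={"enzyme": ez.name, "site_start": site_q, "cut": site_cut},
        spec=spec,
    )


def _rand(rng, k: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))


def _scrub(g: list, site: str, protected: np.ndarray, rng, us, ue, wl, spec) -> str:
    """Remove stray planted-site copies and accidental repeats."""
    n = len(g)

    def reroll(pos):
        if protected[pos]:
            return False
        old = g[pos]
        g[pos] = "ACGT"[(("ACGT".index(old)) + 1 + int(rng.integers(3))) % 4]
        return True

    for _ in range(50):
        s = "".join(g)
        dirty = False
        # stray copies of the planted palindromic site
        i = s.find(site)
        while i >= 0:
            if not protected[i : i + len(site)].all():
                for p in range(i, i + len(site)):
                    if reroll(p):
                        dirty = True
                        break
            i = s.find(site, i + 1)
        # genome-wide duplicate 15-mers (direct or inverted)
        dirty |= _dedup_kmers(g, 15, 0, n, protected, rng)
        # inverted duplicate 12-mers inside the unit (planted pair excepted)
        dirty |= _dedup_kmers(g, wl, us, ue, protected, rng, inverted_only=True)
        if not dirty:
            return "".join(g)
    raise FixtureError("could not scrub accidental repeats from the background")


def _dedup_kmers(g, k, lo, hi, protected, rng, inverted_only=False) -> bool:
    s = "".join(g[lo:hi])
    seen: dict[str, int] = {}
    changed = False
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        rc = revcomp(w)
        prev = seen.get(w) if not inverted_only else None
        prev_rc = seen.get(rc)
        hit = prev if prev is not None else prev_rc
        # a self-palindromic k-mer is an inverted duplicate of itself
        if rc == w or (hit is not None and hit != i):
            for p in range(lo + i, lo + i + k):
                if not protected[p]:
                    old = g[p]
                    g[p] = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(3))) % 4]
                    changed = True
                    break
        else:
            seen.setdefault(w, i)
    return changed


# ---------------------------------------------------------------------------
# hairpin adapters (building an artificial dog bone from a fragment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinAdapter:
    """A single oligo that folds into a stem-loop with a sticky overhang.

    5'->3': overhang + stem + loop + rc(stem); 5'-phosphorylated so it can
    be ligated onto a restriction fragment.  ``small_loop`` flags loops
    below the empirically stable size (17 nt) -- a stability warning, not
    a simulated process.
    """

    name: str
    bases: str
    overhang: str
    stem: str
    loop: str
    phosphorylated_5p: bool = True

    @property
    def small_loop(self) -> bool:
        return len(self.loop) < STABLE_LOOP_MIN

    @property
    def folds_back(self) -> bool:
        return self.bases.endswith(revcomp(self.stem))


def design_hairpin_adapters(
    overhang: str,
    stem_sites: tuple[str, ...] = (),
    loop_len: int = 4,
    seed: int = 0,
    stem_len: int = 24,
) -> HairpinAdapter:
    """Design one hairpin adapter with the given sticky end.

    The stem carries the requested restriction sites (which become duplex,
    cleavable sites once the adapter is part of a dog bone); the loop is
    single-stranded and uncleavable.  Deterministic for a given seed.
    """
    overhang = overhang.upper()
    if loop_len < 2:
        raise DesignError("loop_len must be >= 2")
    if set(overhang) - set("ACGT"):
        raise DesignError("overhang must be plain ACGT")
    need = sum(len(s) for s in stem_sites) + max(0, len(stem_sites) - 1)
    if need > stem_len:
        raise DesignError(
            f"stem sites {stem_sites} need {need} nt but the stem is {stem_len} nt"
        )
    rng = np.random.default_rng(seed)
    stem = list(_rand(rng, stem_len))
    cursor = 1 if need + 1 <= stem_len else 0
    for s in stem_sites:
        if set(s.upper()) - set("ACGT"):
            raise DesignError(f"stem site {s!r} must be plain ACGT")
        stem[cursor : cursor + len(s)] = list(s.upper())
        cursor += len(s) + 1
    stem = "".join(stem)
    loop = _rand(rng, loop_len)
    # keep the loop ends from zipping the stem longer
    if len(loop) > 1 and loop[0] == revcomp(loop[-1]):
        loop = loop[0] + loop[1:-1] + loop[0]
    return HairpinAdapter(
        name=f"hairpin_{overhang}_seed{seed}",
        bases=overhang + stem + loop + revcomp(stem),
        overhang=overhang,
        stem=stem,
        loop=loop,
    )


def cap_fragment_with_hairpins(
    fragment,
    left_adapter: HairpinAdapter,
    right_adapter: HairpinAdapter,
    origins=(),
) -> DogBone:
    """Ligate two hairpin adapters onto a restriction fragment.

    The adapters' sticky ends must match the fragment's overhangs (for
    the palindromic sites modeled here the overhang strings are equal
    when compatible).  The result is a dog bone whose duplex unit is
    ``rc(left stem) + fragment + right stem`` with the two adapter loops
    as terminal single-stranded caps; with an origin-bearing fragment it
    is accepted by the replication step and yields the inverted dimer.
    """
    if left_adapter.overhang != fragment.left_overhang:
        raise DesignError(
            f"left adapter overhang {left_adapter.overhang!r} incompatible "
            f"with fragment end {fragment.left_overhang!r}"
        )
    if right_adapter.overhang != fragment.right_overhang:
        raise DesignError(
            f"right adapter overhang {right_adapter.overhang!r} incompatible "
            f"with fragment end {fragment.right_overhang!r}"
        )
    unit = revcomp(left_adapter.stem) + fragment.seq + right_adapter.stem
    return DogBone(
        unit=unit,
        loop_left=left_adapter.loop,
        loop_right=right_adapter.loop,
        origins=tuple(origins),
        seq_id=f"{fragment.parent}_dogbone",
        arm_len=None,
        small_loop=left_adapter.small_loop or right_adapter.small_loop,
    )
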