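"""An artificial replication fork that can regress and self-ligate.

The construct is assembled from two synthetic oligonucleotides.  Each one
covalently joins a parental template strand to its nascent copy through a
short single-stranded linker loop, so each oligo folds back into a duplex
arm.  Complementary single-stranded tails at the parental ends of the two
oligos anneal to form the unreplicated parental duplex, completing a
four-way fork:

* the leading arm is fully replicated up to the fork junction, including
  an interrupted inverted repeat (arm / spacer / arm) just behind the
  nascent leading 3'-OH;
* the lagging arm carries an Okazaki gap: the same repeat region is
  single-stranded on the lagging template, and the nascent lagging strand
  (5'-phosphorylated) ends at the distal edge of the gap.

Because the two parental strands are complementary over the repeat region
(and only there), the fork can regress base by base over that homology --
every regression state has the same number of paired bases, so the states
are isoenergetic and purely combinatorial.  In the regressed states where
the displaced nascent leading 3' arm has re-annealed onto the exposed
template copy of the repeat, the leading 3'-OH sits on the template helix
directly next to the lagging 5'-phosphate: a nick that DNA ligase can
seal.  Sealing completes an engineered restriction site (XhoI in the
published construct) that exists in no duplex segment of the unligated
fork, so a PCR product across the linkers is obtained only after
ligation, and only the ligated product is cleavable at the junction.

Branch migration is modeled combinatorially (isoenergetic one-base
steps), not thermodynamically; ligation is nick-sealing only (no gap
filling).  Hairpin linker loops are unpaired and uncleavable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AssemblyError, DesignError, ParameterError, PreconditionError
from .seqs import is_wc_pair, revcomp

__all__ = [
    "OligoSpec",
    "ForkAssembly",
    "BranchState",
    "ClosedFork",
    "design_fork_oligos",
    "assemble_fork",
    "enumerate_branch_states",
    "find_ligatable_states",
    "ligate_closed_fork",
    "fork_pcr_primers",
]

Pairing = frozenset  # of ((strand, idx), (strand, idx)) 2-sets


@dataclass(frozen=True)
class OligoSpec:
    """A synthetic oligonucleotide with labeled functional sub-intervals.

    Expected annotation labels (0-based half-open intervals on the oligo):
    leading oligo: ``template`` (with its ``tail`` prefix), ``linker``,
    ``nascent``; lagging oligo: ``nascent``, ``linker``, ``template``
    (with ``gap`` and ``tail`` sub-intervals).
    """

    name: str
    bases: str
    phosphorylated_5p: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.bases) - set("ACGT"):
            raise ParameterError(f"oligo {self.name}: bases must be plain ACGT")
        for label, (a, b) in self.annotations.items():
            if not 0 <= a <= b <= len(self.bases):
                raise ParameterError(
                    f"oligo {self.name}: annotation {label!r} outside the oligo"
                )

    def __len__(self):
        return len(self.bases)

    def region(self, label: str) -> str:
        a, b = self.annotations[label]
        return self.bases[a:b]


class ForkAssembly:
    """The annealed four-way fork: covalent strands plus a pairing relation.

    Positions are indexed as ``(strand, idx)`` with strand ``'leading'``
    or ``'lagging'`` and idx the 0-based 5'->3' position on that oligo.
    Internally a genomic axis g is used with the fork junction at g = 0:
    the parental tail occupies ``[0, tail_len)``, the single-stranded gap
    (the repeat region) ``[-gap_len, 0)``, the nascent leading strand
    ``[-n_lead, 0)`` and the nascent lagging strand
    ``[-gap_len - n_lag, -gap_len)``.
    """

    def __init__(self, leading: OligoSpec, lagging: OligoSpec):
        for oligo, labels in (
            (leading, ("template", "tail", "linker", "nascent")),
            (lagging, ("template", "tail", "linker", "nascent", "gap")),
        ):
            missing = [l for l in labels if l not in oligo.annotations]
            if missing:
                raise AssemblyError(
                    f"oligo {oligo.name} lacks annotations {missing}"
                )
        self.leading = leading
        self.lagging = lagging
        self.n_lead = len(leading.region("nascent"))
        self.n_lag = len(lagging.region("nascent"))
        self.tail_len = len(leading.region("tail"))
        self.gap_len = len(lagging.region("gap"))
        if len(lagging.region("tail")) != self.tail_len:
            raise AssemblyError("tails of the two oligos differ in length")
        self._check_tails()
        self._check_foldbacks()
        gap = lagging.region("gap")
        self.stem_depth = _fold_stem_depth(gap)
        # maximal regression: parental strands complementary over [-R, 0)
        nl = leading.region("nascent")
        r = 0
        while (
            r < min(self.gap_len, self.n_lead)
            and nl[self.n_lead - 1 - r] == gap[self.gap_len - 1 - r]
        ):
            r += 1
        self.max_regression = r

    # -- genomic index maps ------------------------------------------------

    def _lead_template(self, g: int) -> tuple[str, int]:
        return ("leading", self.tail_len - 1 - g)

    def _lead_nascent(self, g: int) -> tuple[str, int]:
        start = self.leading.annotations["nascent"][0]
        return ("leading", start + g + self.n_lead)

    def _lag_template(self, g: int) -> tuple[str, int]:
        start = self.lagging.annotations["template"][0]
        s = -self.gap_len - self.n_lag
        return ("lagging", start + (g - s))

    def _lag_nascent(self, g: int) -> tuple[str, int]:
        return ("lagging", -self.gap_len - 1 - g)

    def base_at(self, pos: tuple[str, int]) -> str:
        oligo = self.leading if pos[0] == "leading" else self.lagging
        return oligo.bases[pos[1]]

    # -- validation --------------------------------------------------------

    def _check_tails(self):
        for g in range(self.tail_len):
            a = self.base_at(self._lead_template(g))
            b = self.base_at(self._lag_template(g))
            if not is_wc_pair(a, b):
                raise AssemblyError(
                    f"tails are not complementary at tail position {g}: "
                    f"leading template {a} vs lagging template {b}"
                )

    def _check_foldbacks(self):
        for g in range(-self.n_lead, 0):
            a = self.base_at(self._lead_template(g))
            b = self.base_at(self._lead_nascent(g))
            if not is_wc_pair(a, b):
                raise AssemblyError(
                    f"leading fold-back arms not complementary at offset {g}"
                )
        for g in range(-self.gap_len - self.n_lag, -self.gap_len):
            a = self.base_at(self._lag_template(g))
            b = self.base_at(self._lag_nascent(g))
            if not is_wc_pair(a, b):
                raise AssemblyError(
                    f"lagging fold-back arms not complementary at offset {g}"
                )

    # -- pairing per regression state -------------------------------------

    def state_pairing(self, r: int) -> frozenset:
        if not 0 <= r <= self.max_regression:
            raise ParameterError(
                f"regression depth {r} outside [0, {self.max_regression}]"
            )
        pairs = set()

        def locate_gap_base(g: int) -> tuple[str, int]:
            # a repeat-region base sits on the lagging template while the
            # fork has not regressed past it, else on the displaced
            # nascent leading strand
            return self._lag_template(g) if g < -r else self._lead_nascent(g)

        for g in range(0, self.tail_len):          # parental tail duplex
            pairs.add(frozenset((self._lead_template(g), self._lag_template(g))))
        for g in range(-r, 0):                      # re-annealed parental
            pairs.add(frozenset((self._lead_template(g), self._lag_template(g))))
        for g in range(-self.n_lead, -r):           # leading arm duplex
            pairs.add(frozenset((self._lead_template(g), self._lead_nascent(g))))
        for g in range(-self.gap_len - self.n_lag, -self.gap_len):
            pairs.add(frozenset((self._lag_template(g), self._lag_nascent(g))))
        for i in range(self.stem_depth):            # repeat-arm stem
            p = -self.gap_len + i
            q = -1 - i
            pairs.add(frozenset((locate_gap_base(p), locate_gap_base(q))))
        return frozenset(pairs)


def _fold_stem_depth(gap: str) -> int:
    """Depth of the fold-back stem the single-stranded repeat region forms."""
    d = 0
    n = len(gap)
    while d < n - 1 - d and is_wc_pair(gap[d], gap[n - 1 - d]):
        d += 1
    return d


@dataclass(frozen=True)
class BranchState:
    """One isoenergetic branch-migration state of an assembled fork."""

    fork: ForkAssembly = field(compare=False, repr=False)
    regression_depth: int = 0

    @property
    def pairing(self) -> frozenset:
        return self.fork.state_pairing(self.regression_depth)

    @property
    def paired_count(self) -> int:
        return len(self.pairing)

    @property
    def is_ligatable(self) -> bool:
        """Leading 3'-OH next to the lagging 5'-P, both template-annealed.

        Requires the whole displaced repeat arm to be re-annealed onto the
        single-stranded template copy of the repeat (every stem pair joins
        a lagging-template base to a displaced nascent-leading base), and
        a 5'-phosphate on the lagging oligo.
        """
        f = self.fork
        if not f.lagging.phosphorylated_5p or f.stem_depth == 0:
            return False
        r = self.regression_depth
        for i in range(f.stem_depth):
            p, q = -f.gap_len + i, -1 - i
            if p >= -r or q < -r:  # p must be template-side, q displaced
                return False
        return True


@dataclass(frozen=True)
class ClosedFork:
    """The covalently closed product of nick ligation at a regressed fork."""

    name: str
    closed_strand: str
    junction_pos: int
    leading_name: str
    lagging_name: str

    @property
    def junction_context(self) -> str:
        j = self.junction_pos
        return self.closed_strand[max(0, j - 10) : j + 10]

    def split_at_junction(self) -> tuple[str, str]:
        """Undo the ligation: recover the two original oligo sequences."""
        return (
            self.closed_strand[: self.junction_pos],
            self.closed_strand[self.junction_pos :],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def assemble_fork(leading: OligoSpec, lagging: OligoSpec) -> ForkAssembly:
    """Anneal two fold-back oligos into the four-way fork.

    Both intramolecular fold-backs must form (nascent complementary to its
    template across the replicated region) and the two parental tails
    must be mutually complementary; a mismatch raises an
    :class:`AssemblyError` naming the offending position.
    """
    return ForkAssembly(leading, lagging)


def enumerate_branch_states(fork: ForkAssembly) -> list[BranchState]:
    """All isoenergetic regression states, r = 0 .. R.

    R is the maximal regression depth preserving full complementarity
    (the length of the parental homology across the repeat region), so a
    fork with R bases of migratable homology has R + 1 states.  Every
    state has the same number of paired bases.
    """
    states = [BranchState(fork, r) for r in range(fork.max_regression + 1)]
    counts = {s.paired_count for s in states}
    assert len(counts) == 1, f"paired-base conservation violated: {counts}"
    return states


def find_ligatable_states(fork: ForkAssembly) -> list[BranchState]:
    """The branch states in which DNA ligase can seal the cross-strand nick.

    Empty when the lagging oligo lacks its 5'-phosphate (ligase strictly
    requires one) or when no regression state places the leading 3'
    terminus on the template helix next to the lagging 5' end.
    """
    return [s for s in enumerate_branch_states(fork) if s.is_ligatable]


def ligate_closed_fork(state: BranchState) -> ClosedFork:
    """Seal the nick: one covalent strand from leading 3'-OH to lagging 5'-P."""
    if not state.is_ligatable:
        raise PreconditionError(
            f"branch state r={state.regression_depth} is not ligatable"
        )
    f = state.fork
    return ClosedFork(
        name=f"{f.leading.name}+{f.lagging.name}",
        closed_strand=f.leading.bases + f.lagging.bases,
        junction_pos=len(f.leading.bases),
        leading_name=f.leading.name,
        lagging_name=f.lagging.name,
    )


# ---------------------------------------------------------------------------
# oligo design
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _rand_bases(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def design_fork_oligos(
    arm_len: int = 7,
    spacer_len: int = 11,
    tail_len: int = 30,
    junction_site: str = "CTCGAG",
    parental_sites: tuple[str, ...] = ("GGCC", "CCATGG"),
    seed: int = 0,
    linker_len: int = 8,
    lead_extra: int = 6,
    lag_nascent: int = 18,
) -> tuple[OligoSpec, OligoSpec]:
    """Design a leading/lagging oligo pair with the published architecture.

    The repeat region behind the fork is ``arm + spacer + rc(arm)``; the
    two parental tails (``tail_len``) are complementary; the junction
    restriction site is split so that its first base is the nascent
    leading 3' terminus and the remainder is contributed by the
    5'-phosphorylated lagging nascent strand -- ligation completes the
    site.  ``parental_sites`` are placed in the parental tail duplex.
    Deterministic for a given seed.  With the defaults the oligos come
    out 100 and 99 nt with 2*arm_len + spacer_len bases of migratable
    homology.
    """
    if arm_len < 4:
        raise DesignError("arm_len must be >= 4")
    if spacer_len < 1:
        raise DesignError(
            "spacer_len must be >= 1: an interrupted repeat needs a spacer "
            "(spacer 0 is a perfect palindrome)"
        )
    w = len(junction_site)
    if w < 2 or set(junction_site.upper()) - set(_BASES):
        raise DesignError("junction_site must be a plain-ACGT site of length >= 2")
    junction_site = junction_site.upper()
    gap_len = 2 * arm_len + spacer_len
    n_lead = gap_len + lead_extra
    n_lag = lag_nascent
    if lead_extra < 1:
        raise DesignError("lead_extra must be >= 1 (regression must stop)")
    if w - 1 > n_lag:
        raise DesignError("lagging nascent strand too short to host the junction site")
    placed, cursor = [], 2
    for site in parental_sites:
        if set(site.upper()) - set(_BASES):
            raise DesignError(f"parental site {site!r} must be plain ACGT")
        if cursor + len(site) > tail_len - 2:
            raise DesignError(
                f"cannot place parental sites {parental_sites} in a "
                f"{tail_len} nt tail: {site!r} does not fit"
            )
        placed.append((cursor, site.upper()))
        cursor += len(site) + 3

    rng = np.random.default_rng(seed)
    comp = dict(zip("ACGT", "TGCA"))
    for _ in range(200):
        # leading genomic frame G over [-n_lead, tail_len), fork at 0
        g = list(_rand_bases(rng, n_lead + tail_len))

        def gset(pos, text):  # pos on the genomic axis
            for k, ch in enumerate(text):
                g[pos + n_lead + k] = ch

        arm = comp[junction_site[0]] + _rand_bases(rng, arm_len - 1)
        spacer = _rand_bases(rng, spacer_len)
        # keep the spacer from extending the repeat stem
        if spacer_len > 1 and is_wc_pair(spacer[0], spacer[-1]):
            spacer = spacer[0] + spacer[1:-1] + spacer[0]
        gset(-gap_len, arm + spacer + revcomp(arm))
        for off, site in placed:
            gset(off, site)
        # block regression past the repeat region
        want_not = comp[junction_site[1]] if w > 1 else None
        if g[n_lead - gap_len - 1] == want_not:
            g[n_lead - gap_len - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[want_not]
        gstr = "".join(g)

        # lagging genomic frame H over [s, tail_len): equal to G across the
        # repeat region and the tail; its own distal region ends with the
        # remainder of the junction site (so the lagging 5' end reads it)
        s_len = n_lag + gap_len + tail_len
        h = list(_rand_bases(rng, s_len))
        h[n_lag:] = gstr[n_lead - gap_len :]
        h[n_lag - (w - 1) : n_lag] = revcomp(junction_site[1:])
        hstr = "".join(h)

        lead_template = revcomp(gstr)
        lead_nascent = gstr[:n_lead]
        linker_a = _rand_bases(rng, linker_len)
        linker_b = _rand_bases(rng, linker_len)
        lead_bases = lead_template + linker_a + lead_nascent
        lag_nascent_seq = revcomp(hstr[:n_lag])
        lag_bases = lag_nascent_seq + linker_b + hstr

        closed = lead_bases + lag_bases
        # the completed site must appear at the junction and nowhere in the
        # leading oligo; the lagging template unavoidably reads it across
        # its duplex/gap boundary, so exactly one copy there
        if junction_site in lead_bases:
            continue
        if lag_bases.count(junction_site) != 1:
            continue
        if closed.count(junction_site) != 2:
            continue

        leading = OligoSpec(
            name=f"lead_a{arm_len}s{spacer_len}_seed{seed}",
            bases=lead_bases,
            phosphorylated_5p=False,
            annotations={
                "template": (0, n_lead + tail_len),
                "tail": (0, tail_len),
                "linker": (n_lead + tail_len, n_lead + tail_len + linker_len),
                "nascent": (n_lead + tail_len + linker_len, len(lead_bases)),
                "ir": (n_lead + tail_len + linker_len + lead_extra, len(lead_bases)),
            },
        )
        lagging = OligoSpec(
            name=f"lag_a{arm_len}s{spacer_len}_seed{seed}",
            bases=lag_bases,
            phosphorylated_5p=True,
            annotations={
                "nascent": (0, n_lag),
                "linker": (n_lag, n_lag + linker_len),
                "template": (n_lag + linker_len, len(lag_bases)),
                "gap": (2 * n_lag + linker_len, 2 * n_lag + linker_len + gap_len),
                "tail": (len(lag_bases) - tail_len, len(lag_bases)),
            },
        )
        fork = assemble_fork(leading, lagging)
        if fork.max_regression != gap_len or fork.stem_depth != arm_len:
            continue
        if not find_ligatable_states(fork):
            continue
        return leading, lagging
    raise DesignError(
        "could not satisfy the requested site placement; the junction site, "
        "repeat geometry and parental sites conflict"
    )


def fork_pcr_primers(fork: ForkAssembly, primer_len: int = 16) -> tuple[str, str]:
    """Convergent primers whose 3' ends sit in the two linker loops.

    The forward primer ends at the last base of the leading linker, the
    reverse primer's 3' end sits at the first base of the lagging linker;
    both point across the fork junction, so only a covalently closed
    (ligated) strand can template a product.
    """
    if primer_len < 15:
        raise ParameterError("primers must be >= 15 nt")
    la, lb = fork.leading.annotations["linker"]
    if lb < primer_len:
        raise ParameterError("leading oligo too short for the primer")
    primer_f = fork.leading.bases[lb - primer_len : lb]
    closed = fork.leading.bases + fork.lagging.bases
    c = len(fork.leading.bases) + fork.lagging.annotations["linker"][0]
    primer_r = revcomp(closed[c : c + primer_len])
    return primer_f, primer_r
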