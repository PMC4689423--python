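"""In-silico molecular assays: digestion, snap-back, end-labeling, PCR,
copy-number profiles and split-read signatures.

These operations predict the readouts a molecular biologist would use to
verify each intermediate of the amplification mechanism: restriction maps
of plasmids and chromosomes, the snap-back/S1 assay that detects
palindromic junction fragments by their ability to reform a half-size
intramolecular duplex, indirect end-labeling of junction regions, PCR
across novel junctions (which requires a covalently continuous template
strand and therefore distinguishes ligated from unligated forks), and
array-CGH-like copy-number staircases over ancestor coordinates.

Restriction sites are recognized in double-stranded regions only: sites
falling in single-stranded hairpin loops are immune, which is what makes
hairpin-capped fragments run slightly large on a gel while remaining
uncut at their ends.  Sizes are reported in exact bp; no gel-mobility
model is applied.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .engine import DerivedChromosome, DimericPlasmid, DogBone
from .enzymes import EnzymeDef, resolve_enzyme
from .errors import ParameterError
from .seqs import Sequence, revcomp

__all__ = [
    "Duplex",
    "RestrictionFragment",
    "SnapbackResult",
    "CNProfile",
    "PCRProduct",
    "restriction_digest",
    "snapback_assay",
    "indirect_end_label",
    "simulate_pcr",
    "cn_profile",
    "junction_split_reads",
]


@dataclass(frozen=True)
class Duplex:
    """A plain double-stranded molecule, represented by its top strand."""

    name: str
    seq: str
    circular: bool = False

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionFragment:
    """One product of a digest.

    ``seq`` is the duplex top strand; hairpin-capped end fragments carry
    their single-stranded loops in ``loop_left``/``loop_right`` (the loops
    add nucleotides -- and a slight gel up-shift -- without adding duplex
    length).  ``start``/``end`` locate the fragment on the parent top
    strand (``end`` may wrap past the origin of a circular parent).
    """

    parent: str
    seq: str
    start: int
    end: int
    loop_left: str = ""
    loop_right: str = ""
    left_overhang: str = ""
    right_overhang: str = ""
    circular: bool = False

    def __len__(self):
        return len(self.seq)

    @property
    def total_nt(self) -> int:
        """Total nucleotides in the covalent molecule (duplex + loops)."""
        return 2 * len(self.seq) + len(self.loop_left) + len(self.loop_right)


@dataclass(frozen=True)
class SnapbackResult:
    """Outcome of denature/quick-cool plus S1 nuclease on one fragment.

    A palindromic fragment of length L with central loop l reforms an
    intramolecular duplex of (L - l)/2 which survives S1; a non-foldback
    strand is degraded (``s1_resistant_len`` 0).
    """

    fragment_len: int
    is_foldback: bool
    duplex_len_after_snapback: int
    loop_len: int
    s1_resistant_len: int
    stem_start: int = 0
    left_overhang_len: int = 0
    right_overhang_len: int = 0


@dataclass(frozen=True)
class CNProfile:
    """Windowed copy number over ancestor coordinates."""

    seq_id: str
    window: int
    values: np.ndarray = field(repr=False)

    def plateaus(self, tol: float = 0.0) -> list[float]:
        """Run-length-compressed window values (for staircase inspection)."""
        out: list[float] = []
        for v in self.values:
            if not out or abs(v - out[-1]) > tol:
                out.append(float(v))
        return out


@dataclass(frozen=True)
class PCRProduct:
    seq: str
    template: str
    start: int
    end: int

    def __len__(self):
        return len(self.seq)


# ---------------------------------------------------------------------------
# restriction digestion
# ---------------------------------------------------------------------------

def _as_duplex(molecule) -> Duplex | DogBone:
    if isinstance(molecule, (DogBone, Duplex)):
        return molecule
    if isinstance(molecule, DimericPlasmid):
        return Duplex(molecule.seq_id or "plasmid", molecule.circle, circular=True)
    if isinstance(molecule, DerivedChromosome):
        return Duplex(molecule.name, molecule.rendered)
    if isinstance(molecule, Sequence):
        return Duplex(molecule.id, molecule.bases)
    if isinstance(molecule, RestrictionFragment):
        return Duplex(molecule.parent, molecule.seq)
    if isinstance(molecule, str):
        return Duplex("seq", molecule)
    raise ParameterError(f"cannot digest object of type {type(molecule).__name__}")


def _cuts_with_overhangs(
    top: str, enzymes, circular: bool
) -> list[tuple[int, str]]:
    """Sorted (top-strand cut position, 5'/3' overhang text) list."""
    if isinstance(enzymes, (str, EnzymeDef)):
        enzymes = [enzymes]
    defs = [resolve_enzyme(e) for e in enzymes]
    search = top + top[: max(len(d.site) for d in defs) - 1] if circular else top
    cuts: dict[int, str] = {}
    for d in defs:
        for c in d.top_cut_positions(search):
            pos = c % len(top) if circular else c
            if not circular and not 0 <= pos <= len(top):
                continue
            if d.overhang_len >= 0:
                ovh = search[c : c + d.overhang_len]
            else:
                ovh = search[c + d.overhang_len : c]
            cuts[pos] = ovh
    return sorted(cuts.items())


def restriction_digest(molecule, enzymes) -> list[RestrictionFragment]:
    """Digest a linear, circular or hairpin-capped duplex.

    A circular molecule with k sites yields k fragments, a linear one
    k+1.  On a hairpin-capped molecule only the duplex core is cut; the
    terminal fragments keep their single-stranded loops attached.
    Concatenating the fragments (respecting circular rotation) restores
    the parent top strand.
    """
    mol = _as_duplex(molecule)
    if isinstance(mol, DogBone):
        top = mol.unit
        cuts = _cuts_with_overhangs(top, enzymes, circular=False)
        name = mol.seq_id or "dog_bone"
        if not cuts:
            return [
                RestrictionFragment(
                    name, top, 0, len(top),
                    loop_left=mol.loop_left, loop_right=mol.loop_right,
                    circular=True,  # covalently closed circuit
                )
            ]
        bounds = [0] + [c for c, _ in cuts] + [len(top)]
        ovhs = [""] + [o for _, o in cuts] + [""]
        frags = []
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            frags.append(
                RestrictionFragment(
                    name, top[s:e], s, e,
                    loop_left=mol.loop_left if i == 0 else "",
                    loop_right=mol.loop_right if i == len(bounds) - 2 else "",
                    left_overhang=ovhs[i], right_overhang=ovhs[i + 1],
                )
            )
        return frags

    top = mol.seq
    cuts = _cuts_with_overhangs(top, enzymes, mol.circular)
    if mol.circular:
        if not cuts:
            return [RestrictionFragment(mol.name, top, 0, len(top), circular=True)]
        frags = []
        for i, (c, o) in enumerate(cuts):
            nc, no = cuts[(i + 1) % len(cuts)]
            seq = top[c:nc] if nc > c else top[c:] + top[:nc]
            frags.append(
                RestrictionFragment(
                    mol.name, seq, c, nc if nc > c else nc + len(top),
                    left_overhang=o, right_overhang=no,
                )
            )
        return frags
    bounds = [0] + [c for c, _ in cuts] + [len(top)]
    ovhs = [""] + [o for _, o in cuts] + [""]
    return [
        RestrictionFragment(
            mol.name, top[bounds[i] : bounds[i + 1]], bounds[i], bounds[i + 1],
            left_overhang=ovhs[i], right_overhang=ovhs[i + 1],
        )
        for i in range(len(bounds) - 1)
    ]


# ---------------------------------------------------------------------------
# snap-back / S1 assay
# ---------------------------------------------------------------------------

_HASH_BASE = 1_000_003
_HASH_MOD = (1 << 61) - 1


def _all_window_hashes(s: str, k: int) -> list[int]:
    n = len(s)
    if k > n:
        return []
    h = 0
    for ch in s[:k]:
        h = (h * _HASH_BASE + ord(ch)) % _HASH_MOD
    out = [h]
    drop = pow(_HASH_BASE, k - 1, _HASH_MOD)
    for i in range(n - k):
        h = ((h - ord(s[i]) * drop) * _HASH_BASE + ord(s[i + k])) % _HASH_MOD
        out.append(h)
    return out


def _best_stem_of_len(
    t: str, u: str, k: int, max_loop: int, first_only: bool
) -> list[tuple[int, int]]:
    """(a, b) pairs with t[a:a+k] == rc(t[b:b+k]) and 0 <= b-a-k <= max_loop.

    ``u`` must be rc(t).  Uses rolling hashes with direct verification.
    """
    L = len(t)
    th = _all_window_hashes(t, k)
    uh = _all_window_hashes(u, k)
    pos: dict[int, list[int]] = {}
    for ap, h in enumerate(uh):
        pos.setdefault(h, []).append(ap)
    found = []
    for a, h in enumerate(th):
        lst = pos.get(h)
        if not lst:
            continue
        # b = L - a' - k ; loop = L - a' - 2k - a must lie in [0, max_loop]
        lo_ap = L - a - 2 * k - max_loop
        hi_ap = L - a - 2 * k
        i0 = bisect_left(lst, lo_ap)
        i1 = bisect_right(lst, hi_ap)
        for ap in lst[i0:i1]:
            if t[a : a + k] == u[ap : ap + k]:
                found.append((a, L - ap - k))
                if first_only:
                    return found
    return found


def snapback_assay(
    fragment, loop_tolerance: int | None = None, min_duplex: int = 30
) -> SnapbackResult:
    """Denature/renature a duplex fragment and report its fold-back.

    Finds the maximal intramolecular fold-back of the fragment's top
    strand: the longest stem ``t[a:a+k] == rc(t[b:b+k])`` with an
    unpaired central loop (``b - a - k``, at most ``loop_tolerance`` if
    given) and unpaired terminal overhangs.  S1 nuclease removes the loop
    and the overhangs, leaving the stem duplex.  Fragments whose best
    stem is shorter than ``min_duplex`` are reported as non-foldback and
    S1-degraded.
    """
    if isinstance(fragment, RestrictionFragment):
        t = fragment.seq
    elif isinstance(fragment, Duplex):
        t = fragment.seq
    elif isinstance(fragment, Sequence):
        t = fragment.bases
    else:
        t = str(fragment)
    L = len(t)
    if L < 2:
        return SnapbackResult(L, False, 0, 0, 0)
    u = revcomp(t)
    max_loop = L if loop_tolerance is None else loop_tolerance

    lo, hi = 1, L // 2  # stem length bounds
    best_k = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _best_stem_of_len(t, u, mid, max_loop, first_only=True):
            best_k = mid
            lo = mid + 1
        else:
            hi = mid - 1
    if best_k < max(1, min_duplex):
        return SnapbackResult(L, False, best_k, 0, 0)
    hits = _best_stem_of_len(t, u, best_k, max_loop, first_only=False)
    a, b = min(hits, key=lambda ab: (ab[1] - ab[0] - best_k, ab[0]))
    loop = b - a - best_k
    return SnapbackResult(
        fragment_len=L,
        is_foldback=True,
        duplex_len_after_snapback=best_k,
        loop_len=loop,
        s1_resistant_len=best_k,
        stem_start=a,
        left_overhang_len=a,
        right_overhang_len=L - (b + best_k),
    )


# ---------------------------------------------------------------------------
# indirect end-labeling
# ---------------------------------------------------------------------------

def indirect_end_label(
    molecule, anchor_enzyme, second_enzymes, probe: str
) -> dict[str, list[int]]:
    """Sizes of probe-containing fragments in anchor + second double digests.

    Models mapping by indirect end-labeling: the molecule is digested with
    the anchor enzyme plus each second enzyme in turn, and a probe placed
    adjacent to an anchor site reports the fragments it hybridizes to.  A
    rearrangement that changes a site spacing shows up as a second band
    relative to the ancestral structure.
    """
    mol = _as_duplex(molecule)
    if isinstance(mol, DogBone):
        raise ParameterError("end-labeling expects a chromosome-like duplex")
    top = mol.seq
    probe = probe.upper()
    occs = _probe_occurrences(top, probe)
    if not occs:
        raise LookupError("probe sequence does not occur in the molecule")
    anchor = resolve_enzyme(anchor_enzyme)
    anchor_cuts = [c for c, _ in _cuts_with_overhangs(top, [anchor], mol.circular)]
    if not anchor_cuts:
        raise LookupError(f"anchor site {anchor.name} absent from the molecule")
    out: dict[str, list[int]] = {}
    for e in second_enzymes:
        ed = resolve_enzyme(e)
        frags = restriction_digest(mol, [anchor, ed])
        sizes = {
            len(f)
            for f in frags
            for (ps, pe) in occs
            if f.start <= ps and pe <= f.end
        }
        out[ed.name] = sorted(sizes, reverse=True)
    return out


def _probe_occurrences(top: str, probe: str) -> list[tuple[int, int]]:
    occs = []
    for pat in {probe, revcomp(probe)}:
        i = top.find(pat)
        while i >= 0:
            occs.append((i, i + len(pat)))
            i = top.find(pat, i + 1)
    return sorted(set(occs))


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------

def _covalent_strands(template) -> list[tuple[str, str, bool]]:
    """(name, 5'->3' strand, circular) for every covalent strand of a template."""
    if isinstance(template, tuple) and len(template) == 3:
        return [template]
    if isinstance(template, str):
        return [("template", template, False)]
    if isinstance(template, Sequence):
        return [
            (template.id, template.bases, False),
            (template.id + "_bottom", revcomp(template.bases), False),
        ]
    if isinstance(template, Duplex):
        return [
            (template.name, template.seq, template.circular),
            (template.name + "_bottom", revcomp(template.seq), template.circular),
        ]
    if isinstance(template, DogBone):
        return [(template.seq_id or "dog_bone", template.covalent_circuit, True)]
    if isinstance(template, DimericPlasmid):
        name = template.seq_id or "plasmid"
        return [
            (name, template.circle, True),
            (name + "_bottom", revcomp(template.circle), True),
        ]
    if isinstance(template, DerivedChromosome):
        return [
            (template.name, template.rendered, False),
            (template.name + "_bottom", revcomp(template.rendered), False),
        ]
    if hasattr(template, "closed_strand"):  # a ligated closed fork
        return [(getattr(template, "name", "closed_fork"), template.closed_strand, False)]
    if hasattr(template, "leading") and hasattr(template, "lagging"):
        return [
            (template.leading.name, template.leading.bases, False),
            (template.lagging.name, template.lagging.bases, False),
        ]
    raise ParameterError(f"cannot use {type(template).__name__} as a PCR template")


def _find_all(s: str, sub: str) -> list[int]:
    out, i = [], s.find(sub)
    while i >= 0:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


def simulate_pcr(
    templates, primer_f: str, primer_r: str, max_product: int = 5000
) -> list[PCRProduct]:
    """Exact-match PCR with convergent primers on covalent strands.

    A product requires both primer sites on one covalently continuous
    strand, in convergent orientation, within ``max_product``: annealing
    is perfect-match over the full primer including the 3' end.  An
    unligated fork therefore gives no product across the fork; the
    ligated molecule gives one.  No product is an empty list, not an
    error.
    """
    primer_f, primer_r = primer_f.upper(), primer_r.upper()
    for p in (primer_f, primer_r):
        if len(p) < 15:
            raise ParameterError("primers must be >= 15 nt")
        if set(p) - set("ACGT"):
            raise ParameterError("primers must be plain ACGT")
    if not isinstance(templates, list):
        templates = [templates]
    products: dict[str, PCRProduct] = {}
    for tmpl in templates:
        for name, strand, circular in _covalent_strands(tmpl):
            n = len(strand)
            s2 = strand + strand if circular else strand
            # arrangement A: primer_f sense, rc(primer_r) downstream
            # arrangement B: primer_r sense, rc(primer_f) downstream (product
            # reported reverse-complemented so it always starts with primer_f)
            for fwd, rev, flip in (
                (primer_f, revcomp(primer_r), False),
                (primer_r, revcomp(primer_f), True),
            ):
                starts = [a for a in _find_all(s2, fwd) if a < n]
                ends = _find_all(s2, rev)
                for a in starts:
                    for b in ends:
                        e = b + len(rev)
                        if b < a + len(fwd):
                            continue
                        if e - a > max_product or (circular and e - a > n):
                            continue
                        seq = s2[a:e]
                        if flip:
                            seq = revcomp(seq)
                        products.setdefault(
                            seq, PCRProduct(seq, name, a % n, e)
                        )
    return sorted(products.values(), key=lambda p: (len(p.seq), p.seq))


# ---------------------------------------------------------------------------
# copy number and split reads
# ---------------------------------------------------------------------------

def cn_profile(d: DerivedChromosome, window: int = 500) -> CNProfile:
    """Windowed copy number of the product over ancestor coordinates.

    Copy number of a window is the mean per-base count of derived
    segments covering it; the ancestor against itself is 1 everywhere,
    a triplication reads 1/3/1, an arm-deleted triplication steps
    1 -> 2 -> 3, an isochromosome reads 2 then 0.
    """
    n = len(d.ancestor)
    if not 1 <= window <= n:
        raise ParameterError(f"window must be in [1, {n}], got {window}")
    cov = d.coverage().astype(float)
    nwin = (n + window - 1) // window
    vals = np.array([cov[i * window : (i + 1) * window].mean() for i in range(nwin)])
    return CNProfile(seq_id=d.ancestor.id, window=window, values=vals)


@dataclass(frozen=True)
class SplitRead:
    name: str
    start: int
    seq: str
    label: str  # 'split' | 'flank' | 'partial'
    junction: dict | None = None


def junction_split_reads(
    d: DerivedChromosome, read_len: int = 100, step: int = 10
) -> list[SplitRead]:
    """Tile reads over the product and label their expected mapping class.

    Reads that fully cover a junction's minimal novel window cannot map
    contiguously to the ancestor on either strand (label ``split``; the
    expected signature is a split alignment between the two ancestral
    loci with an orientation flip at inverted junctions).  Reads touching
    no novel window map contiguously (``flank``); reads partially
    overlapping one are ``partial``.
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    spans = [(r.novel_span, r) for r in d.junction_records]
    widest = max((hi - lo for (lo, hi), _ in spans), default=0)
    if read_len < widest + 2:
        raise ParameterError(
            f"read_len {read_len} too short to anchor across the widest "
            f"junction window ({widest} bp)"
        )
    prod = d.rendered
    reads = []
    for i in range(0, max(1, len(prod) - read_len + 1), step):
        seq = prod[i : i + read_len]
        label, jrec = "flank", None
        for (lo, hi), r in spans:
            if i <= lo and hi <= i + read_len:
                label, jrec = "split", r
                break
        if label == "flank":
            for (lo, hi), r in spans:
                if i < hi and lo < i + read_len:
                    label, jrec = "partial", r
                    break
        reads.append(
            SplitRead(
                name=f"{d.name}_read_{i}",
                start=i,
                seq=seq,
                label=label,
                junction=jrec.to_dict() if jrec else None,
            )
        )
    return reads
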