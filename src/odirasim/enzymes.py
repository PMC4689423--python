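"""Restriction enzyme definitions and duplex site scanning.

Sites are given REBASE-style: an IUPAC recognition sequence plus the cut
offsets on the top and bottom strands, both measured from the 5' end of
the top-strand site (XhoI = CTCGAG, cut 1/5 means C^TCGA_G).  Degenerate
bases are supported; both strands are searched, with palindromic sites
reported once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ParameterError, ParseError
from .seqs import revcomp

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def iupac_regex(site: str) -> re.Pattern:
    """Compile an IUPAC site into an overlapping-match lookahead regex."""
    parts = []
    for b in site.upper():
        if b not in _IUPAC:
            raise ParameterError(f"invalid IUPAC base {b!r} in site {site!r}")
        opts = _IUPAC[b]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class EnzymeDef:
    """A Type II restriction enzyme acting on duplex DNA."""

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        if len(self.site) < 4:
            raise ParameterError(f"{self.name}: site length must be >= 4")
        if not (-1 <= self.cut_top <= len(self.site) + 1):
            raise ParameterError(f"{self.name}: cut_top outside/adjacent to site")
        if not (-1 <= self.cut_bottom <= len(self.site) + 1):
            raise ParameterError(f"{self.name}: cut_bottom outside/adjacent to site")
        iupac_regex(self.site)  # validates characters

    @property
    def is_palindromic(self) -> bool:
        return self.site.upper() == revcomp(self.site.upper())

    @property
    def overhang_len(self) -> int:
        """Positive: 5' overhang; negative: 3' overhang; zero: blunt."""
        return self.cut_bottom - self.cut_top

    def top_cut_positions(self, top: str) -> list[int]:
        """Top-strand cut coordinates of all duplex sites in ``top``.

        Scans the given strand for the site and its reverse complement
        (bottom-strand sites); for a bottom-strand site the top-strand cut
        sits at ``len(site) - cut_bottom`` from the site start.
        """
        pat = iupac_regex(self.site)
        cuts = {m.start() + self.cut_top for m in pat.finditer(top)}
        if not self.is_palindromic:
            rpat = iupac_regex(revcomp(self.site))
            cuts |= {
                m.start() + (len(self.site) - self.cut_bottom)
                for m in rpat.finditer(top)
            }
        return sorted(cuts)


# Enzymes used throughout the molecular assays, plus a few common blunt
# cutters that are convenient for building unambiguous fixtures.
DEFAULT_ENZYMES: dict[str, EnzymeDef] = {
    e.name: e
    for e in [
        EnzymeDef("XhoI", "CTCGAG", 1, 5),
        EnzymeDef("HaeIII", "GGCC", 2, 2),
        EnzymeDef("NcoI", "CCATGG", 1, 5),
        EnzymeDef("HindIII", "AAGCTT", 1, 5),
        EnzymeDef("XbaI", "TCTAGA", 1, 5),
        EnzymeDef("BglII", "AGATCT", 1, 5),
        EnzymeDef("EcoNI", "CCTNNNNNAGG", 5, 6),
        EnzymeDef("ApaLI", "GTGCAC", 1, 5),
        EnzymeDef("ApaI", "GGGCCC", 5, 1),
        EnzymeDef("AflII", "CTTAAG", 1, 5),
        EnzymeDef("KpnI", "GGTACC", 5, 1),
        EnzymeDef("EcoRI", "GAATTC", 1, 5),
        EnzymeDef("EcoRV", "GATATC", 3, 3),
        EnzymeDef("SmaI", "CCCGGG", 3, 3),
        EnzymeDef("StuI", "AGGCCT", 3, 3),
        EnzymeDef("PvuII", "CAGCTG", 3, 3),
    ]
}


def resolve_enzyme(enzyme) -> EnzymeDef:
    """Accept an :class:`EnzymeDef` or a name from the bundled table."""
    if isinstance(enzyme, EnzymeDef):
        return enzyme
    try:
        return DEFAULT_ENZYMES[str(enzyme)]
    except KeyError:
        raise LookupError(
            f"unknown enzyme {enzyme!r}; known: {sorted(DEFAULT_ENZYMES)}"
        ) from None


def load_enzyme_table(path) -> dict[str, EnzymeDef]:
    """Read a tab-separated ``name  site  cut_top  cut_bottom`` table."""
    table: dict[str, EnzymeDef] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"expected 4 tab-separated fields, got {len(parts)}", line=lineno
                )
            name, site, top, bottom = parts
            try:
                table[name] = EnzymeDef(name, site.upper(), int(top), int(bottom))
            except (ValueError, ParameterError) as exc:
                raise ParseError(f"bad enzyme definition: {exc}", line=lineno)
    return table
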