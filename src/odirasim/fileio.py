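"""Readers, writers and run configuration.

All emitted coordinates are 0-based, half-open, top-strand.  Origins are
exchanged as 6-column BED with the name in column 4 and an
``active``/``inactive`` flag in column 5 (anything other than
``inactive`` counts as active).  IIR hits are written as BED6+2 records
spanning arm-spacer-arm, with spacer length and mismatch count as the
two extra columns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .irscan import InterruptedInvertedRepeat, Origin
from .seqs import Sequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "BedRecord",
    "read_bed",
    "write_bed",
    "origins_from_bed",
    "origins_to_bed",
    "iirs_to_bed",
    "write_bedgraph",
    "write_report",
    "RunConfig",
]


def read_fasta(path) -> list[Sequence]:
    """Read a (possibly multi-record) FASTA file, preserving record order."""
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        return []
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path.name}: expected FASTA header '>' before sequence data",
                    line=lineno,
                )
            break
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path.name}: no FASTA records found", line=1)
    return [Sequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."
    extra: tuple = ()

    def to_line(self) -> str:
        fields = [self.chrom, str(self.start), str(self.end),
                  self.name, self.score, self.strand, *map(str, self.extra)]
        return "\t".join(fields)


def read_bed(path) -> list[BedRecord]:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED record needs >= 3 tab-separated fields",
                                 line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("BED start/end must be integers", line=lineno)
            if start < 0 or start >= end:
                raise ParseError(
                    f"BED interval inverted or empty: [{start}, {end})", line=lineno
                )
            recs.append(
                BedRecord(
                    parts[0], start, end,
                    parts[3] if len(parts) > 3 else ".",
                    parts[4] if len(parts) > 4 else ".",
                    parts[5] if len(parts) > 5 else ".",
                    tuple(parts[6:]),
                )
            )
    return recs


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_line() + "\n")


def origins_from_bed(records) -> list[Origin]:
    """BED -> origins; column 5 holds the 'active'/'inactive' flag."""
    return [
        Origin(r.chrom, r.start, r.end, r.name,
               active=r.score.lower() != "inactive")
        for r in records
    ]


def origins_to_bed(origins) -> list[BedRecord]:
    return [
        BedRecord(o.seq_id, o.start, o.end, o.name or ".",
                  "active" if o.active else "inactive", "+")
        for o in origins
    ]


def iirs_to_bed(hits) -> list[BedRecord]:
    return [
        BedRecord(h.seq_id, h.start, h.end, f"IIR_{i}", "0", "+",
                  extra=(h.spacer_len, h.mismatches))
        for i, h in enumerate(hits)
    ]


def iirs_from_bed(records, arm_len: int) -> list[InterruptedInvertedRepeat]:
    return [
        InterruptedInvertedRepeat(
            r.chrom, r.start, int(r.extra[0]) if r.extra else
            (r.end - r.start - 2 * arm_len), arm_len,
            int(r.extra[1]) if len(r.extra) > 1 else 0,
        )
        for r in records
    ]


def write_bedgraph(profile, path) -> None:
    """CN profile -> bedGraph over ancestor coordinates (merged runs)."""
    with open(path, "w") as fh:
        start = 0
        prev = None
        pos = 0
        for v in profile.values:
            if prev is not None and v != prev:
                fh.write(f"{profile.seq_id}\t{start}\t{pos}\t{prev:g}\n")
                start = pos
            prev = v
            pos += profile.window
        if prev is not None:
            fh.write(f"{profile.seq_id}\t{start}\t{pos}\t{prev:g}\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def write_oligo(oligo, fasta_path, ann_path) -> None:
    """Oligo -> FASTA plus a sidecar annotation table (label, start, end)."""
    write_fasta([Sequence(oligo.name, oligo.bases)], fasta_path)
    with open(ann_path, "w") as fh:
        fh.write(f"# phosphorylated_5p\t{str(oligo.phosphorylated_5p).lower()}\n")
        for label, (a, b) in oligo.annotations.items():
            fh.write(f"{label}\t{a}\t{b}\n")


def read_oligo(fasta_path, ann_path):
    from .fork_model import OligoSpec

    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ParseError(f"{fasta_path}: expected exactly one oligo record")
    phos = False
    ann = {}
    with open(ann_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line.startswith("#"):
                if "phosphorylated_5p" in parts[0] and len(parts) > 1:
                    phos = parts[1].strip().lower() == "true"
                continue
            if len(parts) != 3:
                raise ParseError("annotation lines need label, start, end",
                                 line=lineno)
            ann[parts[0]] = (int(parts[1]), int(parts[2]))
    return OligoSpec(seqs[0].id, seqs[0].bases, phos, ann)


@dataclass
class RunConfig:
    """Resolved parameters of one CLI run; written beside every output."""

    command: str = ""
    inputs: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    engine: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
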