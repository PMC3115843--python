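"""Gapped multiple alignments on a 1-based reference coordinate system.

The plastome comparisons in this package all run over a single multiple
alignment of complete (or scaled-down synthetic) chloroplast genomes.  One
taxon is designated the *reference*; every variant position downstream is
reported as a 1-based ungapped position on that taxon, matching how positions
are quoted against a published genome sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
_VALID = set("ACGTN-")


@dataclass
class MultiAlignment:
    """An aligned set of genome sequences over the alphabet {A,C,G,T,N,-}.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels.
    rows
        Equal-length gapped sequences, one per taxon, upper-case.
    reference
        Label of the taxon whose ungapped coordinates anchor all variant
        positions.  Defaults to the first taxon.
    """

    taxa: list[str]
    rows: list[str]
    reference: str = ""
    _colmap: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0])
        self.rows = [r.upper() for r in self.rows]
        for label, row in zip(self.taxa, self.rows):
            if len(row) != ncol:
                raise ValueError(f"ragged alignment: row {label!r}")
            bad = set(row) - _VALID
            if bad:
                raise ValueError(f"invalid characters in {label!r}: {sorted(bad)}")
        if not self.reference:
            self.reference = self.taxa[0]
        if self.reference not in self.taxa:
            raise ValueError(f"reference {self.reference!r} not among taxa")
        ref = np.frombuffer(self.row(self.reference).encode(), dtype="S1")
        # cumulative count of non-gap reference bases; 1-based position per column
        self._colmap = np.cumsum(ref != b"-")

    # -- basic geometry -----------------------------------------------------

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> str:
        """The alignment column at 0-based index ``i``, taxon order."""
        return "".join(r[i] for r in self.rows)

    # -- coordinate map -----------------------------------------------------

    def ref_position(self, col: int) -> int:
        """1-based ungapped reference position for 0-based column ``col``.

        For columns where the reference is gapped (insertions relative to the
        reference) this is the position of the preceding reference base, or 0
        before the first one.
        """
        return int(self._colmap[col])

    def column_of(self, ref_pos: int) -> int:
        """0-based alignment column holding reference base ``ref_pos`` (1-based)."""
        if not 1 <= ref_pos <= int(self._colmap[-1]):
            raise IndexError(f"reference position {ref_pos} out of range")
        return int(np.searchsorted(self._colmap, ref_pos))

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path, reference: str | None = None) -> "MultiAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        taxa = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        return cls(taxa, rows, reference or taxa[0])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(self.taxa, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GeneInterval:
    """One annotated coding interval on reference coordinates (1-based, inclusive)."""

    start: int
    end: int
    strand: str
    name: str
    frame: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval for {self.name}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def read_gff3(path) -> list[GeneInterval]:
    """Read gene/CDS intervals from a GFF3 file (9-column TSV)."""
    out: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f[2]
            frame = 0 if f[7] == "." else int(f[7])
            out.append(GeneInterval(int(f[3]), int(f[4]), f[6], name, frame))
    return out


def write_gff3(intervals, path, seqid: str = "ref", feature: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(
                f"{seqid}\tchlorotype\t{feature}\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t{iv.frame}\tID={iv.name};Name={iv.name}\n"
            )
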