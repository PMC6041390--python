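"""Germline V/J reference handling.

A reference here is a small FASTA of heavy-chain V and J segments plus a
tab-separated anchors file giving, for every record, its segment class and
the codon coordinate of the conserved residue that delimits CDR3:

* V genes carry the 2nd-CYS (Cys104 in IMGT numbering) as their last
  anchoring residue; ``cys104_codon_index`` is the 0-based codon index of
  that cysteine within the V nucleotide sequence.
* J genes carry the conserved TRP/PHE of the W(F)GxG motif (Trp118);
  ``trp118_codon_offset`` is the 0-based codon index of that residue within
  the J segment's reading frame.

All internal coordinates are 0-based; reports use 1-based positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_NT = set("ACGTN")


class GermlineError(ValueError):
    """Raised when a reference file violates a germline invariant."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline segment with its CDR3 anchor coordinate."""

    name: str
    segment: str  # "V" or "J"
    nt_seq: str
    anchor_codon_index: int  # Cys104 codon (V) or Trp118 codon offset (J)
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise GermlineError(f"{self.name}: segment must be V or J, got {self.segment!r}")
        if len(self.nt_seq) < 1:
            raise GermlineError(f"{self.name}: empty sequence")
        bad = set(self.nt_seq) - _VALID_NT
        if bad:
            raise GermlineError(f"{self.name}: non-ACGT/N characters {sorted(bad)}")
        aa = self.anchor_aa
        if self.segment == "V" and aa != "C":
            raise GermlineError(
                f"{self.name}: Cys104 codon at index {self.anchor_codon_index} "
                f"translates to {aa!r}, expected C"
            )
        if self.segment == "J" and aa not in ("W", "F"):
            raise GermlineError(
                f"{self.name}: Trp118 codon at offset {self.anchor_codon_index} "
                f"translates to {aa!r}, expected W or F"
            )

    @property
    def anchor_aa(self) -> str:
        start = 3 * self.anchor_codon_index
        codon = self.nt_seq[start : start + 3]
        if len(codon) < 3:
            raise GermlineError(f"{self.name}: anchor codon index {self.anchor_codon_index} outside sequence")
        return str(Seq(codon).translate())

    @property
    def cys104_codon_index(self) -> int:
        if self.segment != "V":
            raise AttributeError("cys104_codon_index is defined for V genes only")
        return self.anchor_codon_index

    @property
    def trp118_codon_offset(self) -> int:
        if self.segment != "J":
            raise AttributeError("trp118_codon_offset is defined for J genes only")
        return self.anchor_codon_index


@dataclass
class GermlineDB:
    """Collection of germline genes keyed by (segment, name)."""

    genes: dict[tuple[str, str], GermlineGene] = field(default_factory=dict)

    def add(self, gene: GermlineGene) -> None:
        key = (gene.segment, gene.name)
        if key in self.genes:
            raise GermlineError(f"duplicate germline entry {key}")
        self.genes[key] = gene

    def get(self, segment: str, name: str) -> GermlineGene:
        return self.genes[(segment, name)]

    def by_segment(self, segment: str) -> list[GermlineGene]:
        return [g for (seg, _), g in sorted(self.genes.items()) if seg == segment]

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        if not self.genes:
            raise GermlineError("reference contains no genes")

    def require_segment(self, segment: str) -> None:
        """Raise unless the reference has at least one gene of ``segment``.

        Checked lazily at assignment time so that partial references (e.g.
        a V-only FASTA) remain loadable and inspectable.
        """
        if not self.by_segment(segment):
            raise GermlineError(f"reference has no {segment} genes")


def read_anchors(anchors_path: str | Path) -> dict[str, tuple[str, int]]:
    """Read the anchors TSV (id, segment, anchor_codon_index)."""
    anchors: dict[str, tuple[str, int]] = {}
    with open(anchors_path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise GermlineError(f"anchors file: malformed row {row!r}")
            name, segment, idx = row
            anchors[name] = (segment, int(idx))
    return anchors


def load_germline(fasta_path: str | Path, anchors_path: str | Path) -> GermlineDB:
    """Load a V/J reference from FASTA + anchors TSV.

    Every FASTA record must have an anchor entry; V anchors must translate
    to C and J anchors to W or F, otherwise a :class:`GermlineError` is
    raised naming the offending record. ``N`` bases are allowed and flagged.
    """
    anchors = read_anchors(anchors_path)
    db = GermlineDB()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in anchors:
            raise GermlineError(f"no anchor entry for FASTA record {rec.id!r}")
        segment, idx = anchors[rec.id]
        seq = str(rec.seq).upper()
        db.add(
            GermlineGene(
                name=rec.id,
                segment=segment,
                nt_seq=seq,
                anchor_codon_index=idx,
                has_ambiguous="N" in seq,
            )
        )
    db.validate()
    return db


def write_germline(db: GermlineDB, fasta_path: str | Path, anchors_path: str | Path) -> None:
    """Write the reference back out (60-column FASTA + anchors TSV)."""
    records = [
        SeqRecord(Seq(g.nt_seq), id=g.name, description="")
        for g in db.by_segment("V") + db.by_segment("J")
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(anchors_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in db.by_segment("V") + db.by_segment("J"):
            writer.writerow([g.name, g.segment, g.anchor_codon_index])
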