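"""Germline V/J/C segment model with conserved-anchor annotations.

The CDR3 junction of a rearranged TCR beta chain is delimited by two
conserved residues: a cysteine near the 3' end of the V segment and a
phenylalanine (part of the F-G-X-G motif) near the 5' end of the J segment.
Rather than inferring these positions through IMGT numbering, every segment
carries an explicit 0-based ``anchor_nt`` offset of the first base of its
anchor codon.  All coordinates in this package are 0-based, half-open.

A small synthetic germline set (8 V, 6 J, 1 C) is bundled so that the
simulator and annotator run without any external download; a user-supplied
reference in the same FASTA + anchor-table format is a drop-in replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneSegment",
    "GermlineReference",
    "ReferenceError",
    "anchor_motif_check",
    "load_reference",
    "write_reference",
    "bundled_reference",
]

_VALID_KINDS = ("V", "J", "C")
_CYS_CODONS = ("TGT", "TGC")
_PHE_CODONS = ("TTT", "TTC")


class ReferenceError(ValueError):
    """Raised for malformed reference files or invalid segments."""


@dataclass(frozen=True)
class GeneSegment:
    """A germline gene segment with its conserved-anchor coordinate.

    ``anchor_nt`` is the 0-based offset of the first base of the conserved
    Cys codon (V) or Phe codon (J); ``None`` for C segments.
    """

    name: str
    kind: str
    seq: str
    anchor_nt: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ReferenceError(f"segment {self.name!r}: kind must be one of {_VALID_KINDS}")
        if not self.seq:
            raise ReferenceError(f"segment {self.name!r}: empty sequence")
        if set(self.seq) - set("ACGT"):
            raise ReferenceError(f"segment {self.name!r}: sequence must be uppercase DNA over ACGT")
        if self.kind == "C":
            if self.anchor_nt is not None:
                raise ReferenceError(f"segment {self.name!r}: C segments carry no anchor")
            return
        if self.anchor_nt is None:
            raise ReferenceError(f"segment {self.name!r}: {self.kind} segment requires anchor_nt")
        if self.anchor_nt < 0 or self.anchor_nt + 3 > len(self.seq):
            raise ReferenceError(f"segment {self.name!r}: anchor_nt out of range")
        codon = self.anchor_codon
        if self.kind == "V" and codon not in _CYS_CODONS:
            raise ReferenceError(
                f"segment {self.name!r}: anchor codon {codon} does not encode Cys"
            )
        if self.kind == "J":
            if codon not in _PHE_CODONS:
                raise ReferenceError(
                    f"segment {self.name!r}: anchor codon {codon} does not encode Phe"
                )
            if not _fgxg_ok(self.seq, self.anchor_nt):
                raise ReferenceError(
                    f"segment {self.name!r}: F-G-X-G motif not found at the anchor"
                )

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_nt is None:
            return None
        return self.seq[self.anchor_nt : self.anchor_nt + 3]


def _fgxg_ok(seq: str, anchor_nt: int) -> bool:
    """True iff the four codons starting at the anchor translate to F-G-X-G."""
    window = seq[anchor_nt : anchor_nt + 12]
    if len(window) < 12:
        return False
    aa = str(Seq(window).translate())
    return aa[0] == "F" and aa[1] == "G" and aa[3] == "G"


def anchor_motif_check(seg: GeneSegment) -> bool:
    """Check that the segment's anchor codon encodes the conserved residue.

    Returns True iff the codon at ``anchor_nt`` translates to C (V segments)
    or F (J segments).  C segments have no anchor and are unsupported.
    """
    if seg.kind == "C":
        raise ReferenceError("anchor_motif_check is undefined for C segments")
    codon = seg.anchor_codon
    target = "C" if seg.kind == "V" else "F"
    return str(Seq(codon).translate()) == target


@dataclass
class GermlineReference:
    """A validated collection of germline segments, unique by name."""

    segments: list[GeneSegment]
    _by_name: dict[str, GeneSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_name: dict[str, GeneSegment] = {}
        for seg in self.segments:
            if seg.name in by_name:
                raise ReferenceError(f"duplicate segment name {seg.name!r}")
            by_name[seg.name] = seg
        for kind in _VALID_KINDS:
            if not any(s.kind == kind for s in self.segments):
                raise ReferenceError(f"reference has no segment of kind {kind}")
        self._by_name = by_name

    def __getitem__(self, name: str) -> GeneSegment:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.segments)

    def by_kind(self, kind: str) -> list[GeneSegment]:
        return sorted((s for s in self.segments if s.kind == kind), key=lambda s: s.name)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(self.by_kind(k)) for k in _VALID_KINDS}


def _anchor_sidecar(fasta_path: Path) -> Path:
    return fasta_path.with_suffix(".anchors.tsv")


def load_reference(fasta_path: str | Path, anchors_path: str | Path | None = None) -> GermlineReference:
    """Load a germline reference from FASTA plus a `name kind anchor_nt` table.

    The anchor table defaults to ``<fasta stem>.anchors.tsv`` next to the
    FASTA.  Every segment is validated against the anchor-codon invariants.
    """
    fasta_path = Path(fasta_path)
    if anchors_path is None:
        anchors_path = _anchor_sidecar(fasta_path)
    anchors_path = Path(anchors_path)
    if not fasta_path.exists():
        raise ReferenceError(f"reference FASTA not found: {fasta_path}")
    if not anchors_path.exists():
        raise ReferenceError(f"anchor table not found: {anchors_path}")

    meta: dict[str, tuple[str, int | None]] = {}
    with open(anchors_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "name":  # header
                continue
            if len(fields) != 3:
                raise ReferenceError(
                    f"{anchors_path.name}:{lineno}: expected 3 tab-separated fields"
                )
            name, kind, anchor = fields
            if name in meta:
                raise ReferenceError(f"{anchors_path.name}:{lineno}: duplicate segment name {name!r}")
            try:
                anchor_nt = int(anchor) if anchor != "" else None
            except ValueError:
                raise ReferenceError(
                    f"{anchors_path.name}:{lineno}: anchor_nt {anchor!r} is not an integer"
                ) from None
            meta[name] = (kind, anchor_nt)

    segments: list[GeneSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ReferenceError(f"duplicate segment name {rec.id!r} in {fasta_path.name}")
        seen.add(rec.id)
        if rec.id not in meta:
            raise ReferenceError(f"segment {rec.id!r} has no entry in {anchors_path.name}")
        kind, anchor_nt = meta[rec.id]
        segments.append(GeneSegment(rec.id, kind, str(rec.seq).upper(), anchor_nt))
    missing = set(meta) - seen
    if missing:
        raise ReferenceError(f"anchor table entries without FASTA record: {sorted(missing)}")
    if not segments:
        raise ReferenceError(f"no FASTA records in {fasta_path}")
    return GermlineReference(segments)


def write_reference(ref: GermlineReference, fasta_path: str | Path,
                    anchors_path: str | Path | None = None) -> None:
    """Write a reference back out in the FASTA + anchor-table format."""
    fasta_path = Path(fasta_path)
    if anchors_path is None:
        anchors_path = _anchor_sidecar(fasta_path)
    with open(fasta_path, "w") as fa, open(anchors_path, "w") as tsv:
        tsv.write("name\tkind\tanchor_nt\n")
        for seg in ref.segments:
            fa.write(f">{seg.name}\n{seg.seq}\n")
            anchor = "" if seg.anchor_nt is None else str(seg.anchor_nt)
            tsv.write(f"{seg.name}\t{seg.kind}\t{anchor}\n")


def bundled_reference() -> GermlineReference:
    """The bundled synthetic mini-reference (8 V, 6 J, 1 C segments)."""
    data = resources.files("umirep") / "data"
    return load_reference(Path(str(data / "germline.fasta")))
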