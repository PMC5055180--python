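"""Per-molecule consensus calling from the reads of one barcode tag group.

Reads sharing a tag are (in truth) copies of one cDNA molecule, typically at
>99% identity, so a center-star multiple alignment — every read globally
aligned to the longest read and the pairwise gaps projected into a common
frame ("once a gap, always a gap") — is adequate.  The consensus takes, at
each column, the symbol (base or gap) carried by a strict majority of more
than 80% of the reads covering that column; columns without such a majority
yield N.  Groups with more than 50 reads use only the 50 longest.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from .demux import TagGroup

__all__ = [
    "ConsensusRecord",
    "cap_reads",
    "star_align",
    "call_consensus",
    "build_consensus",
]

DEFAULT_READ_CAP = 50
DEFAULT_MAJORITY = 0.80

# alignment scoring shared by consensus and annotation:
# match +1, mismatch -1, gap open -2, gap extension -1
def make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


@dataclass(frozen=True)
class ConsensusRecord:
    tag: str
    n_reads_used: int
    consensus_nt: str
    n_ambiguous_columns: int


def cap_reads(reads: list[str], cap: int = DEFAULT_READ_CAP) -> list[str]:
    """At most ``cap`` reads: the longest ones, ties by order of appearance."""
    if len(reads) <= cap:
        return list(reads)
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), i))[:cap]
    order.sort()
    return [reads[i] for i in order]


def star_align(reads: list[str]) -> list[str]:
    """Center-star alignment: all rows padded with '-' to equal length.

    The longest read (first on ties) is the center; each other read is
    globally aligned to it and the pairwise gaps are merged into one master
    coordinate frame ("once a gap, always a gap").  Within one insertion
    slot, reads inserting the same base at the same offset share a column,
    while different inserted bases occupy distinct columns — so independent
    single-read insertion errors never pile up into one column.  Row order
    matches input order.
    """
    if not reads:
        raise ValueError("cannot align an empty read group")
    if len(set(reads)) == 1:
        return list(reads)
    center_idx = min(i for i in range(len(reads))
                     if len(reads[i]) == max(map(len, reads)))
    center = reads[center_idx]
    L = len(center)

    aligner = make_aligner("global")
    cache: dict[str, tuple[str, dict[int, str]]] = {}

    def decompose(read: str) -> tuple[str, dict[int, str]]:
        """Per center position: the read's aligned char ('-' if gapped) and
        the read's inserted string before each center position."""
        if read == center:
            return center, {}
        hit = cache.get(read)
        if hit is not None:
            return hit
        aln = aligner.align(center, read)[0]
        cg, rg = aln[0], aln[1]
        chars: list[str] = []
        inserts: dict[int, str] = {}
        pending: list[str] = []
        pos = 0
        for c_ch, r_ch in zip(cg, rg):
            if c_ch == "-":
                pending.append(r_ch)
            else:
                if pending:
                    inserts[pos] = "".join(pending)
                    pending = []
                chars.append(r_ch)
                pos += 1
        if pending:
            inserts[L] = "".join(pending)
        hit = ("".join(chars), inserts)
        cache[read] = hit
        return hit

    decomposed = [decompose(r) if i != center_idx else (center, {})
                  for i, r in enumerate(reads)]

    # slot layout: one column per distinct (offset, base) insertion
    slot_columns: dict[int, list[tuple[int, str]]] = {}
    for _, inserts in decomposed:
        for pos, s in inserts.items():
            cols = slot_columns.setdefault(pos, [])
            for p, b in enumerate(s):
                if (p, b) not in cols:
                    cols.append((p, b))
    for cols in slot_columns.values():
        cols.sort()

    def render(chars: str, inserts: dict[int, str]) -> str:
        out: list[str] = []
        for pos in range(L + 1):
            cols = slot_columns.get(pos)
            if cols:
                s = inserts.get(pos, "")
                out.append("".join(b if p < len(s) and s[p] == b else "-"
                                   for p, b in cols))
            if pos < L:
                out.append(chars[pos])
        return "".join(out)

    rows = [render(chars, inserts) for chars, inserts in decomposed]
    assert len({len(r) for r in rows}) == 1
    return rows


def call_consensus(rows: list[str], majority: float = DEFAULT_MAJORITY) -> tuple[str, int]:
    """Strict >``majority`` per-column consensus over covering rows.

    A row covers a column iff the column lies between its first and last
    non-gap symbol (leading/trailing gaps mean the read simply does not
    extend there).  A winning gap symbol emits nothing; no winner emits N.
    Returns ``(consensus, n_ambiguous_columns)``.
    """
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    spans = []
    for r in rows:
        if not r.strip("-"):
            spans.append((width, -1))
            continue
        first = len(r) - len(r.lstrip("-"))
        last = len(r.rstrip("-")) - 1
        spans.append((first, last))
    out: list[str] = []
    n_ambiguous = 0
    for j in range(width):
        counts: dict[str, int] = {}
        ncov = 0
        for r, (first, last) in zip(rows, spans):
            if first <= j <= last:
                ncov += 1
                ch = r[j]
                counts[ch] = counts.get(ch, 0) + 1
        if ncov == 0:
            continue
        best_ch = max(counts, key=lambda c: (counts[c], c))
        if counts[best_ch] > majority * ncov:
            if best_ch != "-":
                out.append(best_ch)
        else:
            out.append("N")
            n_ambiguous += 1
    return "".join(out), n_ambiguous


def build_consensus(group: TagGroup, cap: int = DEFAULT_READ_CAP,
                    majority: float = DEFAULT_MAJORITY) -> ConsensusRecord:
    used = cap_reads(group.reads, cap)
    if len(set(used)) == 1:           # identical reads: no alignment needed
        return ConsensusRecord(group.tag, len(used), used[0], 0)
    rows = star_align(used)
    consensus, n_amb = call_consensus(rows, majority)
    return ConsensusRecord(group.tag, len(used), consensus, n_amb)
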