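"""Barcode-tag demultiplexing, length filtering and molecule counting.

Raw reads are split into sample index (first 5 nt, exact match), barcode tag
(bases between the index and the spacer) and payload (bases after the
spacer).  Because indel errors dominate on the sequencing platform, errors
inside the 12-nt barcode show up as 11- or 13-nt tags; the fraction of
error-free (12-nt) tags is monitored per reads-per-tag bin, the bins where
that fraction falls below 90% are removed via a read-count threshold r*, and
the surviving 12-nt tag groups are the counted molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .simulate import SPACER

__all__ = [
    "RawRead",
    "TagGroup",
    "TagLengthReport",
    "ThresholdError",
    "parse_read",
    "length_filter",
    "demultiplex",
    "group_by_tag",
    "merge_length_variants",
    "tag_error_profile",
    "apply_threshold",
]

DEFAULT_MIN_LEN = 150
DEFAULT_ERROR_FREE_CUT = 0.90
_SPACER_WINDOW = (15, 20)   # allowed spacer start positions (tag lengths 10-15)


class ThresholdError(RuntimeError):
    """No reads-per-tag threshold satisfies the error-free-fraction cut."""


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sample_index: str
    tag: str
    payload: str
    payload_plus_spacer_len: int


@dataclass
class TagGroup:
    """All reads sharing one exact barcode tag."""

    tag: str
    reads: list[str] = field(default_factory=list)
    is_derivative: bool = False
    parent_tag: str | None = None
    merged_children: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def length_class(self) -> str:
        n = len(self.tag)
        return str(n) if n in (11, 12, 13) else "other"


@dataclass
class TagLengthReport:
    """Per reads-per-tag error-free fractions and the chosen threshold r*.

    ``bins`` maps reads-per-tag r to ``(n12, n_derivative, fraction)``;
    fraction is None for empty bins.
    """

    bins: dict[int, tuple[int, int, float | None]]
    r_star: int | None
    error_free_cut: float = DEFAULT_ERROR_FREE_CUT

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("r\tn12\tnderiv\tfraction\n")
            for r in sorted(self.bins):
                n12, nderiv, frac = self.bins[r]
                fh.write(f"{r}\t{n12}\t{nderiv}\t{'' if frac is None else f'{frac:.6f}'}\n")


def parse_read(read_id: str, seq: str, known_indices: set[str] | list[str],
               spacer: str = SPACER, max_spacer_edits: int = 1,
               window: tuple[int, int] = _SPACER_WINDOW) -> tuple[RawRead | None, str | None]:
    """Split one read into index / tag / payload.

    The first 5 nt must match a known sample index exactly.  The spacer is
    located as the best match (<= ``max_spacer_edits`` edits) starting at a
    position inside ``window``; the tag is everything between index and
    spacer.  Returns ``(RawRead, None)`` or ``(None, reason)`` with reason
    ``"unknown_index"`` or ``"no_spacer"``.
    """
    index = seq[:5]
    if index not in known_indices:
        return None, "unknown_index"
    lo, hi = window
    L = len(spacer)
    best: tuple[int, int, int] | None = None   # (distance, start, spacer_end)
    for s in range(lo, min(hi, max(len(seq) - 1, 0)) + 1):
        if seq[s : s + L] == spacer:
            best = (0, s, s + L)
            break
    if best is None and max_spacer_edits > 0:
        for s in range(lo, min(hi, max(len(seq) - 1, 0)) + 1):
            target = seq[s : s + L + max_spacer_edits]
            if not target:
                continue
            res = edlib.align(spacer, target, mode="SHW", task="locations",
                              k=max_spacer_edits)
            if res["editDistance"] < 0:
                continue
            cand = (res["editDistance"], s, s + res["locations"][0][1] + 1)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return None, "no_spacer"
    _, start, spacer_end = best
    return RawRead(
        read_id=read_id,
        sample_index=index,
        tag=seq[5:start],
        payload=seq[spacer_end:],
        payload_plus_spacer_len=len(seq) - start,
    ), None


def length_filter(read: RawRead, min_len: int = DEFAULT_MIN_LEN) -> bool:
    """Keep iff spacer + following sequence is at least ``min_len`` bases."""
    return read.payload_plus_spacer_len >= min_len


def demultiplex(reads, known_indices, spacer: str = SPACER,
                min_len: int = DEFAULT_MIN_LEN
                ) -> tuple[dict[str, list[RawRead]], dict[str, int]]:
    """Parse and length-filter a read stream, split by sample index.

    ``reads`` yields ``(read_id, sequence)``.  Returns per-index RawRead
    lists and a tally of rejection reasons (including ``"short"``).
    """
    by_index: dict[str, list[RawRead]] = {i: [] for i in known_indices}
    tally = {"unknown_index": 0, "no_spacer": 0, "short": 0, "kept": 0}
    for read_id, seq in reads:
        raw, reason = parse_read(read_id, seq, known_indices, spacer)
        if raw is None:
            tally[reason] += 1
            continue
        if not length_filter(raw, min_len):
            tally["short"] += 1
            continue
        tally["kept"] += 1
        by_index[raw.sample_index].append(raw)
    return by_index, tally


def group_by_tag(raw_reads: list[RawRead]) -> dict[str, TagGroup]:
    groups: dict[str, TagGroup] = {}
    for r in raw_reads:
        g = groups.get(r.tag)
        if g is None:
            g = groups[r.tag] = TagGroup(r.tag)
        g.reads.append(r.payload)
    return groups


def _indel_neighbours_12(tag: str) -> set[str]:
    """All 12-mers at exactly one indel from an 11- or 13-mer tag."""
    out: set[str] = set()
    if len(tag) == 11:
        for p in range(12):
            for b in "ACGT":
                out.add(tag[:p] + b + tag[p:])
    elif len(tag) == 13:
        for p in range(13):
            out.add(tag[:p] + tag[p + 1 :])
    return out


def merge_length_variants(groups: dict[str, TagGroup]) -> dict[str, TagGroup]:
    """Mark 11/13-nt tags that are single-indel derivatives of a 12-nt tag.

    Derivative reads are *not* pooled into the parent group; derivatives are
    used only for the tag-error profile and then discarded.  A tag within
    distance 1 of several 12-nt tags goes to the one with most reads, ties
    broken by lexicographically smallest tag.
    """
    twelve = {t for t in groups if len(t) == 12}
    for tag, g in groups.items():
        if len(tag) not in (11, 13):
            continue
        candidates = _indel_neighbours_12(tag) & twelve
        if not candidates:
            continue
        parent = min(candidates, key=lambda t: (-groups[t].n_reads, t))
        g.is_derivative = True
        g.parent_tag = parent
        groups[parent].merged_children.append(tag)
    return groups


def tag_error_profile(groups: dict[str, TagGroup],
                      error_free_cut: float = DEFAULT_ERROR_FREE_CUT) -> TagLengthReport:
    """Per reads-per-tag bin, the fraction of 12-nt tags among 12-nt +
    single-indel-derivative tags, and the smallest threshold r* such that
    every non-empty bin at or above r* passes ``error_free_cut``.
    """
    n12: dict[int, int] = {}
    nderiv: dict[int, int] = {}
    for g in groups.values():
        if len(g.tag) == 12:
            n12[g.n_reads] = n12.get(g.n_reads, 0) + 1
        elif g.is_derivative:
            nderiv[g.n_reads] = nderiv.get(g.n_reads, 0) + 1
    rs = sorted(set(n12) | set(nderiv))
    bins: dict[int, tuple[int, int, float | None]] = {}
    for r in rs:
        a, b = n12.get(r, 0), nderiv.get(r, 0)
        frac = a / (a + b) if (a + b) > 0 else None
        bins[r] = (a, b, frac)
    r_star: int | None = None
    for r in reversed(rs):
        frac = bins[r][2]
        if frac is not None and frac < error_free_cut:
            break
        r_star = r
    if r_star is None:
        raise ThresholdError(
            "every reads-per-tag bin falls below the error-free cut "
            f"({error_free_cut:.0%}); cannot choose a read-count threshold"
        )
    return TagLengthReport(bins=bins, r_star=r_star, error_free_cut=error_free_cut)


def apply_threshold(groups: dict[str, TagGroup], r_star: int) -> list[TagGroup]:
    """Retained molecules: 12-nt, non-derivative tags with >= r* reads."""
    return [g for tag, g in sorted(groups.items())
            if len(tag) == 12 and not g.is_derivative and g.n_reads >= r_star]
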