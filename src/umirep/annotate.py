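"""V/J assignment, CDR3 extraction and productivity filtering.

Consensus sequences arrive in cDNA (antisense) orientation and are first
re-oriented to the mRNA sense strand.  Each germline V and J segment is then
locally aligned against the sense sequence (match +1, mismatch -1, gap open
-2, extension -1) and the best hit per kind is kept.  The CDR3 is the
sub-sequence from the first base of the V segment's conserved Cys codon
through the last base of the J segment's conserved Phe codon, both mapped
onto the consensus through the alignments (an exclusive-anchor convention is
available via ``anchor_convention="exclusive"``).  Translations with a frame
shift, a stop codon or an ambiguous base are discarded with a reason code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .consensus import ConsensusRecord, make_aligner
from .reference import GermlineReference
from .simulate import revcomp

__all__ = [
    "SegmentHit",
    "MoleculeAnnotation",
    "Discard",
    "orient",
    "align_segments",
    "extract_cdr3",
    "translate_and_filter",
    "annotate_records",
    "aggregate_clonotypes",
    "aggregate_aa",
]

DEFAULT_MIN_V_SCORE = 20
DEFAULT_MIN_J_SCORE = 15


@dataclass(frozen=True)
class SegmentHit:
    """Best local alignment of one germline segment onto a sense sequence."""

    segment_name: str
    score: float
    query_start: int       # on the sense/consensus sequence, 0-based half-open
    query_end: int
    target_start: int      # on the germline segment
    target_end: int
    identity: float
    blocks: tuple = ()     # ((qstart, qend), (tstart, tend)) aligned block pairs


class Discard(Exception):
    """A record leaving the pipeline, carrying its reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class MoleculeAnnotation:
    tag: str
    v_name: str
    j_name: str
    cdr3_nt: str
    cdr3_aa: str


_LOCAL = make_aligner("local")


def _best_hit(sense: str, segments) -> SegmentHit | None:
    best: SegmentHit | None = None
    for seg in segments:   # segments arrive sorted by name: first wins ties
        alns = _LOCAL.align(sense, seg.seq)
        if alns.score <= 0:
            continue
        aln = alns[0]
        counts = aln.counts()
        denom = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / denom if denom else 0.0
        qb, tb = aln.aligned
        hit = SegmentHit(
            segment_name=seg.name,
            score=float(alns.score),
            query_start=int(qb[0][0]),
            query_end=int(qb[-1][1]),
            target_start=int(tb[0][0]),
            target_end=int(tb[-1][1]),
            identity=identity,
            blocks=tuple((tuple(map(int, q)), tuple(map(int, t))) for q, t in zip(qb, tb)),
        )
        if best is None or (hit.score, hit.identity) > (best.score, best.identity):
            best = hit
    return best


def _map_target_to_query(hit: SegmentHit, tpos: int) -> int | None:
    """Map a germline-segment coordinate onto the sense sequence, or None if
    the position falls in a gap or outside the aligned region."""
    for (qs, qe), (ts, te) in hit.blocks:
        if ts <= tpos < te:
            return qs + (tpos - ts)
    return None


def orient(consensus_nt: str, ref: GermlineReference | None = None,
           mode: str = "reverse",
           seed_min_score: float = DEFAULT_MIN_V_SCORE) -> tuple[str, bool]:
    """Return ``(sense_nt, oriented)``.

    mode="reverse" (default): reverse-complement unconditionally — the
    library chemistry guarantees antisense reads.  mode="auto": pick the
    strand whose best V-segment score is higher; if neither strand produces
    a V seed hit of at least ``seed_min_score`` the input is passed through
    with ``oriented=False``.  mode="none": pass through (already sense).
    """
    if not consensus_nt:
        raise ValueError("empty consensus")
    if mode == "reverse":
        return revcomp(consensus_nt), True
    if mode == "none":
        return consensus_nt, True
    if mode != "auto":
        raise ValueError(f"unknown orientation mode {mode!r}")
    if ref is None:
        raise ValueError("auto orientation requires a germline reference")
    vs = ref.by_kind("V")
    fwd = _best_hit(consensus_nt, vs)
    rc = revcomp(consensus_nt)
    rev = _best_hit(rc, vs)
    fwd_score = fwd.score if fwd else 0.0
    rev_score = rev.score if rev else 0.0
    if max(fwd_score, rev_score) < seed_min_score:
        return consensus_nt, False
    return (consensus_nt, True) if fwd_score >= rev_score else (rc, True)


def align_segments(sense_nt: str, ref: GermlineReference,
                   min_v_score: float = DEFAULT_MIN_V_SCORE,
                   min_j_score: float = DEFAULT_MIN_J_SCORE) -> tuple[SegmentHit, SegmentHit]:
    """Best V and best J hit on the sense sequence.

    The J hit must lie 3' of the V hit: its aligned region must end past the
    V anchor codon mapped onto the consensus (local V alignments can drift a
    few bases into the junction on short CDR3s, so the anchor — not the raw
    V alignment end — defines "past the V").  Raises :class:`Discard` with
    ``no_v_hit`` / ``no_j_hit`` / ``anchor_outside_alignment``.
    """
    v_hit = _best_hit(sense_nt, ref.by_kind("V"))
    if v_hit is None or v_hit.score < min_v_score:
        raise Discard("no_v_hit")
    v_anchor_q = _map_target_to_query(v_hit, ref[v_hit.segment_name].anchor_nt)
    if v_anchor_q is None:
        raise Discard("anchor_outside_alignment")
    j_best: SegmentHit | None = None
    for seg in ref.by_kind("J"):
        hit = _best_hit(sense_nt, [seg])
        if hit is None or hit.score < min_j_score:
            continue
        if hit.query_end <= v_anchor_q + 3:
            continue
        if j_best is None or (hit.score, hit.identity) > (j_best.score, j_best.identity):
            j_best = hit
    if j_best is None:
        raise Discard("no_j_hit")
    return v_hit, j_best


def extract_cdr3(sense_nt: str, v_hit: SegmentHit, j_hit: SegmentHit,
                 ref: GermlineReference, anchor_convention: str = "inclusive") -> str:
    """CDR3 from the V Cys codon through the J Phe codon (inclusive).

    Both anchor codons are mapped onto the sense sequence through the
    alignments; if either codon is not covered the record is discarded with
    ``anchor_outside_alignment``.  ``anchor_convention="exclusive"`` strips
    the two anchor codons instead.
    """
    if anchor_convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown anchor convention {anchor_convention!r}")
    v_anchor = ref[v_hit.segment_name].anchor_nt
    j_anchor = ref[j_hit.segment_name].anchor_nt
    q_start = _map_target_to_query(v_hit, v_anchor)
    q_start_end = _map_target_to_query(v_hit, v_anchor + 2)
    q_end_first = _map_target_to_query(j_hit, j_anchor)
    q_end = _map_target_to_query(j_hit, j_anchor + 2)
    if None in (q_start, q_start_end, q_end_first, q_end):
        raise Discard("anchor_outside_alignment")
    if anchor_convention == "exclusive":
        return sense_nt[q_start_end + 1 : q_end_first]
    return sense_nt[q_start : q_end + 1]


def translate_and_filter(cdr3_nt: str) -> str:
    """Translate an in-frame, stop-free, unambiguous CDR3; else Discard with
    reason ``ambiguous_base`` / ``frame_shift`` / ``stop_codon``."""
    if "N" in cdr3_nt:
        raise Discard("ambiguous_base")
    if len(cdr3_nt) == 0 or len(cdr3_nt) % 3 != 0:
        raise Discard("frame_shift")
    aa = str(Seq(cdr3_nt).translate())
    if "*" in aa:
        raise Discard("stop_codon")
    return aa


def annotate_one(consensus_nt: str, ref: GermlineReference,
                 orient_mode: str = "reverse",
                 anchor_convention: str = "inclusive",
                 min_v_score: float = DEFAULT_MIN_V_SCORE,
                 min_j_score: float = DEFAULT_MIN_J_SCORE) -> tuple[str, str, str, str]:
    """(v_name, j_name, cdr3_nt, cdr3_aa) for one consensus, or Discard."""
    sense, oriented = orient(consensus_nt, ref, orient_mode)
    if not oriented:
        raise Discard("unoriented")
    v_hit, j_hit = align_segments(sense, ref, min_v_score, min_j_score)
    cdr3_nt = extract_cdr3(sense, v_hit, j_hit, ref, anchor_convention)
    cdr3_aa = translate_and_filter(cdr3_nt)
    return v_hit.segment_name, j_hit.segment_name, cdr3_nt, cdr3_aa


def annotate_records(records: list[ConsensusRecord], ref: GermlineReference,
                     orient_mode: str = "reverse",
                     anchor_convention: str = "inclusive",
                     min_v_score: float = DEFAULT_MIN_V_SCORE,
                     min_j_score: float = DEFAULT_MIN_J_SCORE,
                     ) -> tuple[list[MoleculeAnnotation], Counter]:
    """Annotate every consensus record; returns annotations + discard tally.

    Identical consensus sequences share one alignment (the result depends
    only on the sequence), so annotation is independent of record order.
    """
    cache: dict[str, tuple[str, str, str, str] | str] = {}
    annotations: list[MoleculeAnnotation] = []
    discards: Counter = Counter()
    for rec in records:
        res = cache.get(rec.consensus_nt)
        if res is None:
            try:
                res = annotate_one(rec.consensus_nt, ref, orient_mode,
                                   anchor_convention, min_v_score, min_j_score)
            except Discard as d:
                res = d.reason
            cache[rec.consensus_nt] = res
        if isinstance(res, str):
            discards[res] += 1
        else:
            annotations.append(MoleculeAnnotation(rec.tag, *res))
    return annotations, discards


def aggregate_clonotypes(annotations: list[MoleculeAnnotation],
                         sample_id: str = "sample") -> pd.DataFrame:
    """Group annotated molecules into nucleotide-level clonotypes.

    One row per (v_name, j_name, cdr3_nt); ``n_molecules`` sums to the number
    of annotated molecules.
    """
    if not annotations:
        return pd.DataFrame(columns=["sample_id", "v_name", "j_name",
                                     "cdr3_nt", "cdr3_aa", "n_molecules"])
    df = pd.DataFrame(
        [(a.v_name, a.j_name, a.cdr3_nt, a.cdr3_aa) for a in annotations],
        columns=["v_name", "j_name", "cdr3_nt", "cdr3_aa"],
    )
    out = (df.groupby(["v_name", "j_name", "cdr3_nt", "cdr3_aa"], sort=True)
             .size().reset_index(name="n_molecules"))
    out.insert(0, "sample_id", sample_id)
    return out


def aggregate_aa(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Amino-acid-level clonotypes: nt clonotypes pooled on cdr3_aa alone
    (convergent recombination), ignoring V/J identity."""
    if clonotypes.empty:
        return pd.DataFrame(columns=["sample_id", "cdr3_aa", "n_molecules"])
    return (clonotypes.groupby(["sample_id", "cdr3_aa"], sort=True)["n_molecules"]
            .sum().reset_index())
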