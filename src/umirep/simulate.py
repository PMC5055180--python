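"""Ground-truthed read simulator for barcoded TCR beta repertoire sequencing.

Emulates the library chemistry of the assay: each cDNA molecule is primed in
the C region by an RT primer carrying a 5-bp sample index, a 12-bp random
molecular barcode and a 15-bp spacer, so every sequencing read is laid out

    sample_index(5) + barcode(12) + spacer(15) + C-primer(22) + antisense TCRB

where the antisense part runs from the C-region primer site back through the
J segment, the CDR3 junction and into the V segment, truncated at the read
length.  PCR resampling is modelled as a per-molecule read-count draw and
sequencing noise as independent per-base substitution/insertion/deletion
events (indel-dominant by default, as on semiconductor sequencers), injected
everywhere including inside the barcode.

Everything is deterministic given ``SimConfig.seed``; the seed feeds named
substreams (repertoire, barcodes, sampling, errors) so that, e.g., changing
error rates does not perturb which clones are sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .reference import GermlineReference, GeneSegment

__all__ = [
    "SPACER",
    "C_PRIMER",
    "DEFAULT_SAMPLE_INDEX",
    "Clone",
    "Molecule",
    "SimConfig",
    "SimulationError",
    "simulate_repertoire",
    "recombine",
    "simulate_reads",
    "generate_run",
    "write_run",
]

SPACER = "GTACATATTGTCGTT"
C_PRIMER = "CTCTGCTTCTGATGGCTCAAAC"
DEFAULT_SAMPLE_INDEX = "AAGCT"

_RC = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Clone:
    """One ground-truth clonotype of the simulated repertoire."""

    clone_id: int
    v_name: str
    j_name: str
    junction_nt: str   # bases strictly between the two anchor codons
    cdr3_nt: str       # Cys codon through Phe codon, inclusive
    frequency: float


@dataclass(frozen=True)
class Molecule:
    """One barcoded cDNA molecule drawn from the clone distribution."""

    molecule_id: int
    clone_id: int
    barcode: str
    sample_index: str
    full_sense_nt: str
    n_reads: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sequencing run."""

    n_clones: int = 1000
    abundance_model: str = "uniform"      # "uniform" or "power_law"
    alpha: float = 1.0                    # power-law exponent (frequency ~ rank^-alpha)
    n_molecules: int = 10_000
    reads_per_molecule_mean: float = 10.0
    reads_per_molecule_dispersion: float = 20.0   # NB size parameter; larger = closer to Poisson
    sub_rate: float = 0.001
    ins_rate: float = 0.004
    del_rate: float = 0.004
    read_length: int = 250                # total read length incl. index/barcode/spacer
    sample_index: str = DEFAULT_SAMPLE_INDEX
    unique_barcodes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, attr)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{attr} must lie in [0, 1)")
        if self.abundance_model not in ("uniform", "power_law"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if len(self.sample_index) != 5:
            raise ValueError("sample_index must be 5 nt")
        if self.reads_per_molecule_mean < 1:
            raise ValueError("reads_per_molecule_mean must be >= 1")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("repertoire", "barcodes", "sampling", "errors")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def clone_frequencies(cfg: SimConfig) -> np.ndarray:
    if cfg.abundance_model == "uniform":
        return np.full(cfg.n_clones, 1.0 / cfg.n_clones)
    ranks = np.arange(1, cfg.n_clones + 1, dtype=float)
    w = ranks ** (-cfg.alpha)
    return w / w.sum()


def recombine(v: GeneSegment, j: GeneSegment, rng: np.random.Generator,
              max_trim: int = 6, max_insert: int = 15) -> tuple[str, str]:
    """Simulate one V(D)J junction between a V and a J segment.

    Trims 0-6 nt from the V 3' end after the Cys codon and 0-6 nt from the
    J 5' end before the Phe-codon region, then inserts random non-templated
    bases (0-15 nt; D-segment contribution is absorbed into the insert).
    The insert length is adjusted so the CDR3 is in frame, and junctions
    producing an in-frame stop are redrawn, so the rearrangement is
    productive by construction.  Returns ``(junction_nt, cdr3_nt)``.
    """
    if v.kind != "V" or j.kind != "J":
        raise ValueError("recombine expects a V and a J segment")
    v_tail_len = len(v.seq) - (v.anchor_nt + 3)   # trimmable bases after the Cys codon
    j_head_len = j.anchor_nt                      # trimmable bases before the Phe codon
    while True:
        t_v = int(rng.integers(0, min(max_trim, v_tail_len) + 1))
        t_j = int(rng.integers(0, min(max_trim, j_head_len) + 1))
        v_part = v.seq[v.anchor_nt : len(v.seq) - t_v]
        j_part = j.seq[t_j : j.anchor_nt + 3]
        base_len = len(v_part) + len(j_part)
        n_ins = int(rng.integers(0, max_insert + 1))
        n_ins -= (base_len + n_ins) % 3
        if n_ins < 0:
            n_ins += 3
        insert = _rand_nt(rng, n_ins)
        cdr3 = v_part + insert + j_part
        if "*" in str(Seq(cdr3).translate()):
            continue
        junction = v.seq[v.anchor_nt + 3 : len(v.seq) - t_v] + insert + j.seq[t_j : j.anchor_nt]
        return junction, cdr3


def simulate_repertoire(cfg: SimConfig, ref: GermlineReference,
                        max_retries_per_clone: int = 200) -> list[Clone]:
    """Draw ``cfg.n_clones`` clones with distinct CDR3 nt sequences."""
    rng = _substreams(cfg.seed)["repertoire"]
    vs, js = ref.by_kind("V"), ref.by_kind("J")
    freqs = clone_frequencies(cfg)
    clones: list[Clone] = []
    seen: set[str] = set()
    budget = cfg.n_clones * max_retries_per_clone
    while len(clones) < cfg.n_clones:
        if budget <= 0:
            raise SimulationError(
                f"could not generate {cfg.n_clones} distinct junctions within retry budget"
            )
        budget -= 1
        v = vs[rng.integers(0, len(vs))]
        j = js[rng.integers(0, len(js))]
        junction, cdr3 = recombine(v, j, rng)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        clones.append(Clone(len(clones), v.name, j.name, junction, cdr3,
                            float(freqs[len(clones)])))
    return clones


def clone_sense_sequence(clone: Clone, ref: GermlineReference) -> str:
    """mRNA-sense sequence of the assayed region: V ... CDR3 ... J ... C-primer site."""
    v, j = ref[clone.v_name], ref[clone.j_name]
    c = ref.by_kind("C")[0]
    site = revcomp(C_PRIMER)
    pos = c.seq.find(site)
    if pos < 0:
        raise SimulationError(f"C segment {c.name} does not contain the C-primer site")
    return v.seq[: v.anchor_nt] + clone.cdr3_nt + j.seq[j.anchor_nt + 3 :] + c.seq[: pos + len(site)]


def _inject_errors(arr: np.ndarray, rng: np.random.Generator,
                   sub: float, ins: float, dele: float,
                   counts: list[int] | None = None) -> np.ndarray:
    """Apply independent per-base substitution/insertion/deletion errors.

    ``arr`` is a uint8 array of base codes 0..3; insertions are placed before
    the base they were drawn at.  Optionally accumulates [n_sub, n_ins, n_del]
    into ``counts``.
    """
    n = arr.size
    out = arr
    sub_mask = rng.random(n) < sub
    if sub_mask.any():
        out = out.copy()
        k = int(sub_mask.sum())
        out[sub_mask] = (out[sub_mask] + rng.integers(1, 4, k).astype(np.uint8)) % 4
    keep = rng.random(n) >= dele
    ins_mask = rng.random(n) < ins
    n_ins = int(ins_mask.sum())
    if counts is not None:
        counts[0] += int(sub_mask.sum())
        counts[1] += n_ins
        counts[2] += n - int(keep.sum())
    if n_ins == 0 and keep.all():
        return out
    cnt = ins_mask.astype(np.int64) + keep
    starts = np.concatenate(([0], np.cumsum(cnt)[:-1]))
    res = np.empty(int(cnt.sum()), dtype=np.uint8)
    if n_ins:
        res[starts[ins_mask]] = rng.integers(0, 4, n_ins).astype(np.uint8)
    res[(starts + ins_mask)[keep]] = out[keep]
    return res


def _draw_read_counts(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Reads per molecule: 1 + negative binomial with mean (mean-1)."""
    extra_mean = cfg.reads_per_molecule_mean - 1.0
    if extra_mean <= 0:
        return np.ones(n, dtype=np.int64)
    size = cfg.reads_per_molecule_dispersion
    p = size / (size + extra_mean)
    return 1 + rng.negative_binomial(size, p, n)


def simulate_reads(clones: list[Clone], cfg: SimConfig, ref: GermlineReference
                   ) -> tuple[list[tuple[str, str]], list[Molecule]]:
    """Generate reads and the molecule truth table for one run.

    Returns ``(reads, molecules)`` where reads are ``(read_id, sequence)``
    pairs (read ids are ``m<molecule_id>_r<k>``) and molecules carry their
    true clone identity, barcode and read count.
    """
    if not clones:
        raise SimulationError("empty clone list")
    streams = _substreams(cfg.seed)
    if cfg.n_molecules == 0:
        warnings.warn("n_molecules=0: empty run", stacklevel=2)
        return [], []
    freqs = np.array([c.frequency for c in clones])
    freqs = freqs / freqs.sum()
    clone_ids = streams["sampling"].choice(len(clones), size=cfg.n_molecules, p=freqs)
    n_reads = _draw_read_counts(cfg, streams["sampling"], cfg.n_molecules)

    bc_rng = streams["barcodes"]
    if cfg.unique_barcodes:
        barcodes: list[str] = []
        seen: set[str] = set()
        while len(barcodes) < cfg.n_molecules:
            b = _rand_nt(bc_rng, 12)
            if b not in seen:
                seen.add(b)
                barcodes.append(b)
    else:
        barcodes = [_rand_nt(bc_rng, 12) for _ in range(cfg.n_molecules)]

    err_rng = streams["errors"]
    no_errors = cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0
    sense_cache: dict[int, str] = {}
    reads: list[tuple[str, str]] = []
    molecules: list[Molecule] = []
    for mol_id in range(cfg.n_molecules):
        cid = int(clone_ids[mol_id])
        sense = sense_cache.get(cid)
        if sense is None:
            sense = clone_sense_sequence(clones[cid], ref)
            sense_cache[cid] = sense
        payload_budget = cfg.read_length - 5 - 12 - len(SPACER)
        template = (cfg.sample_index + barcodes[mol_id] + SPACER
                    + revcomp(sense)[: max(payload_budget, 0)])
        molecules.append(Molecule(mol_id, cid, barcodes[mol_id], cfg.sample_index,
                                  sense, int(n_reads[mol_id])))
        if no_errors:
            for k in range(int(n_reads[mol_id])):
                reads.append((f"m{mol_id}_r{k}", template))
        else:
            tmpl_codes = _CODE[np.frombuffer(template.encode(), dtype=np.uint8)]
            for k in range(int(n_reads[mol_id])):
                noisy = _inject_errors(tmpl_codes, err_rng,
                                       cfg.sub_rate, cfg.ins_rate, cfg.del_rate)
                reads.append((f"m{mol_id}_r{k}", _BASES[noisy].tobytes().decode()))
    return reads, molecules


def generate_run(clones: list[Clone], cfg: SimConfig, ref: GermlineReference,
                 fastq_path: str | Path, truth_path: str | Path) -> tuple[int, int]:
    """Simulate a run and write FASTQ + truth-table TSV; returns (n_molecules, n_reads)."""
    reads, molecules = simulate_reads(clones, cfg, ref)
    write_run(reads, molecules, clones, fastq_path, truth_path)
    return len(molecules), len(reads)


def write_run(reads: list[tuple[str, str]], molecules: list[Molecule],
              clones: list[Clone], fastq_path: str | Path, truth_path: str | Path) -> None:
    by_id = {c.clone_id: c for c in clones}
    with open(fastq_path, "w") as fq:
        for rid, seq in reads:
            fq.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(truth_path, "w") as tsv:
        tsv.write("molecule_id\tclone_id\tbarcode\tv_name\tj_name\tcdr3_nt\tn_reads\n")
        for m in molecules:
            c = by_id[m.clone_id]
            tsv.write(f"{m.molecule_id}\t{m.clone_id}\t{m.barcode}\t"
                      f"{c.v_name}\t{c.j_name}\t{c.cdr3_nt}\t{m.n_reads}\n")
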