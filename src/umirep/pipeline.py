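"""End-to-end orchestration: simulate -> demux -> consensus -> annotate -> stats.

Each stage reads the previous stage's text outputs from the run directory,
so any stage can be re-run standalone; a run manifest records every
threshold applied and the record counts entering and leaving each stage.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .reference import GermlineReference, bundled_reference, load_reference
from .simulate import SimConfig, generate_run, simulate_repertoire
from .demux import (DEFAULT_ERROR_FREE_CUT, DEFAULT_MIN_LEN, apply_threshold,
                    demultiplex, group_by_tag, merge_length_variants,
                    tag_error_profile, TagGroup)
from .consensus import DEFAULT_MAJORITY, DEFAULT_READ_CAP, ConsensusRecord, build_consensus
from .annotate import aggregate_aa, aggregate_clonotypes, annotate_records
from .stats import (DEFAULT_RARE_CUTOFF, ace, default_rarefaction_grid,
                    frequency_classes, rarefaction, spectrum,
                    subsample_clonotypes, vj_usage)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline",
           "stage_simulate", "stage_demux", "stage_consensus", "stage_annotate",
           "stage_stats"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the CLI flags one-to-one."""

    out_dir: str = "run"
    sample_id: str = "sample"
    germline: str = "bundled"          # "bundled" or a FASTA path (+ .anchors.tsv sidecar)
    seed: int = 0
    # simulation
    n_clones: int = 1000
    abundance_model: str = "uniform"
    alpha: float = 1.0
    n_molecules: int = 10_000
    reads_per_molecule_mean: float = 10.0
    reads_per_molecule_dispersion: float = 20.0
    sub_rate: float = 0.001
    ins_rate: float = 0.004
    del_rate: float = 0.004
    read_length: int = 250
    sample_index: str = "AAGCT"
    unique_barcodes: bool = False
    # thresholds
    min_read_len: int = DEFAULT_MIN_LEN
    majority: float = DEFAULT_MAJORITY
    read_cap: int = DEFAULT_READ_CAP
    error_free_cut: float = DEFAULT_ERROR_FREE_CUT
    rare_cutoff: int = DEFAULT_RARE_CUTOFF
    subsample: int = 100_000
    anchor_convention: str = "inclusive"
    min_v_score: float = 20.0
    min_j_score: float = 15.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def validate(self) -> None:
        if not self.germline:
            raise ConfigError("missing config field: germline")
        if self.germline != "bundled" and not Path(self.germline).exists():
            raise ConfigError(f"germline: reference FASTA not found: {self.germline}")
        if not (0.0 < self.majority < 1.0):
            raise ConfigError("majority: must lie in (0, 1)")
        if not (0.0 < self.error_free_cut <= 1.0):
            raise ConfigError("error_free_cut: must lie in (0, 1]")
        if self.anchor_convention not in ("inclusive", "exclusive"):
            raise ConfigError("anchor_convention: must be 'inclusive' or 'exclusive'")
        if self.min_read_len < 0 or self.read_cap < 1 or self.rare_cutoff < 1:
            raise ConfigError("min_read_len/read_cap/rare_cutoff out of range")
        # SimConfig re-validates the simulation block
        try:
            self.sim_config()
        except ValueError as e:
            raise ConfigError(str(e)) from None

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_clones=self.n_clones, abundance_model=self.abundance_model,
            alpha=self.alpha, n_molecules=self.n_molecules,
            reads_per_molecule_mean=self.reads_per_molecule_mean,
            reads_per_molecule_dispersion=self.reads_per_molecule_dispersion,
            sub_rate=self.sub_rate, ins_rate=self.ins_rate, del_rate=self.del_rate,
            read_length=self.read_length, sample_index=self.sample_index,
            unique_barcodes=self.unique_barcodes, seed=self.seed,
        )

    def load_germline(self) -> GermlineReference:
        if self.germline == "bundled":
            return bundled_reference()
        return load_reference(self.germline)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "tool_version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "thresholds": {
                "min_read_len": config.min_read_len,
                "majority": config.majority,
                "read_cap": config.read_cap,
                "error_free_cut": config.error_free_cut,
                "rare_cutoff": config.rare_cutoff,
                "subsample": config.subsample,
                "anchor_convention": config.anchor_convention,
                "min_v_score": config.min_v_score,
                "min_j_score": config.min_j_score,
            },
            "stages": {},
        }

    def record(self, stage: str, **counts) -> None:
        self.data["stages"][stage] = counts

    def fail(self, stage: str, error: str) -> None:
        self.data["failed_stage"] = stage
        self.data["error"] = error

    def write(self, out_dir: Path) -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def stage_simulate(config: PipelineConfig, out_dir: Path, manifest: Manifest) -> None:
    ref = config.load_germline()
    cfg = config.sim_config()
    clones = simulate_repertoire(cfg, ref)
    with open(out_dir / "clones.tsv", "w") as fh:
        fh.write("clone_id\tv_name\tj_name\tcdr3_nt\tfrequency\n")
        for c in clones:
            fh.write(f"{c.clone_id}\t{c.v_name}\t{c.j_name}\t{c.cdr3_nt}\t{c.frequency:.12g}\n")
    n_mol, n_reads = generate_run(clones, cfg, ref,
                                  out_dir / "reads.fastq", out_dir / "truth.tsv")
    manifest.record("simulate", n_clones=len(clones), n_molecules=n_mol, n_reads=n_reads)
    _log(f"[simulate] {len(clones)} clones, {n_mol} molecules, {n_reads} reads")


def _read_fastq(path: Path):
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].strip(), seq


def stage_demux(config: PipelineConfig, out_dir: Path, manifest: Manifest) -> None:
    fastq = out_dir / "reads.fastq"
    if not fastq.exists():
        raise StageError(f"demux: missing input {fastq}")
    by_index, tally = demultiplex(_read_fastq(fastq), [config.sample_index],
                                  min_len=config.min_read_len)
    raw = by_index[config.sample_index]
    groups = merge_length_variants(group_by_tag(raw))
    report = tag_error_profile(groups, config.error_free_cut)
    retained = apply_threshold(groups, report.r_star)
    report.to_tsv(out_dir / "tag_report.tsv")
    with open(out_dir / "tags.tsv", "w") as fh:
        fh.write("tag\tn_reads\n")
        for g in retained:
            fh.write(f"{g.tag}\t{g.n_reads}\n")
    with open(out_dir / "retained_reads.tsv", "w") as fh:
        fh.write("tag\tpayload\n")
        for g in retained:
            for p in g.reads:
                fh.write(f"{g.tag}\t{p}\n")
    summary = {"r_star": report.r_star, "molecule_count": len(retained),
               "rejections": tally,
               "n_tag_groups": len(groups)}
    with open(out_dir / "demux_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    manifest.record("demux", reads_in=sum(tally.values()), kept_reads=tally["kept"],
                    rejected_unknown_index=tally["unknown_index"],
                    rejected_no_spacer=tally["no_spacer"],
                    rejected_short=tally["short"], tag_groups=len(groups),
                    r_star=report.r_star, retained_molecules=len(retained))
    _log(f"[demux] kept {tally['kept']} reads; r*={report.r_star}; "
         f"{len(retained)} molecules")


def _read_groups(path: Path) -> list[TagGroup]:
    groups: dict[str, TagGroup] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            tag, payload = line.rstrip("\n").split("\t")
            g = groups.get(tag)
            if g is None:
                g = groups[tag] = TagGroup(tag)
            g.reads.append(payload)
    return [groups[t] for t in sorted(groups)]


def stage_consensus(config: PipelineConfig, out_dir: Path, manifest: Manifest) -> None:
    src = out_dir / "retained_reads.tsv"
    if not src.exists():
        raise StageError(f"consensus: missing input {src}")
    groups = _read_groups(src)
    with open(out_dir / "consensus.fasta", "w") as fh:
        for g in groups:
            rec = build_consensus(g, config.read_cap, config.majority)
            fh.write(f">{rec.tag}|{rec.n_reads_used}|{rec.n_ambiguous_columns}\n"
                     f"{rec.consensus_nt}\n")
    manifest.record("consensus", groups_in=len(groups), consensus_out=len(groups))
    _log(f"[consensus] {len(groups)} consensus sequences")


def _read_consensus(path: Path) -> list[ConsensusRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tag, n_used, n_amb = rec.id.split("|")
        records.append(ConsensusRecord(tag, int(n_used), str(rec.seq), int(n_amb)))
    return records


def stage_annotate(config: PipelineConfig, out_dir: Path, manifest: Manifest) -> None:
    src = out_dir / "consensus.fasta"
    if not src.exists():
        raise StageError(f"annotate: missing input {src}")
    ref = config.load_germline()
    records = _read_consensus(src)
    annotations, discards = annotate_records(
        records, ref, anchor_convention=config.anchor_convention,
        min_v_score=config.min_v_score, min_j_score=config.min_j_score)
    clonotypes = aggregate_clonotypes(annotations, config.sample_id)
    clonotypes.to_csv(out_dir / "clonotypes.tsv", sep="\t", index=False)
    with open(out_dir / "discards.tsv", "w") as fh:
        fh.write("reason\tn\n")
        for reason in sorted(discards):
            fh.write(f"{reason}\t{discards[reason]}\n")
    n_disc = sum(discards.values())
    manifest.record("annotate", consensus_in=len(records),
                    annotated_molecules=len(annotations), discarded=n_disc,
                    nt_clonotypes=len(clonotypes))
    if len(annotations) + n_disc != len(records):
        raise StageError("annotate: molecule count not conserved")
    _log(f"[annotate] {len(annotations)} molecules annotated, {n_disc} discarded, "
         f"{len(clonotypes)} nt clonotypes")


def stage_stats(config: PipelineConfig, out_dir: Path, manifest: Manifest) -> None:
    src = out_dir / "clonotypes.tsv"
    if not src.exists():
        raise StageError(f"stats: missing input {src}")
    clonotypes = pd.read_csv(src, sep="\t")
    if clonotypes.empty:
        raise StageError("stats: empty clonotype table")
    aa = aggregate_aa(clonotypes)
    report: dict = {"sample_id": config.sample_id}
    for level, df in (("nt", clonotypes), ("aa", aa)):
        spec = spectrum(df["n_molecules"].to_numpy(), k=config.rare_cutoff)
        est = ace(spec)
        report[level] = {
            "n_molecules": spec.n_molecules, "s_obs": est.s_obs,
            "s_ace": est.s_ace, "c_ace": est.c_ace, "gamma2": est.gamma2,
            "method": est.method,
        }
    n_total = int(clonotypes["n_molecules"].sum())
    spec_nt = spectrum(clonotypes["n_molecules"].to_numpy(), k=config.rare_cutoff)
    grid = default_rarefaction_grid(n_total)
    exp = rarefaction(spec_nt, grid)
    with open(out_dir / "rarefaction.tsv", "w") as fh:
        fh.write("m\texpected_richness\n")
        for m, e in zip(grid, exp):
            fh.write(f"{m}\t{e:.6f}\n")
    # abundance classes on the aa table, on a fixed-size subsample when possible
    m_sub = min(config.subsample, int(aa["n_molecules"].sum()))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    aa_sub = subsample_clonotypes(aa, m_sub, rng)
    classes = frequency_classes(aa_sub)
    classes.to_csv(out_dir / "classes.tsv", sep="\t", index=False)
    report["classes_subsample_size"] = m_sub
    for kind in ("V", "J"):
        usage = vj_usage(clonotypes, kind, "by_molecule")
        usage.rename("fraction").to_csv(out_dir / f"usage_{kind.lower()}.tsv", sep="\t")
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    manifest.record("stats", nt_clonotypes=len(clonotypes), aa_clonotypes=len(aa),
                    s_ace_nt=report["nt"]["s_ace"], s_ace_aa=report["aa"]["s_ace"])
    _log(f"[stats] s_ace(nt)={report['nt']['s_ace']:.1f} "
         f"s_ace(aa)={report['aa']['s_ace']:.1f}")


_STAGES = {
    "simulate": stage_simulate,
    "demux": stage_demux,
    "consensus": stage_consensus,
    "annotate": stage_annotate,
    "stats": stage_stats,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in order); returns the run dir.

    On a stage failure, partial outputs and a manifest noting the failure
    point are preserved, then :class:`StageError` is re-raised.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    stages = stages or list(_STAGES)
    try:
        for name in stages:
            if name not in _STAGES:
                raise ConfigError(f"unknown stage {name!r}")
            t0 = time.perf_counter()
            _STAGES[name](config, out_dir, manifest)
            _log(f"[{name}] done in {time.perf_counter() - t0:.1f}s")
    except Exception as e:
        if not isinstance(e, ConfigError):
            manifest.fail(name, str(e))
            manifest.write(out_dir)
        raise
    manifest.write(out_dir)
    return out_dir
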