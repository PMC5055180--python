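# umirep

Molecular-barcode-based TCR beta-chain (TCRB) repertoire sequencing toolkit:
a ground-truthed read simulator, UMI-tag demultiplexing with absolute
molecule counting, per-molecule consensus calling, CDR3 extraction, and
repertoire statistics.

## The problem

Bulk sequencing of TCRB CDR3 junctions is the standard way to characterize
T-cell populations — e.g. comparing tumor-infiltrating lymphocytes (TILs)
with peripheral blood lymphocytes (PBLs). Raw reads are a poor proxy for the
molecular population: indel-heavy sequencing errors inflate apparent
diversity, and PCR resampling destroys quantitation. This toolkit implements
a barcode-based protocol: each cDNA molecule carries a 12-nt random barcode
attached at reverse transcription, reads are laid out as

    index(5) + barcode(12) + spacer(15) + C-primer(22) + antisense TCRB,

and the pipeline (a) monitors barcode errors through tag length (indel
errors make 11/13-nt tags), removes reads-per-tag bins whose error-free-tag
fraction falls below 90%, and counts molecules as retained 12-nt tags;
(b) builds one consensus per molecule (center-star alignment of up to the 50
longest reads, strict >80% per-column majority); (c) re-orients to sense,
finds the best V and J germline segments by local alignment, extracts the
CDR3 from the conserved V-cysteine codon through the J-phenylalanine codon,
and discards frame-shifted or stop-containing junctions.

Because molecules are counted absolutely, the clonotype table supports
species-richness statistics: the abundance-based coverage estimator

    S_ACE = S_abund + S_rare/C + (F1/C)·γ²,    C = 1 − F1/N_rare,

with clonotypes observed 1–10 times as the rare group, closed-form
rarefaction curves, abundance classes (low <0.01%, middle 0.01–0.1%,
high ≥0.1% of molecules), V/J segment usage, and cross-sample sharing
tables. A bundled synthetic germline mini-reference (8 V, 6 J, 1 C segments
with annotated anchor codons) makes everything runnable offline; a real
reference in the same FASTA + anchor-table format is a drop-in replacement.

See `docs/methods.md` for the full model, parameter and design notes.

## Worked example

```bash
umirep all --out-dir run --seed 7
```

runs simulate → demux → consensus → annotate → stats at the default study
conditions (1,000 clones, 10,000 molecules, mean 10 reads/molecule,
indel-dominant errors at 0.4%+0.4%+0.1% per base) and logs:

```
[simulate] 1000 clones, 10000 molecules, 100055 reads
[demux] kept 95244 reads; r*=3; 9871 molecules
[consensus] 9871 consensus sequences
[annotate] 8574 molecules annotated, 1297 discarded, 1000 nt clonotypes
[stats] s_ace(nt)=1000.3 s_ace(aa)=947.3
```

Reading: of 100,055 raw reads, 95,244 parse and pass the 150-nt length
filter; the tag-length error monitor picks a read-count threshold r\*=3 and
counts 9,871 molecules (true value 10,000, −1.3%). Consensus + annotation
yield 8,574 productive CDR3 molecules (most discards are molecules whose
low-read consensus carries an ambiguous base inside the CDR3), and the ACE
estimate of nucleotide-clonotype richness is 1,000.3 against a true
repertoire of 1,000. Per-stage tables (`clonotypes.tsv`, `tag_report.tsv`,
`rarefaction.tsv`, `classes.tsv`, usage tables) and a `manifest.json` with
every threshold and record count are written to `run/`.

The same stages are available as a library:

```python
from umirep import bundled_reference, SimConfig, simulate_repertoire
from umirep.stats import spectrum, ace

ref = bundled_reference()
clones = simulate_repertoire(SimConfig(n_clones=500, seed=1), ref)
est = ace(spectrum([1, 1, 1, 2, 2, 5, 20]))
print(round(est.s_ace, 3))   # 10.818
```

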