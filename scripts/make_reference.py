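"""One-off generator for the bundled synthetic germline mini-reference.

Run from repo root: python scripts/make_reference.py
Writes src/umirep/data/germline.fasta + germline.anchors.tsv
"""
import numpy as np

BASES = np.array(list("ACGT"))
C_PRIMER = "CTCTGCTTCTGATGGCTCAAAC"
RC = str.maketrans("ACGT", "TGCA")

STOPS = {"TAA", "TAG", "TGA"}

def rand_nt(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])

def rand_codon_no_stop(rng):
    while True:
        c = rand_nt(rng, 3)
        if c not in STOPS:
            return c

rng = np.random.default_rng(874512)

records = []   # (name, kind, seq, anchor)

# 8 V segments: 280 nt, Cys anchor codon at 271 (9 nt from the 3' end)
for i in range(8):
    body = rand_nt(rng, 271)
    cys = "TGT" if i % 2 == 0 else "TGC"
    # 6 nt after the anchor codon: the trimmable V tail; avoid an in-frame stop
    tail = rand_codon_no_stop(rng) + rand_codon_no_stop(rng)
    seq = body + cys + tail
    assert len(seq) == 280
    records.append((f"V{i+1:02d}", "V", seq, 271))

# 6 J segments: 50 nt, Phe anchor at 9, followed by the F-G-X-G motif
for i in range(6):
    head = "".join(rand_codon_no_stop(rng) for _ in range(3))  # 9 nt trimmable head
    phe = "TTT" if i % 2 == 0 else "TTC"
    g1 = "GG" + "ACGT"[rng.integers(0, 4)]
    x = rand_codon_no_stop(rng)
    g2 = "GG" + "ACGT"[rng.integers(0, 4)]
    rest = rand_nt(rng, 50 - 21)
    seq = head + phe + g1 + x + g2 + rest
    assert len(seq) == 50
    records.append((f"J{i+1:02d}", "J", seq, 9))

# 1 C segment: 6 nt head + reverse complement of the C-region RT primer + filler
site = C_PRIMER.translate(RC)[::-1]
cseq = rand_nt(rng, 6) + site + rand_nt(rng, 40)
assert len(cseq) == 68 and site in cseq
records.append(("C01", "C", cseq, ""))

with open("src/umirep/data/germline.fasta", "w") as fa, \
     open("src/umirep/data/germline.anchors.tsv", "w") as tsv:
    tsv.write("name\tkind\tanchor_nt\n")
    for name, kind, seq, anchor in records:
        fa.write(f">{name}\n{seq}\n")
        tsv.write(f"{name}\t{kind}\t{anchor}\n")
print("wrote", len(records), "segments")
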