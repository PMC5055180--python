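"""Independent reference implementations used as test oracles.

These are deliberately written from the defining formulas (or by brute
force) and share no code with the package.
"""

import itertools


def ace_oracle(counts, k=10):
    """Chao-Lee abundance-based coverage estimator, straight from the formula."""
    counts = list(counts)
    rare = [c for c in counts if c <= k]
    abund = [c for c in counts if c > k]
    if not rare:
        return float(len(abund))
    f1 = sum(1 for c in rare if c == 1)
    n_rare = sum(rare)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return len(counts) + f1 * (f1 - 1) / 2.0  # Chao1 fallback
    fis = {}
    for c in rare:
        fis[c] = fis.get(c, 0) + 1
    num = sum(i * (i - 1) * fi for i, fi in fis.items())
    gamma2 = max((len(rare) / c_ace) * num / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return len(abund) + len(rare) / c_ace + (f1 / c_ace) * gamma2


def rarefaction_oracle(counts, m):
    """Expected distinct clonotypes in an m-subset, by exhaustive enumeration."""
    pool = [i for i, c in enumerate(counts) for _ in range(c)]
    total = 0
    n_sub = 0
    for sub in itertools.combinations(range(len(pool)), m):
        total += len({pool[i] for i in sub})
        n_sub += 1
    return total / n_sub
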