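"""Repertoire statistics: richness estimation, rarefaction, abundance
classes, V/J usage and cross-sample sharing.

Because molecules are counted absolutely (one retained barcode tag = one
cDNA molecule), the clonotype table is a genuine abundance sample and
classical species-richness machinery applies.  Richness is estimated with
the abundance-based coverage estimator (ACE, Chao & Lee), treating
clonotypes seen 1-10 times as the rare group:

    S_ACE = S_abund + S_rare / C_ACE + (F1 / C_ACE) * gamma^2

with sample coverage ``C_ACE = 1 - F1 / N_rare`` and a squared coefficient
of variation correction ``gamma^2``.  Rarefaction uses the closed-form
expectation of distinct clonotypes in a without-replacement subsample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AbundanceSpectrum",
    "RichnessEstimate",
    "spectrum",
    "ace",
    "rarefaction",
    "default_rarefaction_grid",
    "subsample",
    "subsample_clonotypes",
    "abundance_class",
    "frequency_classes",
    "vj_usage",
    "sharing",
    "CLASS_ORDER",
]

DEFAULT_RARE_CUTOFF = 10
CLASS_ORDER = ("low", "middle", "high")
_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}
LOW_BOUND = 1e-4      # frequencies below this are "low"  (<0.01%)
HIGH_BOUND = 1e-3     # frequencies at or above this are "high" (>=0.1%)


@dataclass(frozen=True)
class AbundanceSpectrum:
    """Frequency-of-frequencies: f[i] = number of clonotypes seen i times."""

    f: dict[int, int]
    k: int = DEFAULT_RARE_CUTOFF

    def __post_init__(self) -> None:
        for i, fi in self.f.items():
            if i < 1 or fi < 0:
                raise ValueError("abundances must be >= 1 with non-negative counts")

    @property
    def n_molecules(self) -> int:
        return sum(i * fi for i, fi in self.f.items())

    @property
    def s_obs(self) -> int:
        return sum(self.f.values())

    def counts(self) -> np.ndarray:
        """Expand back to one abundance per clonotype (sorted)."""
        return np.array(sorted(i for i, fi in self.f.items() for _ in range(fi)))


def spectrum(counts, k: int = DEFAULT_RARE_CUTOFF) -> AbundanceSpectrum:
    """Build the abundance spectrum from per-clonotype molecule counts."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty clonotype table")
    if (counts < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    vals, reps = np.unique(counts, return_counts=True)
    return AbundanceSpectrum({int(v): int(r) for v, r in zip(vals, reps)}, k=k)


@dataclass(frozen=True)
class RichnessEstimate:
    s_ace: float
    s_obs: int
    s_rare: int
    s_abund: int
    c_ace: float
    gamma2: float
    f1: int
    n_rare: int
    method: str = "ace"


def ace(spec: AbundanceSpectrum) -> RichnessEstimate:
    """Abundance-based coverage estimate of total clonotype richness.

    Clonotypes with abundance <= k (default 10) form the rare group.  If the
    rare group is empty the estimate is just the observed richness; if every
    rare clonotype is a singleton the coverage is zero and the estimator
    falls back to Chao1 with a warning.
    """
    k = spec.k
    f = spec.f
    s_obs = spec.s_obs
    s_rare = sum(fi for i, fi in f.items() if i <= k)
    s_abund = s_obs - s_rare
    f1 = f.get(1, 0)
    n_rare = sum(i * fi for i, fi in f.items() if i <= k)
    if s_rare == 0:
        return RichnessEstimate(float(s_abund), s_obs, 0, s_abund, 1.0, 0.0, 0, 0,
                                method="abundant_only")
    if n_rare <= 1:
        raise ValueError("rare group holds <= 1 molecule; ACE undefined")
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn("all rare clonotypes are singletons (coverage 0); "
                      "falling back to Chao1", stacklevel=2)
        chao1 = s_obs + f1 * (f1 - 1) / 2.0
        return RichnessEstimate(chao1, s_obs, s_rare, s_abund, 0.0, float("nan"),
                                f1, n_rare, method="chao1")
    sum_i_im1 = sum(i * (i - 1) * fi for i, fi in f.items() if i <= k)
    gamma2 = max((s_rare / c_ace) * sum_i_im1 / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    s_ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return RichnessEstimate(s_ace, s_obs, s_rare, s_abund, c_ace, gamma2,
                            f1, n_rare, method="ace")


def rarefaction(spec: AbundanceSpectrum | np.ndarray, m_grid) -> np.ndarray:
    """Expected number of distinct clonotypes in without-replacement
    subsamples of the sizes in ``m_grid``.

    E[S_m] = sum_j [1 - C(N - N_j, m) / C(N, m)], evaluated with
    log-binomial coefficients for numerical stability.
    """
    counts = spec.counts() if isinstance(spec, AbundanceSpectrum) else np.asarray(spec)
    n = int(counts.sum())
    m_grid = np.atleast_1d(np.asarray(m_grid, dtype=np.int64))
    if (m_grid < 0).any() or (m_grid > n).any():
        raise ValueError(f"subsample sizes must lie in [0, {n}]")

    def log_binom(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    vals, reps = np.unique(counts, return_counts=True)
    out = np.empty(m_grid.shape, dtype=float)
    for idx, m in enumerate(m_grid):
        ok = (n - vals) >= m
        miss = np.zeros(vals.shape, dtype=float)
        miss[ok] = np.exp(log_binom(n - vals[ok], m) - log_binom(n, m))
        out[idx] = float(np.sum(reps * (1.0 - miss)))
    return out


def default_rarefaction_grid(n: int, n_points: int = 20) -> np.ndarray:
    """Log-spaced grid of unique subsample sizes from 1 to N."""
    grid = np.unique(np.round(np.logspace(0, np.log10(n), n_points)).astype(np.int64))
    return np.clip(grid, 1, n)


def subsample(counts, m: int, seed_or_rng) -> np.ndarray:
    """Multivariate hypergeometric draw of ``m`` molecules without
    replacement; deterministic given the seed."""
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if m > n:
        raise ValueError(f"cannot draw {m} molecules from {n}")
    if m == n:
        return counts.copy()
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.multivariate_hypergeometric(counts, m)


def subsample_clonotypes(clonotypes: pd.DataFrame, m: int, seed_or_rng) -> pd.DataFrame:
    """Fixed-size subsample of a clonotype table; rows drawn to zero vanish."""
    new = subsample(clonotypes["n_molecules"].to_numpy(), m, seed_or_rng)
    out = clonotypes.copy()
    out["n_molecules"] = new
    return out[out["n_molecules"] > 0].reset_index(drop=True)


def abundance_class(n_molecules: int, n_total: int) -> str:
    """low (<0.01%), middle (0.01-0.1%), high (>=0.1%) by molecule frequency."""
    freq = n_molecules / n_total
    if freq < LOW_BOUND:
        return "low"
    if freq < HIGH_BOUND:
        return "middle"
    return "high"


def frequency_classes(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Clonotype counts and unique-clonotype fractions per abundance class."""
    n_total = int(clonotypes["n_molecules"].sum())
    if n_total == 0:
        raise ValueError("empty clonotype table")
    cls = clonotypes["n_molecules"].map(lambda n: abundance_class(int(n), n_total))
    counts = cls.value_counts()
    rows = []
    s = len(clonotypes)
    for c in CLASS_ORDER:
        k = int(counts.get(c, 0))
        rows.append({"abundance_class": c, "n_clonotypes": k, "fraction": k / s})
    return pd.DataFrame(rows)


def vj_usage(clonotypes: pd.DataFrame, kind: str = "V",
             weighting: str = "by_molecule") -> pd.Series:
    """Per-segment usage fractions (sum to 1) for V or J segments.

    ``by_molecule`` weights each segment by molecule count; ``by_clonotype``
    counts each clonotype once.
    """
    col = {"V": "v_name", "J": "j_name"}[kind]
    if weighting == "by_molecule":
        counts = clonotypes.groupby(col)["n_molecules"].sum()
    elif weighting == "by_clonotype":
        counts = clonotypes.groupby(col).size()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (counts / counts.sum()).sort_index()


def _sample_keys(df: pd.DataFrame, level: str) -> pd.Series:
    if level == "aa":
        return df.groupby("cdr3_aa")["n_molecules"].sum()
    if level == "nt":
        return df.groupby(["v_name", "j_name", "cdr3_nt"])["n_molecules"].sum()
    raise ValueError(f"unknown sharing level {level!r}")


def sharing(samples: dict[str, pd.DataFrame], level: str = "aa") -> pd.DataFrame:
    """Cross-sample sharing table with per-abundance-class rows.

    For every clonotype present in exactly m >= 2 samples, its abundance
    class is computed in each sample where it occurs (relative to that
    sample's total molecule count).  Under the "all" category rule the
    clonotype is assigned to the minimum class across those samples; under
    "any" it is assigned to the highest class it attains in any sample.
    Returns a table indexed by (category, abundance_class) with one column
    per m; row sums over classes within a category equal the number of
    clonotypes shared by exactly m samples.
    """
    if len(samples) < 2:
        raise ValueError("sharing requires at least two samples")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    per_sample = {}
    totals = {}
    for sid, df in samples.items():
        counts = _sample_keys(df, level)
        per_sample[sid] = counts
        totals[sid] = int(df["n_molecules"].sum())

    membership: dict = {}
    for sid, counts in per_sample.items():
        for key, n in counts.items():
            membership.setdefault(key, []).append((sid, int(n)))

    ms = range(2, len(samples) + 1)
    table = {("all", c): {m: 0 for m in ms} for c in CLASS_ORDER}
    table.update({("any", c): {m: 0 for m in ms} for c in CLASS_ORDER})
    for key, occ in membership.items():
        m = len(occ)
        if m < 2:
            continue
        classes = [abundance_class(n, totals[sid]) for sid, n in occ]
        ranks = [_CLASS_RANK[c] for c in classes]
        table[("all", CLASS_ORDER[min(ranks)])][m] += 1
        table[("any", CLASS_ORDER[max(ranks)])][m] += 1

    idx = pd.MultiIndex.from_tuples(table.keys(), names=["category", "abundance_class"])
    out = pd.DataFrame([[table[key][m] for m in ms] for key in table],
                       index=idx, columns=[f"shared_by_{m}" for m in ms])
    return out
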