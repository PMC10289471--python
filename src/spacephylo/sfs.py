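"""Unfolded site-frequency spectrum diagnostics and the ABBA-BABA D.

Ancestral states are known by construction in simulated data (allele 0 is
ancestral), so the unfolded SFS is exact. Under the standard neutral
coalescent E[xi_i] = theta / i; spatial structure shifts mass toward
intermediate frequencies because sampled haplotypes split into local
clans whose shared variants segregate at intermediate counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genealogy import VariantTable

__all__ = [
    "SFSVector",
    "compute_sfs",
    "neutral_expectation",
    "intermediate_skew",
    "compute_d_statistic",
    "d_statistic_bootstrap",
    "DStatResult",
]


@dataclass
class SFSVector:
    """Counts xi_i of derived-allele frequency classes i = 1..n-1."""

    counts: np.ndarray
    n: int
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.n - 1:
            raise ValueError("SFS must have n-1 frequency classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())


def compute_sfs(variants: VariantTable, sample_haplotypes=None) -> SFSVector:
    """Unfolded SFS over ``sample_haplotypes`` (default: all in the table).

    Sites monomorphic within the subsample (derived count 0 or n) are
    excluded; their number is recorded in ``n_excluded`` and warned about.
    """
    haps = list(
        variants.haplotypes if sample_haplotypes is None else sample_haplotypes
    )
    n = len(haps)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = variants.derived_counts(haps)
    seg = (counts > 0) & (counts < n)
    excluded = int(np.sum(~seg))
    if excluded:
        warnings.warn(
            f"{excluded} site(s) monomorphic in the subsample were excluded"
        )
    xi = np.bincount(counts[seg], minlength=n)[1:n]
    return SFSVector(counts=xi, n=n, n_excluded=excluded)


def neutral_expectation(theta: float, n: int) -> np.ndarray:
    """Standard neutral expectation E[xi_i] = theta / i, i = 1..n-1."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n < 2:
        raise ValueError("n must be at least 2")
    return theta / np.arange(1, n)


def intermediate_skew(sfs: SFSVector, middle_fraction: float = 1 / 3) -> float:
    """Excess of segregating sites at intermediate derived frequencies.

    Score = (observed proportion of segregating sites in the middle
    ``middle_fraction`` of frequency classes) - (the proportion implied by
    the neutral 1/i shape). Positive scores mean an intermediate-frequency
    excess, the signature of spatial structure in the unfolded SFS.
    """
    k = sfs.counts.size
    if k < 6:
        raise ValueError("need at least 6 frequency classes")
    if sfs.n_segregating == 0:
        raise ValueError("no segregating sites")
    lo = int(np.floor(k * (0.5 - middle_fraction / 2)))
    hi = int(np.ceil(k * (0.5 + middle_fraction / 2)))
    obs = sfs.counts[lo:hi].sum() / sfs.n_segregating
    w = 1.0 / np.arange(1, k + 1)
    neutral = w[lo:hi].sum() / w.sum()
    return float(obs - neutral)


@dataclass(frozen=True)
class DStatResult:
    D: float
    abba: int
    baba: int


def compute_d_statistic(
    variants: VariantTable, p1: str, p2: str, p3: str, outgroup: str
) -> DStatResult:
    """ABBA-BABA D over biallelic sites, one haplotype per taxon.

    Sites where the outgroup carries the derived allele are skipped (the
    outgroup defines the ancestral state). D = (ABBA - BABA) /
    (ABBA + BABA); an excess of one pattern suggests gene flow between P3
    and one ingroup taxon -- or, just as well, spatially structured
    ancestry.
    """
    mat = variants.matrix([p1, p2, p3, outgroup]).astype(bool)
    d1, d2, d3, do = mat.T
    usable = ~do
    abba = int(np.sum(usable & ~d1 & d2 & d3))
    baba = int(np.sum(usable & d1 & ~d2 & d3))
    if abba + baba == 0:
        raise ValueError("no ABBA or BABA sites")
    return DStatResult(D=(abba - baba) / (abba + baba), abba=abba, baba=baba)


def d_statistic_bootstrap(
    variants: VariantTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    rng: np.random.Generator,
    n_boot: int = 1000,
) -> float:
    """Two-sided p-value for D != 0 by block bootstrap over loci.

    Loci are resampled with replacement (sites within a locus share a
    genealogy, so the locus is the exchangeable block) and D recomputed;
    the p-value is the normal-approximation tail of D / sd(D*).
    """
    mat = variants.matrix([p1, p2, p3, outgroup]).astype(bool)
    d1, d2, d3, do = mat.T
    usable = ~do
    abba_site = usable & ~d1 & d2 & d3
    baba_site = usable & d1 & ~d2 & d3
    loci = np.unique(variants.locus)
    per_locus = np.zeros((loci.size, 2))
    for i, l in enumerate(loci):
        sel = variants.locus == l
        per_locus[i] = [abba_site[sel].sum(), baba_site[sel].sum()]
    tot = per_locus.sum(axis=0)
    if tot.sum() == 0:
        raise ValueError("no ABBA or BABA sites")
    d_obs = (tot[0] - tot[1]) / tot.sum()
    draws = rng.integers(0, loci.size, size=(n_boot, loci.size))
    boot = per_locus[draws].sum(axis=1)
    denom = boot.sum(axis=1)
    ok = denom > 0
    d_boot = (boot[ok, 0] - boot[ok, 1]) / denom[ok]
    sd = d_boot.std(ddof=1)
    if sd == 0:
        return 1.0 if d_obs == 0 else 0.0
    from scipy import stats

    z = d_obs / sd
    return float(2.0 * stats.norm.sf(abs(z)))
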