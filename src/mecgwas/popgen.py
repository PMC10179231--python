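"""Hardy-Weinberg equilibrium tests and pairwise linkage disequilibrium.

HWE is tested two ways: the 1-df Pearson chi-square against expected
genotype proportions p^2 : 2pq : q^2, and the exact conditional test that
sums, over all heterozygote counts compatible with the observed allele
counts, the probabilities no larger than that of the observed table.  LD
between two unphased SNPs is measured by D' and r^2 from two-locus haplotype
frequencies estimated by EM, where only the double-heterozygote diplotype is
phase-ambiguous and is split by the current phase odds each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

__all__ = ["HWEResult", "LDResult", "hwe_chi2", "hwe_exact", "ld_em"]


@dataclass(frozen=True)
class HWEResult:
    n_AA: int
    n_Aa: int
    n_aa: int
    chi2: float
    df: int
    p_chi2: float
    p_exact: float | None = None


@dataclass(frozen=True)
class LDResult:
    """Pairwise LD summary; ``defined`` is False for a monomorphic locus."""

    hap_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    d_prime: float
    r2: float
    defined: bool = True
    n_iter: int = 0
    loglik: float = float("nan")


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Pearson 1-df goodness-of-fit test against HWE proportions.

    The expected counts use the sample allele frequency.  A monomorphic
    sample has nothing to test and returns chi2 = 0 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype sample")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(n_AA, n_Aa, n_aa, 0.0, 1, 1.0)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return HWEResult(n_AA, n_Aa, n_aa, chi2, 1, float(stats.chi2.sf(chi2, 1)))


def _het_prob(n_het: int, n: int, n_a: int) -> Fraction:
    """Exact P(heterozygote count | allele counts) under HWE, as a rational.

    Conditional distribution of the number of heterozygotes given n diploid
    individuals and n_a copies of the minor allele.
    """
    n_hom_minor = (n_a - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    num = (
        Fraction(comb(n, n_het))
        * comb(n - n_het, n_hom_minor)
        * 2**n_het
    )
    return num / comb(2 * n, n_a)


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE test (standard, non-mid-p formulation).

    Sums the probabilities of all heterozygote counts — given the observed
    allele counts — that are no more probable than the observed one.
    Computed in exact rational arithmetic, so there is no tie tolerance.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype sample")
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele copies
    if n_a == 0:
        return 1.0
    obs_p = _het_prob(n_Aa, n, n_a)
    total = Fraction(0)
    start = n_a % 2
    for het in range(start, n_a + 1, 2):
        if (n_a - het) // 2 + het > n:
            continue
        pr = _het_prob(het, n, n_a)
        if pr <= obs_p:
            total += pr
    return float(min(total, Fraction(1)))


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over complete cases."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    tab = np.zeros((3, 3))
    for a, b in zip(g1[ok].astype(int), g2[ok].astype(int)):
        tab[a, b] += 1
    return tab


def ld_em(
    g1: np.ndarray,
    g2: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> LDResult:
    """Estimate two-locus haplotype frequencies by EM and derive D'/r^2.

    Genotypes are minor-allele counts (0/1/2, NaN missing).  Haplotypes are
    ordered (AB, Ab, aB, ab) with A/B the minor alleles.  All diplotypes
    except the double heterozygote have known phase; the EM splits the
    double-het mass between AB/ab and Ab/aB by the current phase odds.

    D = p_AB - p_A p_B; D' = |D| / D_max; r^2 = D^2 / (p_A p_a p_B p_b).
    """
    tab = _genotype_table(g1, g2)
    n = tab.sum()
    if n < 2:
        raise ValueError("need >= 2 complete diplotypes")
    # allele frequencies of the coded (minor) allele at each locus
    pA = (2 * tab[2, :].sum() + tab[1, :].sum()) / (2 * n)
    pB = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDResult(np.full(4, np.nan), np.nan, np.nan, np.nan, defined=False)

    # known haplotype counts (AB, Ab, aB, ab) excluding double hets
    known = np.zeros(4)
    for a in range(3):
        for b in range(3):
            c = tab[a, b]
            if c == 0 or (a == 1 and b == 1):
                continue
            # each individual contributes two haplotypes with known phase
            hapA = {2: (1, 1), 1: (1, 0), 0: (0, 0)}[a]
            hapB = {2: (1, 1), 1: (1, 0), 0: (0, 0)}[b]
            for ha, hb in zip(hapA, hapB):
                known[_hap_index(ha, hb)] += c
    n_dh = tab[1, 1]

    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = known + n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = counts / counts.sum()
        ll = _ld_loglik(known, n_dh, f_new)
        if np.all(np.abs(f_new - f) < tol) and ll - ll_prev < tol:
            f = f_new
            break
        f = f_new
        ll_prev = ll
    D = f[0] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / d_max if d_max > 0 else np.nan
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(f, float(D), float(d_prime), float(r2), True, it,
                    _ld_loglik(known, n_dh, f))


def _hap_index(ha: int, hb: int) -> int:
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(ha, hb)]


def _ld_loglik(known: np.ndarray, n_dh: float, f: np.ndarray) -> float:
    """Observed-data log likelihood of haplotype frequencies."""
    with np.errstate(divide="ignore"):
        lf = np.where(known > 0, np.log(np.maximum(f, 1e-300)), 0.0)
    ll = float(known @ lf)
    if n_dh > 0:
        ll += n_dh * float(np.log(max(2 * f[0] * f[3] + 2 * f[1] * f[2], 1e-300)))
    return ll
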