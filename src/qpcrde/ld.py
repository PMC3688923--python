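"""Pairwise linkage disequilibrium from unphased genotypes.

For each pair of biallelic SNPs the four haplotype frequencies are
estimated from the 3x3 genotype count table by an EM algorithm: every
genotype combination except the double heterozygote determines its two
gametes; the double heterozygotes are split between the coupling (AB/ab)
and repulsion (Ab/aB) phases in proportion to the current frequency
estimates, and frequencies are re-estimated until convergence.  The
linkage statistic is

    r^2 = D^2 / (p_A p_a p_B p_b),    D = f(AB) - p_A p_B,

the squared allelic correlation; r^2 = 1 means the two SNPs cosegregate.
Groups of mutually cosegregating SNPs are recovered as connected
components of the r^2 >= threshold graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import GenotypeTable

__all__ = [
    "LdResult",
    "maf",
    "two_locus_counts",
    "em_haplotypes",
    "r_squared",
    "d_prime",
    "ld_matrix",
    "cosegregation_groups",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000
COMPLETE_LINKAGE_TOL = 1e-9


class EmError(RuntimeError):
    """EM failed to converge; carries the iteration trace."""

    def __init__(self, msg: str, trace: list[np.ndarray]):
        super().__init__(msg)
        self.trace = trace


def maf(calls: Sequence[str | None]) -> float:
    """Minor allele frequency of a genotype column (missing calls excluded).

    Monomorphic columns return 0.0.
    """
    counts: dict[str, int] = {}
    for call in calls:
        if call is None:
            continue
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
    if not counts:
        raise ValueError("no non-missing calls")
    if len(counts) > 2:
        raise ValueError(f"more than two alleles: {sorted(counts)}")
    total = sum(counts.values())
    if len(counts) == 1:
        return 0.0
    return min(counts.values()) / total


def _dosage(call: str | None, allele: str) -> int | None:
    if call is None:
        return None
    return call.count(allele)


def two_locus_counts(
    calls1: Sequence[str | None], calls2: Sequence[str | None]
) -> tuple[np.ndarray, list[str], list[str]]:
    """3x3 genotype count table for two SNP columns (pairwise-complete).

    Rows index copies (0, 1, 2) of the alphabetically second allele at
    locus 1, columns likewise for locus 2.  Returns the table together
    with the sorted allele lists of each locus.  Monomorphic loci get a
    single pseudo second allele count of zero copies.
    """
    if len(calls1) != len(calls2):
        raise ValueError("genotype columns differ in length")

    def alleles_of(calls):
        s: set[str] = set()
        for c in calls:
            if c is not None:
                s.update(c)
        return sorted(s)

    a1, a2 = alleles_of(calls1), alleles_of(calls2)
    if len(a1) > 2 or len(a2) > 2:
        raise ValueError("loci must be biallelic")
    counts = np.zeros((3, 3), dtype=float)
    for c1, c2 in zip(calls1, calls2):
        if c1 is None or c2 is None:
            continue
        i = c1.count(a1[-1]) if len(a1) == 2 else 0
        j = c2.count(a2[-1]) if len(a2) == 2 else 0
        counts[i, j] += 1
    if counts.sum() == 0:
        raise ValueError("no pairwise-complete genotype calls")
    return counts, a1, a2


def em_haplotypes(counts: np.ndarray) -> np.ndarray:
    """EM haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) from a 3x3 table.

    "A"/"B" denote the allele indexed by 0 rows/columns.  Every cell but
    the double heterozygote contributes unambiguous gametes; the double
    heterozygote count is split between coupling and repulsion phase by
    the current estimates.  Starts from linkage equilibrium (product of
    allele frequencies), converges when no frequency moves by more than
    1e-8, errors after 1000 iterations.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3) or (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("counts must be a non-negative 3x3 table with total > 0")
    n = counts.sum()
    # allele frequencies: index 0 = allele 'A'/'B' (0 copies of second allele)
    dos1 = counts.sum(axis=1) @ np.array([0.0, 1.0, 2.0])
    dos2 = counts.sum(axis=0) @ np.array([0.0, 1.0, 2.0])
    p_a2 = dos1 / (2 * n)  # freq of second allele at locus 1
    p_b2 = dos2 / (2 * n)
    freqs = np.array(
        [
            (1 - p_a2) * (1 - p_b2),
            (1 - p_a2) * p_b2,
            p_a2 * (1 - p_b2),
            p_a2 * p_b2,
        ]
    )
    # unambiguous gamete counts: cell (i, j) holds i copies of the second
    # allele at locus 1 and j at locus 2; except (1,1) the two gametes are
    # determined.
    base = np.zeros(4)  # AB, Ab, aB, ab with 'a','b' = second alleles
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # each individual contributes two gametes
            g1 = [0] * (2 - i) + [1] * i  # locus-1 allele per gamete
            g2 = [0] * (2 - j) + [1] * j
            # for single hets pair the alleles arbitrarily: phase is
            # irrelevant when only one locus is heterozygous
            for k in range(2):
                idx = 2 * g1[k] + g2[k]
                base[idx] += c
    dh = counts[1, 1]
    trace = [freqs.copy()]
    for _ in range(EM_MAX_ITER):
        if dh > 0:
            coupling = freqs[0] * freqs[3]
            repulsion = freqs[1] * freqs[2]
            tot = coupling + repulsion
            w = 0.5 if tot == 0 else coupling / tot
            extra = np.array([w, 1 - w, 1 - w, w]) * dh
        else:
            extra = np.zeros(4)
        new = (base + extra) / (2 * n)
        delta = np.abs(new - freqs).max()
        freqs = new
        trace.append(freqs.copy())
        if delta < EM_TOL:
            return freqs
    raise EmError("EM did not converge within 1000 iterations", trace)


def _allele_freqs(hapfreqs: np.ndarray) -> tuple[float, float]:
    p_a = hapfreqs[0] + hapfreqs[1]  # first allele at locus 1
    p_b = hapfreqs[0] + hapfreqs[2]  # first allele at locus 2
    return float(p_a), float(p_b)


def r_squared(hapfreqs: Sequence[float]) -> float:
    """Squared allelic correlation from four haplotype frequencies.

    Frequencies are ordered (AB, Ab, aB, ab).  Returns NaN when either
    locus is monomorphic; otherwise clamps to [0, 1] against floating-
    point drift.
    """
    h = np.asarray(hapfreqs, dtype=float)
    if h.shape != (4,) or not np.isclose(h.sum(), 1.0, atol=1e-6):
        raise ValueError("need four haplotype frequencies summing to 1")
    p_a, p_b = _allele_freqs(h)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return float("nan")
    d = h[0] - p_a * p_b
    return float(min(max(d * d / denom, 0.0), 1.0))


def d_prime(hapfreqs: Sequence[float]) -> float:
    """Normalized disequilibrium D' (secondary statistic)."""
    h = np.asarray(hapfreqs, dtype=float)
    p_a, p_b = _allele_freqs(h)
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        return float("nan")
    d = h[0] - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    return float(abs(d) / dmax) if dmax > 0 else float("nan")


@dataclass
class LdResult:
    """Pairwise r^2 matrix with per-SNP MAFs and cosegregation groups."""

    r2: pd.DataFrame
    mafs: pd.Series
    dprime: pd.DataFrame
    groups: list[list[str]]


def ld_matrix(
    gt: GenotypeTable, group_threshold: float = 1.0 - COMPLETE_LINKAGE_TOL
) -> LdResult:
    """All pairwise r^2 (EM-based) for the SNPs of a genotype table.

    Animals missing a call at either locus of a pair are dropped for that
    pair only.  Pairs involving a monomorphic SNP get NaN.
    """
    snps = gt.snps
    k = len(snps)
    r2 = pd.DataFrame(np.eye(k), index=snps, columns=snps)
    dp = pd.DataFrame(np.eye(k), index=snps, columns=snps)
    mafs = pd.Series({s: maf(list(gt.calls[s])) for s in snps}, name="maf")
    for i in range(k):
        for j in range(i + 1, k):
            counts, a1, a2 = two_locus_counts(
                list(gt.calls[snps[i]]), list(gt.calls[snps[j]])
            )
            if len(a1) < 2 or len(a2) < 2:
                val = dval = float("nan")
            else:
                h = em_haplotypes(counts)
                val = r_squared(h)
                dval = d_prime(h)
            r2.iloc[i, j] = r2.iloc[j, i] = val
            dp.iloc[i, j] = dp.iloc[j, i] = dval
    groups = cosegregation_groups(r2, threshold=group_threshold)
    return LdResult(r2=r2, mafs=mafs, dprime=dp, groups=groups)


def cosegregation_groups(
    r2: pd.DataFrame, threshold: float = 1.0 - COMPLETE_LINKAGE_TOL
) -> list[list[str]]:
    """Partition SNPs by transitive closure of pairs with r^2 >= threshold.

    Missing (NaN) entries count as below threshold.  Groups are sorted by
    their smallest member id; members sorted within each group.
    """
    snps = list(r2.index)
    parent = {s: s for s in snps}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(snps):
        for b in snps[i + 1 :]:
            v = r2.at[a, b]
            if not np.isnan(v) and v >= threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for s in snps:
        groups.setdefault(find(s), []).append(s)
    out = [sorted(members) for members in groups.values()]
    out.sort(key=lambda g: g[0])
    return out
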