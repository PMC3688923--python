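"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops, statistics.stdev, no shared code with
the package internals.
"""

import math
import statistics

import numpy as np


def brute_pairwise_variation(values, samples, genes, gene_j, gene_k):
    """SD of per-sample log2 ratios, written as an explicit loop."""
    j = genes.index(gene_j)
    k = genes.index(gene_k)
    ratios = [math.log2(values[s][j] / values[s][k]) for s in range(len(samples))]
    return statistics.stdev(ratios)


def brute_stability_m(values, samples, genes):
    """M_j = mean over k != j of V_jk."""
    out = {}
    for g in genes:
        vs = [
            brute_pairwise_variation(values, samples, genes, g, other)
            for other in genes
            if other != g
        ]
        out[g] = sum(vs) / len(vs)
    return out


def brute_rank(values, samples, genes):
    """Stepwise exclusion of the highest-M gene (lexicographic-last ties)."""
    rounds = []
    current_genes = list(genes)
    current_values = [list(row) for row in values]
    while len(current_genes) > 2:
        m = brute_stability_m(current_values, samples, current_genes)
        worst = max(m.values())
        tied = sorted(g for g, v in m.items() if abs(v - worst) <= 1e-12)
        excluded = tied[-1]
        rounds.append((list(current_genes), m, excluded))
        idx = current_genes.index(excluded)
        current_genes.pop(idx)
        for row in current_values:
            row.pop(idx)
    m = brute_stability_m(current_values, samples, current_genes)
    rounds.append((list(current_genes), m, None))
    return rounds, tuple(sorted(current_genes))


def gamete_count_haplotypes(counts):
    """Direct gamete counting; valid only when no double heterozygotes."""
    counts = np.asarray(counts, dtype=float)
    assert counts[1, 1] == 0
    hap = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0:
                continue
            g1 = [0] * (2 - i) + [1] * i
            g2 = [0] * (2 - j) + [1] * j
            for k in range(2):
                hap[2 * g1[k] + g2[k]] += c
    return hap / hap.sum()


def sample_two_locus_table(hapfreqs, n, rng):
    """Draw n diplotypes from known haplotype frequencies, collapse phase."""
    haps = rng.choice(4, size=(n, 2), p=np.asarray(hapfreqs, dtype=float))
    table = np.zeros((3, 3))
    for h1, h2 in haps:
        i = (h1 >> 1) + (h2 >> 1)  # copies of second allele, locus 1
        j = (h1 & 1) + (h2 & 1)
        table[i, j] += 1
    return table


def anova_one_way_reml(y_by_group):
    """Balanced one-way random-effects REML = ANOVA estimators.

    y_by_group: 2-D array (m groups x k replicates).  Returns
    (mu_hat, sigma2_between, sigma2_within); the between component is
    clamped at zero.
    """
    y = np.asarray(y_by_group, dtype=float)
    m, k = y.shape
    group_means = y.mean(axis=1)
    grand = y.mean()
    msw = ((y - group_means[:, None]) ** 2).sum() / (m * (k - 1))
    msb = k * ((group_means - grand) ** 2).sum() / (m - 1)
    return grand, max((msb - msw) / k, 0.0), msw
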