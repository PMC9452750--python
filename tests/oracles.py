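"""Independent reference computations used only by the test suite.

Each routine is a direct, scalar-level transcription of the published
formula it checks, deliberately written without reuse of the package's
vectorized implementations.
"""

import numpy as np
from math import comb


def wc84_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components a, b, c for one site.

    Two populations; n_i diploid sample sizes, p_i alternate-allele
    frequencies, h_i observed heterozygote proportions. Scalar
    transcription of the published component formulas.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc84_from_genotypes(g1, g2):
    """Components from two genotype vectors (codes 0/1/2, -1 missing)."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    g1 = g1[g1 >= 0]
    g2 = g2[g2 >= 0]
    n1, n2 = len(g1), len(g2)
    p1 = g1.sum() / (2.0 * n1)
    p2 = g2.sum() / (2.0 * n2)
    h1 = (g1 == 1).mean()
    h2 = (g2 == 1).mean()
    return wc84_components(n1, p1, h1, n2, p2, h2)


def ari_contingency(labels_a, labels_b):
    """Adjusted Rand index from the contingency-table pair-count formula."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    n = len(labels_a)
    cats_a = {v: i for i, v in enumerate(sorted(set(labels_a.tolist())))}
    cats_b = {v: i for i, v in enumerate(sorted(set(labels_b.tolist())))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[cats_a[x], cats_b[y]] += 1
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return (sum_ij - expected) / (max_index - expected)


def pairwise_pi_bruteforce(genotypes):
    """Mean pairwise allele difference at one site, by explicit enumeration.

    ``genotypes`` are codes 0/1/2 with -1 missing; the 2n observed alleles
    are enumerated and all unordered pairs compared.
    """
    alleles = []
    for g in genotypes:
        if g < 0:
            continue
        alleles += [1] * int(g) + [0] * (2 - int(g))
    m = len(alleles)
    if m < 2:
        return 0.0
    diffs = sum(
        1 for i in range(m) for j in range(i + 1, m) if alleles[i] != alleles[j]
    )
    return diffs / comb(m, 2)


def pairwise_r2(x, y):
    """Squared Pearson correlation of two genotype dosage vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return 0.0
    return float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)
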