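"""Independent brute-force / enumeration oracles used by the test suite.

Each oracle is written directly from first principles (explicit pairwise
loops, exhaustive enumeration, textbook formulas evaluated with scalar
arithmetic) and never calls the library code paths it is checking.
"""

from math import comb

import numpy as np


def brute_ehh(alleles: np.ndarray, carriers, core: int, j: int) -> float:
    """EHH by explicit pairwise comparison over the site range core..j."""
    lo, hi = (core, j) if j >= core else (j, core)
    rows = [alleles[h, lo : hi + 1] for h in carriers]
    n = len(rows)
    ident = sum(
        1
        for a in range(n)
        for b in range(a + 1, n)
        if np.array_equal(rows[a], rows[b])
    )
    return ident / comb(n, 2)


def brute_sl(alleles: np.ndarray, carriers, core: int, cap: int) -> float:
    """Mean pairwise identity-tract length in sites (counting the core),
    each direction capped at `cap` sites."""
    L = alleles.shape[1]
    n = len(carriers)
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            ha, hb = alleles[carriers[a]], alleles[carriers[b]]
            length = 1  # the core itself (same allele by class membership)
            j = core - 1
            while j >= 0 and core - j <= cap and ha[j] == hb[j]:
                length += 1
                j -= 1
            j = core + 1
            while j < L and j - core <= cap and ha[j] == hb[j]:
                length += 1
                j += 1
            total += length
    return total / comb(n, 2)


def enum_hwe_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE P by full enumeration with integer arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        # multinomial weight x 2^h, exact integers
        w = (
            comb(n, h) * comb(n - h, hom_min) * (2**h)
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_het]
    return sum(w for w in weights.values() if w <= obs) / total


def textbook_wc_components(pop_genotypes: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one SNP, scalar textbook form.

    pop_genotypes: one dosage vector (0/1/2, no missing) per population.
    """
    r = len(pop_genotypes)
    n = [len(g) for g in pop_genotypes]
    p = [sum(g) / (2 * len(g)) for g in pop_genotypes]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pop_genotypes]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni * ni for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_intersect(track_a, track_b):
    """All overlapping interval pairs by O(n^2) scan (1-based inclusive)."""
    out = []
    for a in track_a:
        for b in track_b:
            if a.chrom != b.chrom:
                continue
            ov = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1
            if ov >= 1:
                out.append((a, b, ov))
    return out
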