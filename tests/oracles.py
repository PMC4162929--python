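"""Independent brute-force oracles used to pin expected values.

Everything here is written in plain linear-space arithmetic, independent
of the package's log-space implementations, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def emission_linear(alleles, haplotype, alpha: float) -> float:
    p = 1.0
    for a, h in zip(alleles, haplotype):
        p *= (1.0 - alpha) if a == h else alpha
    return p


def nf_brute(alleles, pairs, alpha: float) -> float:
    """Sum over pairs and haplotype choices, linear space."""
    total = 0.0
    for hap_a, hap_b, prob in pairs:
        total += prob * 0.5 * (
            emission_linear(alleles, hap_a, alpha)
            + emission_linear(alleles, hap_b, alpha)
        )
    return total


def cf_brute(alleles, pairs, alpha: float) -> float:
    """Sum over pairs, split points and the two orderings, linear space."""
    L = len(alleles)
    total = 0.0
    for hap_a, hap_b, prob in pairs:
        for left, right in ((hap_a, hap_b), (hap_b, hap_a)):
            for k in range(1, L):
                total += prob * 0.5 * (
                    emission_linear(alleles[:k], left[:k], alpha)
                    * emission_linear(alleles[k:], right[k:], alpha)
                )
    return total


def chimerity_brute(alleles, h1, h2, alpha0: float) -> float:
    """Max-over-splits/orderings chimerity, linear space."""
    L = len(alleles)
    n = max(emission_linear(alleles, h1, alpha0),
            emission_linear(alleles, h2, alpha0))
    c = 0.0
    for left, right in ((h1, h2), (h2, h1)):
        for k in range(1, L):
            c = max(
                c,
                emission_linear(alleles[:k], left[:k], alpha0)
                * emission_linear(alleles[k:], right[k:], alpha0),
            )
    return float(np.log(c) - np.log(n))


def mann_whitney_auc(pos_scores, neg_scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def multinomial_grid_argmax(counts: dict[tuple, int], haplotypes, grid: int = 60):
    """Brute-force maximizer of the HWE multinomial genotype likelihood.

    For a tiny 2-site panel, scan frequency vectors over a simplex grid
    and return the best log-likelihood and frequencies.  ``counts`` maps
    genotype tuples to multiplicities.
    """
    best_ll = -np.inf
    best = None
    axes = [np.linspace(0, 1, grid + 1)] * (len(haplotypes) - 1)
    for combo in itertools.product(*axes):
        s = sum(combo)
        if s > 1.0 + 1e-12:
            continue
        freqs = list(combo) + [1.0 - s]
        ll = 0.0
        for geno, mult in counts.items():
            like = 0.0
            for fa, a in zip(freqs, haplotypes):
                for fb, b in zip(freqs, haplotypes):
                    if all(x + y == g for x, y, g in zip(a, b, geno)):
                        like += fa * fb
            if like <= 0:
                ll = -np.inf
                break
            ll += mult * np.log(like)
        if ll > best_ll:
            best_ll = ll
            best = freqs
    return best_ll, dict(zip(haplotypes, best))
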