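"""Chimerity based on statistical phasing (CSP).

A chimeric fragment (CF) is an artificial recombinant: its left and right
parts derive from different homologous chromosomes.  Because recombinants
of the two true haplotypes are unlikely to match any biological haplotype
in the population, a fragment that fits the candidate haplotype pairs only
*after* switching origin at some interior point is suspect.

For a SNP fragment f with covered sites X(f) and candidate haplotype
pairs h^(p) = (h^(p,A), h^(p,B)) with probabilities P(h^(p)):

* natural-fragment probability
  ``P_n(f) = sum_p P(h^(p)) * 1/2 * sum_{d in {A,B}} P(f | h^(p,d))``
* chimeric-fragment probability
  ``P_c(f) = sum_p P(h^(p)) * 1/2 * sum_{k=1}^{L-1} sum_{d != d'}
  P(f_<=k | h^(p,d)) * P(f_>k | h^(p,d'))``
* ``CSP(f) = ln P_c(f) - ln P_n(f)``

where ``P(f|h)`` multiplies (1 - alpha) per matching covered site and
alpha per mismatch; alpha absorbs sequencing and phasing errors.  The sum
over split points k is left unnormalized, which places the score peaks at
-ln(alpha/(1-alpha)) (switch one site from the end) and
-2 ln(alpha/(1-alpha)) (two sites from the end) — about 4.6 and 9.2 at
alpha = 0.01.  Fragments longer than the window width W are scored by the
maximum CSP over sliding windows of W consecutive covered sites, with the
candidate pairs re-obtained per window.

Everything is computed in log space with log-sum-exp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.special import logsumexp

from .phasing import CandidatePairSet, PhasingError
from .types import SnpFragment, ValidationError

logger = logging.getLogger(__name__)


class PhasingBackend(Protocol):
    def pairs_for(self, window_sites: Sequence[int]) -> CandidatePairSet: ...


@dataclass
class CspParams:
    """Scoring parameters: error term, window width, CF-candidate cutoff."""

    alpha: float = 0.01
    window: int = 5
    threshold: float = 7.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValidationError("alpha must be in (0, 0.5)")
        if self.window < 2:
            raise ValidationError("window width must be >= 2")
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


@dataclass
class CspResult:
    """CSP of one fragment; ``score`` is None for unscorable fragments."""

    fragment_id: str
    score: Optional[float]
    window_scores: list[tuple[int, float]] = field(default_factory=list)


def log_emission(
    alleles: Sequence[int], haplotype: Sequence[int], alpha: float
) -> float:
    """ln P(alleles | haplotype): per-site (1-alpha) on match, alpha on mismatch."""
    a = np.asarray(alleles)
    h = np.asarray(haplotype)
    if a.shape != h.shape:
        raise ValidationError("fragment and haplotype lengths differ")
    mismatches = int(np.sum(a != h))
    matches = a.size - mismatches
    if alpha == 0.0:
        return 0.0 if mismatches == 0 else -np.inf
    return matches * math.log1p(-alpha) + mismatches * math.log(alpha)


def emission_prob(
    alleles: Sequence[int], haplotype: Sequence[int], alpha: float
) -> float:
    return float(np.exp(log_emission(alleles, haplotype, alpha)))


def _restrict(fragment: SnpFragment, pairs: CandidatePairSet) -> np.ndarray:
    """Column of each fragment site within the window, validating coverage."""
    index = {s: j for j, s in enumerate(pairs.window_sites)}
    try:
        return np.asarray([index[int(s)] for s in fragment.sites])
    except KeyError as exc:
        raise ValidationError(
            f"fragment {fragment.id} covers site {exc.args[0]} outside window"
        ) from exc


def log_nf_probability(
    fragment: SnpFragment, pairs: CandidatePairSet, alpha: float
) -> float:
    """ln of the natural-fragment probability (mixture over pairs and haplotypes)."""
    if not pairs.pairs:
        raise ValidationError("empty candidate pair set")
    cols = _restrict(fragment, pairs)
    alleles = np.asarray(fragment.alleles)
    terms = []
    for hap_a, hap_b, prob in pairs.pairs:
        if prob <= 0:
            continue
        lp = math.log(prob) + math.log(0.5)
        for hap in (hap_a, hap_b):
            h = np.asarray(hap)[cols]
            terms.append(lp + log_emission(alleles, h, alpha))
    return float(logsumexp(terms))


def log_cf_probability(
    fragment: SnpFragment, pairs: CandidatePairSet, alpha: float
) -> float:
    """ln of the chimeric-fragment probability (single switch, all splits).

    The sum over split points is unnormalized: no 1/(L-1) prior, so a
    perfect recombinant scores near the number of covered sites on its
    minority side times -ln(alpha/(1-alpha)).
    """
    if fragment.size < 2:
        raise ValidationError("chimeric probability needs a fragment of size >= 2")
    if not pairs.pairs:
        raise ValidationError("empty candidate pair set")
    cols = _restrict(fragment, pairs)
    alleles = np.asarray(fragment.alleles)
    terms = []
    for hap_a, hap_b, prob in pairs.pairs:
        if prob <= 0:
            continue
        lp = math.log(prob) + math.log(0.5)
        ha = np.asarray(hap_a)[cols]
        hb = np.asarray(hap_b)[cols]
        for left, right in ((ha, hb), (hb, ha)):
            for k in range(1, fragment.size):
                terms.append(
                    lp
                    + log_emission(alleles[:k], left[:k], alpha)
                    + log_emission(alleles[k:], right[k:], alpha)
                )
    return float(logsumexp(terms))


def nf_probability(
    fragment: SnpFragment, pairs: CandidatePairSet, alpha: float
) -> float:
    return float(np.exp(log_nf_probability(fragment, pairs, alpha)))


def cf_probability(
    fragment: SnpFragment, pairs: CandidatePairSet, alpha: float
) -> float:
    return float(np.exp(log_cf_probability(fragment, pairs, alpha)))


def csp_window(fragment: SnpFragment, pairs: CandidatePairSet, alpha: float) -> float:
    """CSP of a fragment against one window's candidate pairs."""
    return log_cf_probability(fragment, pairs, alpha) - log_nf_probability(
        fragment, pairs, alpha
    )


def csp_score(
    fragment: SnpFragment, backend: PhasingBackend, params: CspParams
) -> CspResult:
    """CSP of a fragment, sliding over windows of W consecutive covered sites.

    Fragments of size <= W are scored in one piece over S = X(f); longer
    fragments take the maximum over all windows (the window placing a
    switch deepest from its end scores highest).  Fragments of size < 2
    cannot host a switch and get a missing score.
    """
    if fragment.size < 2:
        return CspResult(fragment_id=fragment.id, score=None)
    W = params.window
    if fragment.size <= W:
        offsets = [0]
        width = fragment.size
    else:
        offsets = list(range(fragment.size - W + 1))
        width = W
    window_scores: list[tuple[int, float]] = []
    for beta in offsets:
        sub = fragment.subfragment(beta, beta + width)
        try:
            pairs = backend.pairs_for(tuple(int(s) for s in sub.sites))
            score = csp_window(sub, pairs, params.alpha)
        except (PhasingError, ValidationError) as exc:
            logger.warning(
                "fragment %s: window at offset %d skipped: %s", fragment.id, beta, exc
            )
            continue
        window_scores.append((beta, score))
    if not window_scores:
        return CspResult(fragment_id=fragment.id, score=None)
    best = max(s for _, s in window_scores)
    return CspResult(fragment_id=fragment.id, score=best, window_scores=window_scores)


def detect_cf_candidates(
    results: Sequence[CspResult], threshold: float
) -> list[bool]:
    """CF candidate iff a score is present and exceeds the threshold."""
    return [r.score is not None and r.score > threshold for r in results]
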