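"""Trio-based chimerity and true CF/NF labeling.

When a trio (child plus parents) resolves the child's haplotypes, a
fragment can be tested directly: how much better does it fit as a
single-switch recombinant of the true haplotype pair than as a copy of
one haplotype?  With the fixed error term alpha0,

* N = max_d P(f | h^(t,d))
* C = max over split k in 1..L-1 and orderings d != d' of
  P(f_<=k | h^(t,d)) * P(f_>k | h^(t,d'))
* chimerity = ln C - ln N

A fragment identical to one haplotype has chimerity ln(alpha0/(1-alpha0))
(< 0); a perfect single-switch chimera with m covered sites on its
minority side has chimerity -m ln(alpha0/(1-alpha0)).  The default label
cutoff -2 ln(alpha0/(1-alpha0)) therefore demands at least two error-
equivalents of support for the switch.  Fragments covering any site the
trio could not determine are excluded from labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

from .csp import log_emission
from .types import HaplotypeBlock, SnpFragment, TrioTruth, ValidationError

TruthLike = Union[TrioTruth, HaplotypeBlock, Sequence[HaplotypeBlock]]


class Label(str, Enum):
    CF = "CF"
    NF = "NF"
    EXCLUDED = "excluded"


def default_chimerity_threshold(alpha0: float) -> float:
    return -2.0 * math.log(alpha0 / (1.0 - alpha0))


@dataclass
class TruthParams:
    """Chimerity error term and label cutoff."""

    alpha0: float = 0.01
    chimerity_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 < 0.5:
            raise ValidationError("alpha0 must be in (0, 0.5)")
        if self.chimerity_threshold is None:
            self.chimerity_threshold = default_chimerity_threshold(self.alpha0)


def _truth_haplotypes(
    truth: TruthLike, sites: np.ndarray
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """The true haplotype pair over ``sites``, or None if not all resolvable.

    Accepts trio truth (undetermined sites unresolvable), a single block,
    or a list of blocks (a fragment spanning two blocks has no defined
    relative phase, hence unresolvable).
    """
    if isinstance(truth, TrioTruth):
        h1, h2 = [], []
        for s in sites:
            if not truth.is_determined(int(s)):
                return None
            a1, a2 = truth.alleles(int(s))
            h1.append(a1)
            h2.append(a2)
        return np.asarray(h1), np.asarray(h2)
    if isinstance(truth, HaplotypeBlock):
        blocks: Sequence[HaplotypeBlock] = [truth]
    else:
        blocks = truth
    for block in blocks:
        block_sites = set(int(s) for s in block.sites)
        if all(int(s) in block_sites for s in sites):
            idx = np.searchsorted(block.sites, sites)
            return np.asarray(block.hap1)[idx], np.asarray(block.hap2)[idx]
    return None


def trio_chimerity(
    fragment: SnpFragment, truth: TruthLike, params: TruthParams
) -> Optional[float]:
    """Chimerity of a fragment against true haplotypes; None if unscorable."""
    if fragment.size < 2:
        return None
    haps = _truth_haplotypes(truth, np.asarray(fragment.sites))
    if haps is None:
        return None
    h1, h2 = haps
    alleles = np.asarray(fragment.alleles)
    a0 = params.alpha0
    log_n = max(log_emission(alleles, h1, a0), log_emission(alleles, h2, a0))
    log_c = -math.inf
    for left, right in ((h1, h2), (h2, h1)):
        for k in range(1, fragment.size):
            val = log_emission(alleles[:k], left[:k], a0) + log_emission(
                alleles[k:], right[k:], a0
            )
            log_c = max(log_c, val)
    return log_c - log_n


@dataclass
class FragmentLabel:
    fragment_id: str
    chimerity: Optional[float]
    label: Label = field(default=Label.EXCLUDED)


_BOUNDARY_EPS = 1e-9  # a perfect 2-site switch sits exactly at the default cutoff


def label_fragments(
    fragments: Sequence[SnpFragment], truth: TruthLike, params: TruthParams
) -> list[FragmentLabel]:
    """Label each fragment CF / NF / excluded by its trio chimerity.

    The threshold comparison allows a tiny numerical tolerance: the
    boundary case (a perfect single-switch chimera with two minority
    sites) is mathematically equal to the default cutoff, and float
    cancellation over long fragments must not flip it.
    """
    out = []
    for frag in fragments:
        chim = trio_chimerity(frag, truth, params)
        if chim is None:
            label = Label.EXCLUDED
        elif chim >= params.chimerity_threshold - _BOUNDARY_EPS:
            label = Label.CF
        else:
            label = Label.NF
        out.append(FragmentLabel(fragment_id=frag.id, chimerity=chim, label=label))
    return out
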