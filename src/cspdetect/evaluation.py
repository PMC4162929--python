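"""Accuracy measures for chimera detection and haplotype assembly.

Chimera detection is scored as a binary classifier over trio-labeled
fragments (ROC over the score threshold, AUC).  Assembled haplotypes are
scored against trio truth by pairwise precision CP/(CP+IP), switch error
rate, and QAN50 — an N50-style span statistic over blocks cut at switch
errors, with each sub-block's physical span scaled by the fraction of
spanned heterozygous sites it actually phases.  Sites the trio could not
determine are excluded from all three assembly measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .truth_labels import Label
from .types import HaplotypeBlock, SitePositionTable, TrioTruth, ValidationError


@dataclass
class PrecisionResult:
    """Consistent / inconsistent phased-pair counts."""

    cp: int
    ip: int

    @property
    def precision(self) -> Optional[float]:
        if self.cp + self.ip == 0:
            return None
        return self.cp / (self.cp + self.ip)


@dataclass
class RocCurve:
    """ROC points (1-specificity, sensitivity) and the area under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValidationError("ROC points must be monotone non-decreasing")
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC must lie in [0, 1]")


def _block_orientations(
    block: HaplotypeBlock, truth: TrioTruth
) -> tuple[list[int], list[int]]:
    """Determined sites of a block and, per site, which truth hap matches hap1."""
    sites, orients = [], []
    for i, s in enumerate(block.sites):
        s = int(s)
        if not truth.is_determined(s):
            continue
        a1, _ = truth.alleles(s)
        sites.append(s)
        orients.append(0 if int(block.hap1[i]) == a1 else 1)
    return sites, orients


def pairwise_precision(
    blocks: Sequence[HaplotypeBlock], truth: TrioTruth
) -> PrecisionResult:
    """CP/IP over all within-block pairs of determined sites.

    A pair is consistent iff the inferred relative phase (same or
    different allele on hap1) matches the true relative phase.
    """
    cp = ip = 0
    for block in blocks:
        _, orients = _block_orientations(block, truth)
        n_a = sum(1 for o in orients if o == 0)
        n_b = len(orients) - n_a
        # pairs with equal orientation are consistent, mixed pairs are not
        cp += n_a * (n_a - 1) // 2 + n_b * (n_b - 1) // 2
        ip += n_a * n_b
    return PrecisionResult(cp=cp, ip=ip)


def switch_error_rate(
    blocks: Sequence[HaplotypeBlock], truth: TrioTruth
) -> Optional[float]:
    """Orientation flips between adjacent determined sites, per adjacent pair."""
    switches = pairs = 0
    for block in blocks:
        _, orients = _block_orientations(block, truth)
        pairs += max(len(orients) - 1, 0)
        switches += sum(1 for a, b in zip(orients, orients[1:]) if a != b)
    if pairs == 0:
        return None
    return switches / pairs


def qan50(
    blocks: Sequence[HaplotypeBlock],
    truth: TrioTruth,
    positions: SitePositionTable,
) -> Optional[float]:
    """QAN50 in bases: N50 over switch-error-free sub-blocks, span-adjusted.

    Each block is cut at every switch error; a sub-block's adjusted span
    is its physical span (first to last phased site) times the fraction
    of spanned heterozygous sites it phases.  QAN50 is the adjusted span
    at which sub-blocks at least that large cover half of all phased
    sites.
    """
    sub_blocks: list[tuple[float, int]] = []  # (adjusted span, phased sites)
    for block in blocks:
        sites, orients = _block_orientations(block, truth)
        if not sites:
            continue
        runs: list[list[int]] = [[sites[0]]]
        for s, o_prev, o in zip(sites[1:], orients, orients[1:]):
            if o != o_prev:
                runs.append([s])
            else:
                runs[-1].append(s)
        for run in runs:
            span = positions.position(run[-1]) - positions.position(run[0])
            spanned = run[-1] - run[0] + 1
            adjusted = span * (len(run) / spanned)
            sub_blocks.append((adjusted, len(run)))
    if not sub_blocks:
        return None
    total = sum(n for _, n in sub_blocks)
    acc = 0
    for adjusted, n in sorted(sub_blocks, reverse=True):
        acc += n
        if acc * 2 >= total:
            return float(adjusted)
    return float(sub_blocks[-1][0])


def roc_auc(
    scores: Sequence[Optional[float]], labels: Sequence[Label | str]
) -> RocCurve:
    """ROC and AUC of a chimera score against CF/NF labels.

    Excluded items are ignored; missing scores rank below every finite
    score.  Requires at least one CF and one NF.
    """
    y, s = [], []
    for score, label in zip(scores, labels):
        label = Label(label)
        if label == Label.EXCLUDED:
            continue
        y.append(1 if label == Label.CF else 0)
        s.append(score)
    if not y or len(set(y)) < 2:
        raise ValidationError("ROC needs at least one CF and one NF")
    finite = [x for x in s if x is not None]
    floor = (min(finite) - 1.0) if finite else 0.0
    s = [floor if x is None else x for x in s]
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))
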