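"""Greedy single-individual haplotyping with connectivity confidence.

The assembler links sites that share a fragment into connected
components, greedily assigns each fragment a haplotype orientation
against the running consensus (largest fragments first; ties keep
orientation A), and emits complementary haplotype block pairs.  It is a
deliberately simple stand-in for likelihood-based assemblers; what
matters downstream is the *connectivity* confidence score, defined as
the log-likelihood margin of the assembled configuration over its
recombinant at a site j0:

``connectivity(j0) = L(H) - L(H')``

where H' swaps the two haplotypes at all block sites >= j0, and
``L(H) = sum_i ln 1/2 [P(f_i|h1) + P(f_i|h2)]`` over fragments touching
the block.  The minimum connectivity (MC) over a region's interior sites
gates block extraction; raising the MC threshold trades block length for
phasing reliability.

The module also implements coverage-based recovery of CF candidates:
candidates lying in well-covered regions are re-admitted, re-assembled
with the rest, and re-checked by chimerity against the inferred
haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .csp import log_emission
from .truth_labels import TruthParams, default_chimerity_threshold, trio_chimerity
from .types import HaplotypeBlock, SnpFragment, ValidationError


@dataclass
class AssemblyParams:
    """Assembler and recovery knobs (alpha is the emission error rate)."""

    alpha: float = 0.01
    mc_threshold: float = 0.0
    recovery_coverage_threshold: int = 3
    recovery_chimerity_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValidationError("alpha must be in (0, 0.5)")
        if self.recovery_coverage_threshold < 1:
            raise ValidationError("recovery coverage threshold must be >= 1")
        if self.recovery_chimerity_threshold is None:
            self.recovery_chimerity_threshold = default_chimerity_threshold(self.alpha)


def _components(fragments: Sequence[SnpFragment]) -> list[list[int]]:
    """Connected components of sites linked by shared fragments (union-find)."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for frag in fragments:
        sites = [int(s) for s in frag.sites]
        for s in sites:
            parent.setdefault(s, s)
        for a, b in zip(sites, sites[1:]):
            union(a, b)
    groups: dict[int, list[int]] = {}
    for s in parent:
        groups.setdefault(find(s), []).append(s)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def assemble(fragments: Sequence[SnpFragment]) -> list[HaplotypeBlock]:
    """Greedy consensus assembly; deterministic for a fixed input order.

    Within a component, fragments are processed largest-first among those
    that overlap a site with a defined consensus (so orientation always
    propagates through the component; input order breaks ties); each is
    oriented to agree with the current consensus at more of its covered
    sites (ties keep orientation A), then votes allele 0/1 per site; the
    consensus is the running majority (ties vote allele 0).
    """
    comps = _components(fragments)
    site_to_comp = {s: ci for ci, comp in enumerate(comps) for s in comp}
    per_comp: list[list[SnpFragment]] = [[] for _ in comps]
    for frag in fragments:
        per_comp[site_to_comp[int(frag.sites[0])]].append(frag)

    blocks: list[HaplotypeBlock] = []
    for ci, comp in enumerate(comps):
        votes = {s: 0 for s in comp}  # +1 per oriented allele 0, -1 per allele 1
        pending = list(enumerate(per_comp[ci]))
        while pending:
            overlapping = [
                (order, frag)
                for order, frag in pending
                if any(votes[int(s)] != 0 for s in frag.sites)
            ]
            pool = overlapping or pending
            order, frag = min(pool, key=lambda t: (-t[1].size, t[0]))
            pending.remove((order, frag))
            agree_a = agree_b = 0
            for s, a in zip(frag.sites, frag.alleles):
                v = votes[int(s)]
                if v == 0:
                    continue
                consensus = 0 if v > 0 else 1
                if int(a) == consensus:
                    agree_a += 1
                else:
                    agree_b += 1
            flip = agree_b > agree_a  # tie keeps orientation A
            for s, a in zip(frag.sites, frag.alleles):
                allele = int(a) ^ flip
                votes[int(s)] += 1 if allele == 0 else -1
        hap1 = [0 if votes[s] >= 0 else 1 for s in comp]
        blocks.append(
            HaplotypeBlock(
                id=f"block{len(blocks)}",
                sites=comp,
                hap1=hap1,
                hap2=[1 - a for a in hap1],
            )
        )
    return blocks


def _block_log_likelihood(
    block: HaplotypeBlock, fragments: Sequence[SnpFragment], alpha: float,
    swap_from: Optional[int] = None,
) -> float:
    """L(H) over fragments touching the block; optionally recombinant at a site."""
    site_idx = {int(s): i for i, s in enumerate(block.sites)}
    h1 = np.asarray(block.hap1).copy()
    h2 = np.asarray(block.hap2).copy()
    if swap_from is not None:
        j = site_idx[swap_from]
        h1[j:], h2[j:] = h2[j:].copy(), h1[j:].copy()
    total = 0.0
    for frag in fragments:
        cols = [site_idx[int(s)] for s in frag.sites if int(s) in site_idx]
        if not cols:
            continue
        alleles = np.asarray(
            [a for s, a in zip(frag.sites, frag.alleles) if int(s) in site_idx]
        )
        cols_arr = np.asarray(cols)
        e1 = log_emission(alleles, h1[cols_arr], alpha)
        e2 = log_emission(alleles, h2[cols_arr], alpha)
        total += math.log(0.5) + np.logaddexp(e1, e2)
    return total


def connectivity(
    block: HaplotypeBlock,
    fragments: Sequence[SnpFragment],
    j0: int,
    alpha: float,
) -> float:
    """Log-likelihood margin of H over its recombinant at interior site j0."""
    sites = [int(s) for s in block.sites]
    if j0 not in sites or j0 == sites[0]:
        raise ValidationError(f"site {j0} is not interior to the block")
    return _block_log_likelihood(block, fragments, alpha) - _block_log_likelihood(
        block, fragments, alpha, swap_from=j0
    )


def min_connectivity(
    block: HaplotypeBlock, fragments: Sequence[SnpFragment], alpha: float
) -> float:
    """MC of a block: minimum connectivity over its interior sites."""
    sites = [int(s) for s in block.sites]
    if len(sites) < 2:
        return math.inf
    return min(connectivity(block, fragments, j, alpha) for j in sites[1:])


def extract_blocks(
    blocks: Sequence[HaplotypeBlock],
    fragments: Sequence[SnpFragment],
    mc_threshold: float,
    alpha: float,
) -> list[HaplotypeBlock]:
    """Cut blocks at every interior site whose connectivity is below threshold."""
    out: list[HaplotypeBlock] = []
    for block in blocks:
        sites = [int(s) for s in block.sites]
        runs: list[list[int]] = [[0]]
        for i in range(1, len(sites)):
            if connectivity(block, fragments, sites[i], alpha) < mc_threshold:
                runs.append([i])
            else:
                runs[-1].append(i)
        for run in runs:
            idx = np.asarray(run)
            out.append(
                HaplotypeBlock(
                    id=f"{block.id or 'block'}.{len(out)}",
                    sites=np.asarray(block.sites)[idx],
                    hap1=np.asarray(block.hap1)[idx],
                    hap2=np.asarray(block.hap2)[idx],
                )
            )
    return out


def recover_candidates(
    cf_candidate_ids: set[str],
    all_fragments: Sequence[SnpFragment],
    params: AssemblyParams,
) -> dict[str, str]:
    """Coverage-based recovery of CF candidates, with a chimerity re-check.

    Chimeras arise from random co-aliquoting, so many candidate fragments
    stacked over the same well-covered region are more plausibly natural.
    A candidate is provisionally recovered iff every site it covers is
    covered by >= ``recovery_coverage_threshold`` non-candidate fragments;
    the provisional set is assembled together with the non-candidates and
    each recovered fragment re-checked by chimerity against the inferred
    haplotypes (re-removed if it still switches).
    Returns ``{candidate_id: "recovered" | "removed"}``.
    """
    non_candidates = [f for f in all_fragments if f.id not in cf_candidate_ids]
    candidates = [f for f in all_fragments if f.id in cf_candidate_ids]
    coverage: dict[int, int] = {}
    for frag in non_candidates:
        for s in frag.sites:
            coverage[int(s)] = coverage.get(int(s), 0) + 1

    provisional = [
        frag
        for frag in candidates
        if all(
            coverage.get(int(s), 0) >= params.recovery_coverage_threshold
            for s in frag.sites
        )
    ]
    status = {frag.id: "removed" for frag in candidates}
    if not provisional:
        return status

    blocks = assemble(non_candidates + provisional)
    truth_params = TruthParams(
        alpha0=params.alpha,
        chimerity_threshold=params.recovery_chimerity_threshold,
    )
    for frag in provisional:
        chim = trio_chimerity(frag, blocks, truth_params)
        if chim is not None and chim > params.recovery_chimerity_threshold:
            status[frag.id] = "removed"
        else:
            status[frag.id] = "recovered"
    return status
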