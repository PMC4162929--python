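"""Cluster-level preprocessing and the baseline chimera detectors.

A read cluster that merged two DNA fragments of different haplotype
origin tends (a) to be physically longer than typical clusters and (b)
to show heterozygous read calls where the merged fragments overlap.
This module implements the preprocessing that exploits those signals —
splitting clusters at heterozygous calls and at a length cap — plus the
three heterozygosity measures used as baseline chimera scores, and the
majority-decision conversion of clusters into SNP fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
    ReadCluster,
    SitePositionTable,
    SnpFragment,
    ValidationError,
)


@dataclass
class FilterParams:
    """Preprocessing knobs.

    ``max_cluster_len`` caps physical cluster span in bases (30 kb and
    45 kb were used for shorter- and longer-fragment dilution protocols,
    respectively).  ``avg_aliquot_coverage`` feeds the heterozygous-call
    rule; when None it is computed per aliquot from the data.
    """

    max_cluster_len: int = 45_000
    avg_aliquot_coverage: Optional[float] = None
    enable_het_split: bool = True
    enable_length_split: bool = True

    def __post_init__(self) -> None:
        if self.max_cluster_len <= 0:
            raise ValidationError("max_cluster_len must be positive")
        if self.avg_aliquot_coverage is not None and self.avg_aliquot_coverage < 0:
            raise ValidationError("avg_aliquot_coverage must be >= 0")


@dataclass
class HeterozygosityMeasures:
    """Minority-allele summaries of one cluster."""

    total: int
    maximum: float
    average: float

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValidationError("total heterozygosity must be >= 0")
        for v in (self.maximum, self.average):
            if not 0.0 <= v <= 0.5:
                raise ValidationError("minority rates must lie in [0, 0.5]")


def heterozygous_call(count0: int, count1: int, avg_aliquot_coverage: float) -> bool:
    """True iff a site's read counts look heterozygous within its cluster.

    Either condition triggers: minority reads exceed half the aliquot's
    average coverage, or minority reads exceed half the majority reads.
    """
    minority = min(count0, count1)
    majority = max(count0, count1)
    return minority > avg_aliquot_coverage / 2.0 or minority > majority / 2.0


def aliquot_coverage(clusters: list[ReadCluster]) -> dict[str, float]:
    """Mean reads per covered site, per aliquot, over that aliquot's clusters."""
    per_cluster: dict[str, list[float]] = {}
    for cl in clusters:
        covered = [(c0, c1) for _, c0, c1 in cl.site_counts if c0 + c1 > 0]
        if not covered:
            continue
        mean = sum(c0 + c1 for c0, c1 in covered) / len(covered)
        per_cluster.setdefault(cl.aliquot, []).append(mean)
    return {a: float(np.mean(v)) for a, v in per_cluster.items()}


def _piece(cluster: ReadCluster, suffix: str, start: int, end: int,
           site_counts: list[tuple[int, int, int]]) -> ReadCluster:
    return ReadCluster(
        id=f"{cluster.id}{suffix}",
        aliquot=cluster.aliquot,
        chrom=cluster.chrom,
        start=start,
        end=end,
        site_counts=site_counts,
    )


def split_cluster(
    cluster: ReadCluster,
    params: FilterParams,
    positions: SitePositionTable,
    avg_coverage: Optional[float] = None,
) -> list[ReadCluster]:
    """Split a cluster at heterozygous calls, then enforce the length cap.

    Heterozygous-call sites are dropped from both daughter pieces (their
    allele is unreliable by construction); the physical cut falls at the
    dropped site.  Pieces longer than ``max_cluster_len`` are then cut
    between covered sites into the minimal number of groups whose tight
    spans fit the cap, balancing site counts across groups.  Daughter ids
    are suffixed deterministically.
    """
    if avg_coverage is None:
        avg_coverage = params.avg_aliquot_coverage
        if avg_coverage is None:
            cov = aliquot_coverage([cluster])
            avg_coverage = cov.get(cluster.aliquot, 0.0)

    pieces: list[ReadCluster] = []
    if params.enable_het_split:
        current: list[tuple[int, int, int]] = []
        seg_start = cluster.start
        n_out = 0
        for entry in cluster.site_counts:
            site, c0, c1 = entry
            if heterozygous_call(c0, c1, avg_coverage):
                pos = positions.position(site)  # cut at the dropped site
                if current or seg_start < pos - 1:
                    pieces.append(
                        _piece(cluster, f".h{n_out}", seg_start, max(pos - 1, seg_start + 1), current)
                    )
                    n_out += 1
                current = []
                seg_start = pos
            else:
                current.append(entry)
        if n_out == 0 and seg_start == cluster.start:
            pieces.append(cluster)  # no het call: unchanged
        elif current or seg_start < cluster.end:
            pieces.append(_piece(cluster, f".h{n_out}", seg_start, cluster.end, current))
    else:
        pieces = [cluster]

    if not params.enable_length_split:
        return pieces

    out: list[ReadCluster] = []
    for piece in pieces:
        if piece.length <= params.max_cluster_len or len(piece.site_counts) <= 1:
            out.append(piece)
            continue
        out.extend(_length_split(piece, params.max_cluster_len, positions))
    return out


def _tight_span(site_counts: list[tuple[int, int, int]],
                positions: SitePositionTable) -> tuple[int, int]:
    first = positions.position(site_counts[0][0])
    last = positions.position(site_counts[-1][0])
    return first - 1, last  # 0-based half-open over the covered sites


def _length_split(
    cluster: ReadCluster, max_len: int, positions: SitePositionTable
) -> list[ReadCluster]:
    """Cut into the minimal number of balanced consecutive site groups."""
    n = len(cluster.site_counts)
    for m in range(2, n + 1):
        groups = [g for g in np.array_split(np.arange(n), m) if len(g)]
        spans = []
        for g in groups:
            counts = [cluster.site_counts[i] for i in g]
            s, e = _tight_span(counts, positions)
            spans.append(e - s)
        if all(sp <= max_len for sp in spans):
            out = []
            for j, g in enumerate(groups):
                counts = [cluster.site_counts[i] for i in g]
                s, e = _tight_span(counts, positions)
                out.append(_piece(cluster, f".l{j}", s, e, counts))
            return out
    # every group is a single site: always fits
    out = []
    for j in range(n):
        counts = [cluster.site_counts[j]]
        s, e = _tight_span(counts, positions)
        out.append(_piece(cluster, f".l{j}", s, e, counts))
    return out


def heterozygosity_measures(cluster: ReadCluster) -> HeterozygosityMeasures:
    """Total / maximum / average minority-allele measures of a cluster.

    Sites without reads are excluded from the maximum and average; the
    total sums minority reads over all sites.
    """
    rates = []
    total = 0
    for _, c0, c1 in cluster.site_counts:
        depth = c0 + c1
        minority = min(c0, c1)
        total += minority
        if depth > 0:
            rates.append(minority / depth)
    if not rates:
        raise ValidationError(f"cluster {cluster.id}: no site has reads")
    return HeterozygosityMeasures(
        total=total, maximum=float(max(rates)), average=float(np.mean(rates))
    )


def cluster_to_fragment(cluster: ReadCluster) -> Optional[SnpFragment]:
    """Majority-decision conversion of a cluster into a SNP fragment.

    Tied or zero-read sites are dropped; returns None if no site survives
    (fragments of size below 1 are discarded).
    """
    sites: list[int] = []
    alleles: list[int] = []
    for s, c0, c1 in cluster.site_counts:
        if c0 + c1 == 0 or c0 == c1:
            continue
        sites.append(s)
        alleles.append(0 if c0 > c1 else 1)
    if not sites:
        return None
    return SnpFragment(
        id=cluster.id, sites=sites, alleles=alleles, source_cluster=cluster.id
    )


def baseline_scores(
    clusters: list[ReadCluster],
) -> list[tuple[int, Optional[HeterozygosityMeasures]]]:
    """Per-cluster (physical length, heterozygosity measures) baseline scores."""
    out: list[tuple[int, Optional[HeterozygosityMeasures]]] = []
    for cl in clusters:
        try:
            measures: Optional[HeterozygosityMeasures] = heterozygosity_measures(cl)
        except ValidationError:
            measures = None
        out.append((cl.length, measures))
    return out


def filter_clusters(
    clusters: list[ReadCluster],
    positions: SitePositionTable,
    params: FilterParams,
) -> tuple[list[ReadCluster], list[SnpFragment]]:
    """Run the full preprocessing: split every cluster, convert to fragments."""
    coverage = (
        {cl.aliquot: params.avg_aliquot_coverage for cl in clusters}
        if params.avg_aliquot_coverage is not None
        else aliquot_coverage(clusters)
    )
    out_clusters: list[ReadCluster] = []
    for cl in clusters:
        out_clusters.extend(
            split_cluster(cl, params, positions, coverage.get(cl.aliquot, 0.0))
        )
    fragments = []
    for cl in out_clusters:
        frag = cluster_to_fragment(cl)
        if frag is not None:
            fragments.append(frag)
    return out_clusters, fragments
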