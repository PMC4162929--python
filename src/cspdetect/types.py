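"""Domain types for dilution-sequencing haplotype data.

All heterozygous sites are addressed by 1-based indices into the
genome-ordered list of the target individual's heterozygous sites
("site indices").  Genomic base coordinates (0-based, half-open) appear
only in :class:`ReadCluster` and :class:`SitePositionTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

MISSING = -1  # sentinel for a missing genotype cell


class ValidationError(ValueError):
    """An object violates one of its documented invariants."""


def _as_int_array(values: Iterable[int], name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=np.int64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class SnpFragment:
    """A virtual long read restricted to heterozygous sites.

    ``sites`` are strictly increasing 1-based site indices; ``alleles``
    hold the binary allele observed at each site.
    """

    id: str
    sites: Sequence[int]
    alleles: Sequence[int]
    source_cluster: Optional[str] = None

    def __post_init__(self) -> None:
        self.sites = _as_int_array(self.sites, "sites")
        self.alleles = _as_int_array(self.alleles, "alleles")
        if len(self.sites) != len(self.alleles):
            raise ValidationError(
                f"fragment {self.id}: {len(self.sites)} sites but "
                f"{len(self.alleles)} alleles"
            )
        if len(self.sites) < 1:
            raise ValidationError(f"fragment {self.id}: size must be >= 1")
        if np.any(np.diff(self.sites) <= 0):
            raise ValidationError(
                f"fragment {self.id}: site indices must be strictly increasing"
            )
        if not np.all((self.alleles == 0) | (self.alleles == 1)):
            raise ValidationError(f"fragment {self.id}: alleles must be 0/1")

    @property
    def size(self) -> int:
        return len(self.sites)

    def subfragment(self, start: int, stop: int) -> "SnpFragment":
        """Partial fragment over covered sites [start, stop) (0-based offsets)."""
        return SnpFragment(
            id=f"{self.id}[{start}:{stop}]",
            sites=self.sites[start:stop],
            alleles=self.alleles[start:stop],
            source_cluster=self.source_cluster,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpFragment):
            return NotImplemented
        return (
            self.id == other.id
            and np.array_equal(self.sites, other.sites)
            and np.array_equal(self.alleles, other.alleles)
            and self.source_cluster == other.source_cluster
        )


@dataclass
class ReadCluster:
    """A mapped short-read cluster: genomic span plus per-site allele counts.

    ``site_counts`` is an ordered list of ``(site_index, count0, count1)``.
    """

    id: str
    aliquot: str
    chrom: str
    start: int
    end: int
    site_counts: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"cluster {self.id}: start must be < end")
        sites = [s for s, _, _ in self.site_counts]
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ValidationError(
                f"cluster {self.id}: site indices must be strictly increasing"
            )
        if any(c0 < 0 or c1 < 0 for _, c0, c1 in self.site_counts):
            raise ValidationError(f"cluster {self.id}: counts must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sites(self) -> list[int]:
        return [s for s, _, _ in self.site_counts]

    def validate_positions(self, positions: "SitePositionTable") -> None:
        """Check that every counted site lies inside [start, end)."""
        for s, _, _ in self.site_counts:
            chrom, pos = positions.locate(s)
            if chrom != self.chrom or not (self.start <= pos - 1 < self.end):
                raise ValidationError(
                    f"cluster {self.id}: site {s} at {chrom}:{pos} outside span"
                )


@dataclass
class SitePositionTable:
    """Genomic location of each heterozygous site index (1-based positions)."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        prev: Optional[tuple[str, int]] = None
        for chrom, pos in self.entries:
            if prev is not None and chrom == prev[0] and pos <= prev[1]:
                raise ValidationError("site positions must be genome-ordered and unique")
            prev = (chrom, pos)

    def __len__(self) -> int:
        return len(self.entries)

    def locate(self, site: int) -> tuple[str, int]:
        """Return (chrom, 1-based pos) of a 1-based site index."""
        return self.entries[site - 1]

    def position(self, site: int) -> int:
        return self.entries[site - 1][1]


@dataclass
class GenotypePanel:
    """Population genotypes over the target's heterozygous sites.

    ``genotypes`` is individuals x sites with values in {0, 1, 2, MISSING};
    row ``target_index`` is the single-individual-haplotyping target.
    """

    site_positions: list[tuple[str, int]]
    genotypes: np.ndarray
    target_index: int = 0
    individual_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotype matrix must be 2-D")
        if self.genotypes.shape[1] != len(self.site_positions):
            raise ValidationError(
                f"{self.genotypes.shape[1]} genotype columns but "
                f"{len(self.site_positions)} site positions"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotypes must be 0/1/2/missing")
        if not 0 <= self.target_index < self.genotypes.shape[0]:
            raise ValidationError("target_index out of range")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def target_genotypes(self) -> np.ndarray:
        return self.genotypes[self.target_index]

    @property
    def positions(self) -> SitePositionTable:
        return SitePositionTable(list(self.site_positions))


@dataclass
class HaplotypeBlock:
    """A contiguous phased region: two complementary binary haplotypes."""

    sites: Sequence[int]
    hap1: Sequence[int]
    hap2: Sequence[int]
    id: Optional[str] = None

    def __post_init__(self) -> None:
        self.sites = _as_int_array(self.sites, "sites")
        self.hap1 = _as_int_array(self.hap1, "hap1")
        self.hap2 = _as_int_array(self.hap2, "hap2")
        if not (len(self.sites) == len(self.hap1) == len(self.hap2)):
            raise ValidationError("sites/hap1/hap2 length mismatch")
        if np.any(np.diff(self.sites) <= 0):
            raise ValidationError("block sites must be strictly increasing")
        if not np.all(self.hap1 + self.hap2 == 1):
            raise ValidationError(
                "hap2 must be the complement of hap1 (sites are heterozygous)"
            )

    def __len__(self) -> int:
        return len(self.sites)

    def allele(self, site: int, hap: int) -> int:
        idx = int(np.searchsorted(self.sites, site))
        if idx >= len(self.sites) or self.sites[idx] != site:
            raise KeyError(f"site {site} not phased in this block")
        return int(self.hap1[idx] if hap == 0 else self.hap2[idx])


@dataclass
class TrioTruth:
    """Trio-determined haplotypes with per-site determined flags.

    Sites the trio could not resolve carry ``determined == False`` and are
    excluded from chimerity labeling and all assembly accuracy measures.
    """

    sites: Sequence[int]
    hap1: Sequence[int]
    hap2: Sequence[int]
    determined: Sequence[bool]

    def __post_init__(self) -> None:
        self.sites = _as_int_array(self.sites, "sites")
        self.hap1 = _as_int_array(self.hap1, "hap1")
        self.hap2 = _as_int_array(self.hap2, "hap2")
        self.determined = np.asarray(list(self.determined), dtype=bool)
        n = len(self.sites)
        if not (len(self.hap1) == len(self.hap2) == len(self.determined) == n):
            raise ValidationError("truth arrays must have equal length")
        if np.any(np.diff(self.sites) <= 0):
            raise ValidationError("truth sites must be strictly increasing")
        det = self.determined
        if not np.all(self.hap1[det] + self.hap2[det] == 1):
            raise ValidationError("determined truth haplotypes must be complementary")
        self._index = {int(s): i for i, s in enumerate(self.sites)}

    def is_determined(self, site: int) -> bool:
        i = self._index.get(site)
        return i is not None and bool(self.determined[i])

    def alleles(self, site: int) -> tuple[int, int]:
        i = self._index[site]
        return int(self.hap1[i]), int(self.hap2[i])

    @classmethod
    def from_block(cls, block: HaplotypeBlock) -> "TrioTruth":
        return cls(
            sites=block.sites,
            hap1=block.hap1,
            hap2=block.hap2,
            determined=[True] * len(block),
        )
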