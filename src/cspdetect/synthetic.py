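"""Synthetic dilution-sequencing data with known truth.

The generator emulates the full upstream of the pipeline: a population
genotype panel with limited haplotype diversity (founder-mosaic model),
a diploid target, long DNA fragments distributed at random into
aliquots, transitive merging of physically overlapping same-aliquot
fragments into read clusters (the mechanism that creates chimeras),
per-site read counts, and sequencing error.  Ground truth — the target
haplotype pair, per-fragment provenance and per-cluster chimera flags —
is returned alongside, so chimera detectors and assemblers can be
evaluated without any external data.

Defaults mirror the dilution-sequencing studies the pipeline targets: a
61-genotype panel including the target, and two dataset-like presets
that differ in aliquot count (196 vs 32), fragment length and error
rate; fewer aliquots and longer fragments raise the chimera rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .cluster_filters import cluster_to_fragment
from .truth_labels import TruthParams, label_fragments
from .types import (
    GenotypePanel,
    HaplotypeBlock,
    ReadCluster,
    SitePositionTable,
    SnpFragment,
    TrioTruth,
    ValidationError,
)


@dataclass
class SimParams:
    """Generator knobs; defaults give a small but realistic instance."""

    n_sites: int = 300          # heterozygous sites retained for the target
    site_spacing: int = 1000    # mean bases between heterozygous sites
    n_founders: int = 6         # founder haplotypes (limited diversity)
    n_individuals: int = 61     # panel size, target included
    recomb_per_site: float = 0.01  # founder-mosaic switch probability
    n_aliquots: int = 32
    n_fragments: int = 60       # long DNA fragments across all aliquots
    frag_len_mean: float = 40_000.0
    frag_len_sd: float = 10_000.0
    coverage_per_site: float = 2.5  # mean reads at a read-covered site
    site_dropout: float = 0.5   # P(a spanned site gets no read from a fragment)
    seq_error: float = 0.02     # per-read allele flip probability
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_sites": self.n_sites,
            "site_spacing": self.site_spacing,
            "n_founders": self.n_founders,
            "n_individuals": self.n_individuals,
            "n_aliquots": self.n_aliquots,
            "n_fragments": self.n_fragments,
            "frag_len_mean": self.frag_len_mean,
            "frag_len_sd": self.frag_len_sd,
            "coverage_per_site": self.coverage_per_site,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        for name, value in (
            ("recomb_per_site", self.recomb_per_site),
            ("seq_error", self.seq_error),
            ("site_dropout", self.site_dropout),
        ):
            if not 0.0 <= value < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")


PRESETS: dict[str, dict] = {
    # tiny: seconds-scale fixture for tests
    "tiny": dict(n_sites=60, n_fragments=20, n_aliquots=8, n_individuals=30,
                 frag_len_mean=15_000.0, frag_len_sd=4_000.0,
                 coverage_per_site=3.0, site_dropout=0.3),
    "default": dict(),
    # many aliquots, shorter fragments, sparse low-error reads: few chimeras
    "kaper-like": dict(n_aliquots=196, n_fragments=150, frag_len_mean=25_000.0,
                       frag_len_sd=6_000.0, seq_error=0.012,
                       coverage_per_site=1.7, site_dropout=0.4),
    # few aliquots, longer fragments, higher error: more chimeras
    "duitama-like": dict(n_aliquots=32, n_fragments=60, frag_len_mean=40_000.0,
                         frag_len_sd=10_000.0, seq_error=0.04,
                         coverage_per_site=2.9, site_dropout=0.55),
}


def preset_params(name: str, seed: int = 0, **overrides) -> SimParams:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimParams(seed=seed, **kwargs)


@dataclass
class FragmentProvenance:
    """Where a simulated long DNA fragment came from."""

    fragment_index: int
    homolog: int            # 0 or 1
    aliquot: int
    start: int              # 0-based half-open genomic span
    end: int


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    target_block: HaplotypeBlock
    cluster_is_cf: dict[str, bool] = field(default_factory=dict)
    provenance: dict[str, list[FragmentProvenance]] = field(default_factory=dict)

    def as_trio_truth(self, determined_fraction: float = 1.0,
                      rng: Optional[np.random.Generator] = None) -> TrioTruth:
        """Truth with an optional fraction of sites hidden (trio gaps)."""
        block = self.target_block
        n = len(block)
        determined = np.ones(n, dtype=bool)
        if determined_fraction < 1.0:
            if rng is None:
                rng = np.random.default_rng(0)
            determined = rng.random(n) < determined_fraction
        return TrioTruth(
            sites=block.sites, hap1=block.hap1, hap2=block.hap2, determined=determined
        )


def simulate_population(
    params: SimParams,
) -> tuple[GenotypePanel, HaplotypeBlock]:
    """Founder-mosaic population panel plus the target's true haplotypes.

    Founders are uniform binary haplotypes; every individual is a pair of
    independent founder mosaics (switching founder with probability
    ``recomb_per_site`` between adjacent sites).  Only sites heterozygous
    in the target are retained and re-indexed from 1.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])

    n_raw = params.n_sites * 3  # oversample; ~half the sites are het in the target
    founders = rng.integers(0, 2, size=(params.n_founders, n_raw))
    gaps = rng.integers(1, 2 * params.site_spacing, size=n_raw)
    positions_all = np.cumsum(gaps)

    def mosaic() -> np.ndarray:
        choice = np.zeros(n_raw, dtype=np.int64)
        choice[0] = rng.integers(params.n_founders)
        switches = rng.random(n_raw - 1) < params.recomb_per_site
        new = rng.integers(params.n_founders, size=n_raw - 1)
        for j in range(1, n_raw):
            choice[j] = new[j - 1] if switches[j - 1] else choice[j - 1]
        return founders[choice, np.arange(n_raw)]

    haplotypes = np.stack(
        [mosaic() for _ in range(2 * params.n_individuals)]
    ).reshape(params.n_individuals, 2, n_raw)
    genotypes = haplotypes.sum(axis=1)

    target = 0
    het = genotypes[target] == 1
    if het.sum() < 2:
        raise ValidationError(
            "target has fewer than 2 heterozygous sites; increase n_sites or "
            "n_founders, or change the seed"
        )
    keep = np.nonzero(het)[0][: params.n_sites]
    panel = GenotypePanel(
        site_positions=[("chr1", int(p)) for p in positions_all[keep]],
        genotypes=genotypes[:, keep],
        target_index=target,
        individual_ids=[f"ind{i}" for i in range(params.n_individuals)],
    )
    truth = HaplotypeBlock(
        sites=np.arange(1, len(keep) + 1),
        hap1=haplotypes[target, 0, keep],
        hap2=haplotypes[target, 1, keep],
    )
    return panel, truth


def simulate_dilution(
    params: SimParams,
    truth: HaplotypeBlock,
    positions: SitePositionTable,
) -> tuple[list[ReadCluster], SimTruth]:
    """Aliquoted long fragments, merged clusters, read counts, chimera flags.

    Fragments land uniformly on the genome with truncated-normal lengths
    and a fair homolog choice; same-aliquot fragments whose spans overlap
    merge transitively into one cluster.  Short-read coverage is sparse:
    a fragment leaves no read at a spanned site with probability
    ``site_dropout`` and otherwise 1 + Poisson(coverage_per_site - 1)
    reads; each read carries its homolog's allele, flipped with
    probability ``seq_error``.  A cluster is flagged chimeric iff it
    merged fragments from both homologs.
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    genome_len = int(positions.position(len(positions)) + params.site_spacing)
    site_pos = np.asarray([positions.position(s) for s in truth.sites])

    frags: list[FragmentProvenance] = []
    for i in range(params.n_fragments):
        length = 0
        while length < 1:
            length = int(rng.normal(params.frag_len_mean, params.frag_len_sd))
        start = int(rng.integers(0, max(genome_len - length, 1)))
        frags.append(
            FragmentProvenance(
                fragment_index=i,
                homolog=int(rng.integers(2)),
                aliquot=int(rng.integers(params.n_aliquots)),
                start=start,
                end=start + length,
            )
        )

    clusters: list[ReadCluster] = []
    sim_truth = SimTruth(target_block=truth)
    read_rng = np.random.default_rng(ss.spawn(3)[2])
    by_aliquot: dict[int, list[FragmentProvenance]] = {}
    for fp in frags:
        by_aliquot.setdefault(fp.aliquot, []).append(fp)

    for aliquot in sorted(by_aliquot):
        members = sorted(by_aliquot[aliquot], key=lambda f: (f.start, f.end))
        merged: list[list[FragmentProvenance]] = []
        for fp in members:
            if merged and fp.start < max(m.end for m in merged[-1]):
                merged[-1].append(fp)
            else:
                merged.append([fp])
        for ci, group in enumerate(merged):
            start = min(f.start for f in group)
            end = max(f.end for f in group)
            counts: dict[int, list[int]] = {}
            for fp in group:
                covered = np.nonzero(
                    (site_pos - 1 >= fp.start) & (site_pos - 1 < fp.end)
                )[0]
                hap = truth.hap1 if fp.homolog == 0 else truth.hap2
                extra = max(params.coverage_per_site - 1.0, 0.0)
                for j in covered:
                    if read_rng.random() < params.site_dropout:
                        continue
                    n_reads = 1 + int(read_rng.poisson(extra))
                    flips = int(read_rng.binomial(n_reads, params.seq_error))
                    allele = int(hap[j])
                    c = counts.setdefault(int(truth.sites[j]), [0, 0])
                    c[allele] += n_reads - flips
                    c[1 - allele] += flips
            cid = f"a{aliquot}c{ci}"
            clusters.append(
                ReadCluster(
                    id=cid,
                    aliquot=f"a{aliquot}",
                    chrom="chr1",
                    start=start,
                    end=end,
                    site_counts=[
                        (s, counts[s][0], counts[s][1]) for s in sorted(counts)
                    ],
                )
            )
            sim_truth.cluster_is_cf[cid] = len({f.homolog for f in group}) > 1
            sim_truth.provenance[cid] = group
    return clusters, sim_truth


def simulate(params: SimParams) -> tuple[GenotypePanel, list[ReadCluster], SimTruth]:
    """Run both stages; deterministic for a fixed seed."""
    panel, truth = simulate_population(params)
    clusters, sim_truth = simulate_dilution(params, truth, panel.positions)
    return panel, clusters, sim_truth


def clusters_to_fragments(clusters: list[ReadCluster]) -> list[SnpFragment]:
    """Majority-decision fragments of all clusters with >= 1 decided site."""
    out = []
    for cl in clusters:
        frag = cluster_to_fragment(cl)
        if frag is not None:
            out.append(frag)
    return out


def make_fixture(params: SimParams, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write every canonical file; returns the path map.

    Files: ``sites.tsv``, ``panel.tsv``, ``clusters.tsv``, ``fragments.txt``
    (raw majority-decision fragments), ``truth.tsv`` (target haplotypes)
    and ``labels.tsv`` (fragment chimerity labels plus the provenance
    chimera flag of the source cluster).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, clusters, sim_truth = simulate(params)
    positions = panel.positions
    fragments = clusters_to_fragments(clusters)
    trio = sim_truth.as_trio_truth()
    labels = label_fragments(fragments, trio, TruthParams())

    paths = {
        "sites": outdir / "sites.tsv",
        "panel": outdir / "panel.tsv",
        "clusters": outdir / "clusters.tsv",
        "fragments": outdir / "fragments.txt",
        "truth": outdir / "truth.tsv",
        "labels": outdir / "labels.tsv",
    }
    cio.write_panel(panel, paths["sites"], paths["panel"])
    cio.write_clusters(clusters, paths["clusters"])
    cio.write_fragments(fragments, paths["fragments"])
    cio.write_truth(trio, paths["truth"])
    with open(paths["labels"], "w") as fh:
        fh.write("fragment_id\tchimerity\tlabel\tcluster_mixed\n")
        for frag, lab in zip(fragments, labels):
            chim = "NA" if lab.chimerity is None else f"{lab.chimerity:.4f}"
            mixed = sim_truth.cluster_is_cf.get(frag.source_cluster, False)
            fh.write(f"{frag.id}\t{chim}\t{lab.label.value}\t{int(mixed)}\n")
    return paths
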