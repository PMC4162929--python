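"""Readers and writers for the canonical plain-text dialects.

Dialects (all whitespace/tab separated):

* fragment file — ``id n_sites site_1 allele_1 ... site_n allele_n``
* cluster file  — ``cluster_id aliquot chrom start end site:c0:c1 ...``
* site table    — ``index chrom pos``
* genotype matrix — header row ``id site_1 ... site_n``; one row per
  individual: ``individual_id g_1 ... g_n`` with g in {0,1,2,.}
* truth file    — ``site hap1_allele hap2_allele`` with ``.`` for
  sites the trio could not determine
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .types import (
    MISSING,
    GenotypePanel,
    HaplotypeBlock,
    ReadCluster,
    SitePositionTable,
    SnpFragment,
    TrioTruth,
    ValidationError,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A line of an input file does not follow its dialect."""


def _lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_fragments(path: PathLike) -> list[SnpFragment]:
    fragments: list[SnpFragment] = []
    seen: set[str] = set()
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'id n_sites ...'")
        frag_id = tokens[0]
        try:
            n = int(tokens[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad site count {tokens[1]!r}") from exc
        if n < 1:
            raise ParseError(f"{path}:{lineno}: fragment size must be >= 1")
        if len(tokens) != 2 + 2 * n:
            raise ParseError(
                f"{path}:{lineno}: expected {2 * n} site/allele tokens, "
                f"got {len(tokens) - 2}"
            )
        if frag_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate fragment id {frag_id!r}")
        seen.add(frag_id)
        try:
            values = [int(t) for t in tokens[2:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer token") from exc
        try:
            fragments.append(
                SnpFragment(id=frag_id, sites=values[0::2], alleles=values[1::2])
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return fragments


def write_fragments(fragments: list[SnpFragment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            parts = [frag.id, str(frag.size)]
            for s, a in zip(frag.sites, frag.alleles):
                parts.extend((str(int(s)), str(int(a))))
            fh.write(" ".join(parts) + "\n")


def read_clusters(path: PathLike) -> list[ReadCluster]:
    clusters: list[ReadCluster] = []
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) < 5:
            raise ParseError(
                f"{path}:{lineno}: expected 'id aliquot chrom start end ...'"
            )
        cid, aliquot, chrom = tokens[:3]
        try:
            start, end = int(tokens[3]), int(tokens[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
        site_counts = []
        for tok in tokens[5:]:
            fields = tok.split(":")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: bad site triplet {tok!r}")
            try:
                site_counts.append((int(fields[0]), int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad site triplet {tok!r}") from exc
        try:
            clusters.append(
                ReadCluster(
                    id=cid,
                    aliquot=aliquot,
                    chrom=chrom,
                    start=start,
                    end=end,
                    site_counts=site_counts,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return clusters


def write_clusters(clusters: list[ReadCluster], path: PathLike) -> None:
    with open(path, "w") as fh:
        for cl in clusters:
            parts = [cl.id, cl.aliquot, cl.chrom, str(cl.start), str(cl.end)]
            parts.extend(f"{s}:{c0}:{c1}" for s, c0, c1 in cl.site_counts)
            fh.write("\t".join(parts) + "\n")


def read_sites(path: PathLike) -> SitePositionTable:
    entries: list[tuple[str, int]] = []
    expected = 1
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'index chrom pos'")
        try:
            idx, pos = int(tokens[0]), int(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad index/position") from exc
        if idx != expected:
            raise ParseError(
                f"{path}:{lineno}: site indices must be consecutive from 1 "
                f"(got {idx}, expected {expected})"
            )
        expected += 1
        entries.append((tokens[1], pos))
    return SitePositionTable(entries)


def write_sites(positions: SitePositionTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(positions.entries, start=1):
            fh.write(f"{i}\t{chrom}\t{pos}\n")


def read_panel(
    path_sites: PathLike, path_matrix: PathLike, target: str | int = 0
) -> GenotypePanel:
    """Read a genotype panel; ``target`` names or indexes the SIH individual."""
    positions = read_sites(path_sites)
    ids: list[str] = []
    rows: list[list[int]] = []
    header_seen = False
    for lineno, line in _lines(path_matrix):
        tokens = line.split()
        if not header_seen:
            header_seen = True
            if len(tokens) != len(positions) + 1:
                raise ParseError(
                    f"{path_matrix}:{lineno}: header lists {len(tokens) - 1} "
                    f"sites but site table has {len(positions)}"
                )
            continue
        if len(tokens) != len(positions) + 1:
            raise ParseError(
                f"{path_matrix}:{lineno}: expected {len(positions)} genotype cells"
            )
        ids.append(tokens[0])
        row = []
        for tok in tokens[1:]:
            if tok == ".":
                row.append(MISSING)
            elif tok in ("0", "1", "2"):
                row.append(int(tok))
            else:
                raise ParseError(f"{path_matrix}:{lineno}: bad genotype {tok!r}")
        rows.append(row)
    if not rows:
        raise ParseError(f"{path_matrix}: no individuals")
    if isinstance(target, str) and not target.lstrip("-").isdigit():
        try:
            target_index = ids.index(target)
        except ValueError as exc:
            raise ParseError(f"target individual {target!r} not in matrix") from exc
    else:
        target_index = int(target)
    return GenotypePanel(
        site_positions=list(positions.entries),
        genotypes=np.asarray(rows, dtype=np.int64),
        target_index=target_index,
        individual_ids=ids,
    )


def write_panel(panel: GenotypePanel, path_sites: PathLike, path_matrix: PathLike) -> None:
    write_sites(panel.positions, path_sites)
    ids = panel.individual_ids or [f"ind{i}" for i in range(panel.n_individuals)]
    with open(path_matrix, "w") as fh:
        fh.write("id\t" + "\t".join(str(i + 1) for i in range(panel.n_sites)) + "\n")
        for name, row in zip(ids, panel.genotypes):
            cells = ["." if g == MISSING else str(int(g)) for g in row]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


def read_truth(path: PathLike) -> TrioTruth:
    sites: list[int] = []
    hap1: list[int] = []
    hap2: list[int] = []
    determined: list[bool] = []
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'site hap1 hap2'")
        try:
            sites.append(int(tokens[0]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad site index") from exc
        if tokens[1] == "." or tokens[2] == ".":
            hap1.append(0)
            hap2.append(1)
            determined.append(False)
        else:
            if tokens[1] not in "01" or tokens[2] not in "01":
                raise ParseError(f"{path}:{lineno}: alleles must be 0/1/.")
            hap1.append(int(tokens[1]))
            hap2.append(int(tokens[2]))
            determined.append(True)
    return TrioTruth(sites=sites, hap1=hap1, hap2=hap2, determined=determined)


def write_truth(truth: TrioTruth, path: PathLike) -> None:
    with open(path, "w") as fh:
        for s, a1, a2, det in zip(truth.sites, truth.hap1, truth.hap2, truth.determined):
            if det:
                fh.write(f"{s}\t{int(a1)}\t{int(a2)}\n")
            else:
                fh.write(f"{s}\t.\t.\n")


def truth_blocks(truth: TrioTruth) -> list[HaplotypeBlock]:
    """Maximal runs of determined sites, as haplotype blocks."""
    blocks: list[HaplotypeBlock] = []
    run: list[int] = []
    for i, det in enumerate(truth.determined):
        if det:
            run.append(i)
        elif run:
            blocks.append(_block_from_run(truth, run))
            run = []
    if run:
        blocks.append(_block_from_run(truth, run))
    return blocks


def _block_from_run(truth: TrioTruth, run: list[int]) -> HaplotypeBlock:
    return HaplotypeBlock(
        sites=truth.sites[run],
        hap1=truth.hap1[run],
        hap2=truth.hap2[run],
    )


def read_blocks(path: PathLike) -> list[HaplotypeBlock]:
    """Read assembled blocks from TSV ``block_id site hap1 hap2``."""
    grouped: dict[str, list[tuple[int, int, int]]] = {}
    order: list[str] = []
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) != 4:
            raise ParseError(f"{path}:{lineno}: expected 'block_id site hap1 hap2'")
        bid = tokens[0]
        try:
            entry = (int(tokens[1]), int(tokens[2]), int(tokens[3]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad block row") from exc
        if bid not in grouped:
            grouped[bid] = []
            order.append(bid)
        grouped[bid].append(entry)
    blocks = []
    for bid in order:
        rows = sorted(grouped[bid])
        blocks.append(
            HaplotypeBlock(
                id=bid,
                sites=[r[0] for r in rows],
                hap1=[r[1] for r in rows],
                hap2=[r[2] for r in rows],
            )
        )
    return blocks


def write_blocks(blocks: list[HaplotypeBlock], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, block in enumerate(blocks):
            bid = block.id or f"block{i}"
            for s, a1, a2 in zip(block.sites, block.hap1, block.hap2):
                fh.write(f"{bid}\t{int(s)}\t{int(a1)}\t{int(a2)}\n")
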