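"""Candidate haplotype pairs for small windows of heterozygous sites.

Statistical phasing exploits the limited diversity of local haplotypes in
a population.  For the short windows used by chimeric-fragment scoring
(<= 10 sites) a plain haplotype-frequency EM over all 2^|S| haplotypes is
adequate: it estimates population haplotype frequencies by maximum
likelihood under Hardy-Weinberg random pairing, then converts them into
posterior probabilities of the target individual's unordered haplotype
pairs.  Parsed output of an external phaser can be substituted through
:class:`FixedPairsBackend`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .types import MISSING, GenotypePanel, ValidationError

MAX_WINDOW = 10  # 2^10 haplotypes is the enumeration bound
PAIR_PROB_FLOOR = 1e-6


class PhasingError(RuntimeError):
    """Phasing could not produce candidate pairs for a window."""


@dataclass
class HaplotypeFrequencySet:
    """Estimated population haplotype frequencies for one window.

    ``freq`` maps haplotype (tuple of 0/1 of window length) to frequency;
    only haplotypes with nonzero mass are stored.
    """

    window_sites: tuple[int, ...]
    freq: dict[tuple[int, ...], float]
    log_likelihood: float = float("nan")
    n_iter: int = 0
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if self.freq and not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"haplotype frequencies sum to {total}, not 1")


@dataclass
class CandidatePairSet:
    """Candidate haplotype pairs with probabilities for one window."""

    window_sites: tuple[int, ...]
    pairs: list[tuple[tuple[int, ...], tuple[int, ...], float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        w = len(self.window_sites)
        for hap_a, hap_b, prob in self.pairs:
            if len(hap_a) != w or len(hap_b) != w:
                raise ValidationError("pair haplotype length != window size")
            if prob < 0:
                raise ValidationError("pair probability must be >= 0")
        total = sum(p for _, _, p in self.pairs)
        if self.pairs and not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"pair probabilities sum to {total}, not 1")

    def check_genotype(self, genotype: Sequence[int]) -> None:
        for hap_a, hap_b, _ in self.pairs:
            if any(a + b != g for a, b, g in zip(hap_a, hap_b, genotype)):
                raise ValidationError("candidate pair inconsistent with genotype")


def _enumerate_haplotypes(n_sites: int) -> np.ndarray:
    """All 2^n binary haplotypes as an array, row h = bits of h (MSB first)."""
    n = 1 << n_sites
    out = np.zeros((n, n_sites), dtype=np.int64)
    for j in range(n_sites):
        out[:, j] = (np.arange(n) >> (n_sites - 1 - j)) & 1
    return out


def em_haplotype_frequencies(
    panel: GenotypePanel,
    window_sites: Sequence[int],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> HaplotypeFrequencySet:
    """Estimate window haplotype frequencies by EM over the panel.

    Individuals with missing genotypes at a window site are marginalized
    over that site.  The observed-data log-likelihood is non-decreasing
    across iterations; iteration stops when the improvement drops below
    ``tol`` or after ``max_iter`` rounds.
    """
    window_sites = tuple(int(s) for s in window_sites)
    w = len(window_sites)
    if w == 0:
        raise PhasingError("empty window")
    if w > MAX_WINDOW:
        raise PhasingError(
            f"window of {w} sites exceeds the enumeration bound of {MAX_WINDOW}; "
            "use sliding windows"
        )
    if panel.n_individuals < 2:
        raise PhasingError("panel must contain at least 2 individuals")
    cols = np.asarray(window_sites) - 1
    G = panel.genotypes[:, cols]
    n_ind = G.shape[0]
    haps = _enumerate_haplotypes(w)
    n_hap = haps.shape[0]

    # Per-individual list of compatible ordered haplotype pairs (ia, ib):
    # a site with genotype g constrains a+b == g unless g is missing.
    ia_list: list[int] = []
    ib_list: list[int] = []
    owner: list[int] = []
    # compat[i, h]: haplotype h matches individual i at every homozygous site
    sums = haps[:, None, :] + haps[None, :, :]  # n_hap x n_hap x w
    for i in range(n_ind):
        g = G[i]
        ok = np.ones((n_hap, n_hap), dtype=bool)
        for j in range(w):
            if g[j] != MISSING:
                ok &= sums[:, :, j] == g[j]
        a_idx, b_idx = np.nonzero(ok)
        if len(a_idx) == 0:
            raise PhasingError(f"individual {i} has no compatible haplotype pair")
        ia_list.extend(a_idx.tolist())
        ib_list.extend(b_idx.tolist())
        owner.extend([i] * len(a_idx))
    ia = np.asarray(ia_list)
    ib = np.asarray(ib_list)
    own = np.asarray(owner)

    # uniform init over haplotypes compatible with >= 1 individual
    support = np.zeros(n_hap, dtype=bool)
    support[ia] = True
    support[ib] = True
    freq = support / support.sum()

    last_ll = -np.inf
    n_iter = 0
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        weight = freq[ia] * freq[ib]
        norm = np.zeros(n_ind)
        np.add.at(norm, own, weight)
        if np.any(norm <= 0):
            raise PhasingError("EM lost all mass for an individual")
        ll = float(np.sum(np.log(norm)))
        history.append(ll)
        post = weight / norm[own]
        counts = np.zeros(n_hap)
        np.add.at(counts, ia, post)
        np.add.at(counts, ib, post)
        freq = counts / (2.0 * n_ind)
        if ll - last_ll < tol and n_iter > 1:
            last_ll = ll
            break
        last_ll = ll

    freq_map = {
        tuple(int(x) for x in haps[h]): float(freq[h])
        for h in range(n_hap)
        if freq[h] > 0
    }
    return HaplotypeFrequencySet(
        window_sites=window_sites,
        freq=freq_map,
        log_likelihood=last_ll,
        n_iter=n_iter,
        ll_history=history,
    )


def candidate_pairs(
    freqs: HaplotypeFrequencySet, target_genotype: Sequence[int]
) -> CandidatePairSet:
    """Posterior unordered-pair probabilities for the target individual.

    P({a, b}) is proportional to (2 - delta_ab) freq(a) freq(b), restricted
    to pairs consistent with the target's genotype; pairs below
    ``PAIR_PROB_FLOOR`` are pruned and the rest renormalized.
    """
    g = [int(x) for x in target_genotype]
    if any(x == MISSING for x in g):
        raise PhasingError("target genotype has missing entries in the window")
    if len(g) != len(freqs.window_sites):
        raise PhasingError("target genotype length != window size")
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    raw: list[tuple[tuple[int, ...], tuple[int, ...], float]] = []
    for h in sorted(freqs.freq):
        # the genotype determines h's partner uniquely
        partner = tuple(z - x for x, z in zip(h, g))
        if any(y not in (0, 1) for y in partner):
            continue
        a, b = min(h, partner), max(h, partner)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        mult = 1.0 if a == b else 2.0
        p = mult * freqs.freq.get(a, 0.0) * freqs.freq.get(b, 0.0)
        raw.append((a, b, p))
    total = sum(p for _, _, p in raw)
    if total <= 0 and raw:
        # degenerate: one member of a consistent pair carries all the mass
        # (its forced complement was never seen); weight by marginal mass
        raw = [
            (a, b, freqs.freq.get(a, 0.0) + freqs.freq.get(b, 0.0))
            for a, b, _ in raw
        ]
        total = sum(p for _, _, p in raw)
    if total <= 0:
        raise PhasingError("phasing mass zero: no consistent pair has positive mass")
    kept = [(a, b, p / total) for a, b, p in raw if p / total >= PAIR_PROB_FLOOR]
    if not kept:  # floor removed everything; keep the unpruned distribution
        kept = [(a, b, p / total) for a, b, p in raw]
    total = sum(p for _, _, p in kept)
    pairs = [(a, b, p / total) for a, b, p in kept]
    return CandidatePairSet(window_sites=freqs.window_sites, pairs=pairs)


def parse_phase_pairs(path: Union[str, Path]) -> list[CandidatePairSet]:
    """Parse external-phaser candidate pairs.

    Dialect: a ``# window: s1,s2,...`` header line, then one
    ``hapstring hapstring prob`` line per candidate pair; haplotype
    strings are over {0,1}.  Probabilities are renormalized per window.
    """
    sets: list[CandidatePairSet] = []
    window: tuple[int, ...] | None = None
    pairs: list[tuple[tuple[int, ...], tuple[int, ...], float]] = []

    def flush() -> None:
        nonlocal pairs, window
        if window is None:
            return
        if not pairs:
            raise ValueError(f"{path}: window {window} has no candidate pairs")
        total = sum(p for _, _, p in pairs)
        if total <= 0:
            raise ValueError(f"{path}: window {window} has zero total probability")
        sets.append(
            CandidatePairSet(
                window_sites=window,
                pairs=[(a, b, p / total) for a, b, p in pairs],
            )
        )
        pairs = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if not body.lower().startswith("window:"):
                    continue
                flush()
                try:
                    window = tuple(
                        int(t) for t in body.split(":", 1)[1].split(",") if t.strip()
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad window header") from exc
                continue
            if window is None:
                raise ValueError(f"{path}:{lineno}: pair line before window header")
            tokens = line.split()
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'hapA hapB prob'")
            for hap in tokens[:2]:
                if len(hap) != len(window) or any(c not in "01" for c in hap):
                    raise ValueError(
                        f"{path}:{lineno}: haplotype {hap!r} not binary of "
                        f"window length {len(window)}"
                    )
            pairs.append(
                (
                    tuple(int(c) for c in tokens[0]),
                    tuple(int(c) for c in tokens[1]),
                    float(tokens[2]),
                )
            )
    flush()
    return sets


class EmPhasingBackend:
    """Produce candidate pairs for arbitrary windows from a genotype panel.

    Results are cached per window-site tuple: many fragments share sliding
    windows, and the EM result for a window is deterministic.
    """

    def __init__(self, panel: GenotypePanel, max_iter: int = 500, tol: float = 1e-8):
        self.panel = panel
        self.max_iter = max_iter
        self.tol = tol
        self._cache: dict[tuple[int, ...], CandidatePairSet] = {}

    def pairs_for(self, window_sites: Sequence[int]) -> CandidatePairSet:
        key = tuple(int(s) for s in window_sites)
        if key not in self._cache:
            freqs = em_haplotype_frequencies(
                self.panel, key, max_iter=self.max_iter, tol=self.tol
            )
            cols = np.asarray(key) - 1
            target = self.panel.target_genotypes[cols]
            self._cache[key] = candidate_pairs(freqs, target)
        return self._cache[key]


class FixedPairsBackend:
    """Serve pre-computed candidate pairs (e.g. parsed phaser output)."""

    def __init__(self, pair_sets: list[CandidatePairSet]):
        self._by_window = {ps.window_sites: ps for ps in pair_sets}

    def pairs_for(self, window_sites: Sequence[int]) -> CandidatePairSet:
        key = tuple(int(s) for s in window_sites)
        try:
            return self._by_window[key]
        except KeyError:
            raise PhasingError(f"no candidate pairs available for window {key}")
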