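# Methods

## Model

A SNP fragment `f` covers a strictly increasing set of heterozygous-site
indices `X(f)` with a binary allele at each. Given candidate haplotype
pairs `h⁽ᵖ⁾ = (h⁽ᵖ'ᴬ⁾, h⁽ᵖ'ᴮ⁾)` with probabilities `P(h⁽ᵖ⁾)` for the
window containing `X(f)`, the fragment's natural-origin probability
mixes over pairs and a fair haplotype choice, and its chimeric-origin
probability additionally mixes over the single switch point `k` and the
two left/right haplotype orderings:

    P_n(f) = Σ_p P(h⁽ᵖ⁾) · ½ [P(f|h⁽ᵖ'ᴬ⁾) + P(f|h⁽ᵖ'ᴮ⁾)]
    P_c(f) = Σ_p P(h⁽ᵖ⁾) · ½ Σ_{k=1}^{L−1} [P(f≤k|h⁽ᵖ'ᴬ⁾)P(f>k|h⁽ᵖ'ᴮ⁾)
                                            + P(f≤k|h⁽ᵖ'ᴮ⁾)P(f>k|h⁽ᵖ'ᴬ⁾)]
    CSP(f) = ln P_c(f) − ln P_n(f)

The emission `P(f|h)` multiplies `(1−α)` per matching covered site and
`α` per mismatch; `α` absorbs both sequencing error and phasing error.
A chimera switching origin `m` covered sites from the fragment end then
scores ≈ `−m·ln(α/(1−α))`, i.e. 4.6 and 9.2 at the defaults for m = 1, 2
— these peaks anchor both the CF-candidate threshold and the truth
labeling below.

Three structural choices deserve note, since each has a defensible
alternative:

* **The sum over k is unnormalized** (no 1/(L−1) switch-point prior).
  A uniform prior would shift the peaks down by `ln(L−1)` and decouple
  them from `−m·ln(α/(1−α))`; the unnormalized form keeps the score an
  "error-equivalents" count, which is what makes the fixed candidate
  threshold of 7 meaningful across fragment sizes.
* **Sliding windows combine by maximum.** For fragments longer than
  W = 5 covered sites, CSP is the max over all windows of W consecutive
  covered sites (windows advance one covered site at a time; physical
  gaps are irrelevant). The max is what places a true switch two covered
  sites from some window's end and reproduces the 9.2 signature; mean-
  or sum-combination would dilute it with the many windows that do not
  straddle the switch.
* **A single switch only.** Multi-switch chimeras (three or more source
  fragments in one cluster) are rare under dilution conditions, and the
  single-switch form approximately marginalizes over them.

All probability arithmetic is done in log space with log-sum-exp;
fragments of hundreds of sites underflow linear space at α = 0.01.
Fragments of size 1 admit no split and receive a missing score (never a
CF candidate); a phasing failure in one window skips that window with a
warning, and a fragment whose windows all fail gets a missing score.

## Candidate pairs: haplotype-frequency EM

CSP needs, per window `S`, candidate haplotype pairs with probabilities
for the target individual. Windows are at most W sites, so a plain EM
over all `2^|S|` haplotypes is exact and fast: under Hardy-Weinberg
random pairing, the E-step distributes each panel individual over its
genotype-compatible ordered haplotype pairs (sites with missing
genotypes are marginalized), and the M-step re-estimates frequencies
from expected counts. Initialization is uniform over haplotypes
compatible with at least one individual — deterministic, so the whole
pipeline is seed-free given its inputs. Iteration stops when the
observed-data log-likelihood improves by less than `tol` (default 1e-8,
max 500 iterations); the likelihood is asserted non-decreasing.

Pair probabilities for the target are
`P({a,b}) ∝ (2−δ_ab)·freq(a)·freq(b)` restricted to pairs consistent
with the target's genotype, normalized, pruned below 1e-6 and
renormalized. Renormalization after pruning is this package's choice;
external phasers do not document theirs. In the degenerate case where a
consistent pair exists but its product mass is zero (one member of the
forced pair was never seen in the panel), pairs are weighted by marginal
mass instead; only a genotype realizable by no pair at all is an error.
When the target is part of the panel — as in the datasets this pipeline
models, where the target's own genotype is included and only its parents
are excluded — the degenerate case cannot arise for the target's own
windows.

Parsed output of an external phaser (blocks of `hapA hapB prob` lines
per window) can replace the EM through `FixedPairsBackend`; per-window
results are cached by site tuple either way, since overlapping fragments
share sliding windows.

## Preprocessing and baseline detectors

A site in a read cluster shows a *heterozygous call* when its minority
read count exceeds half the aliquot's average coverage or half the
majority count. Clusters are split at het-call sites (the site itself is
dropped from both daughters — its allele is unreliable by construction),
then any piece whose physical span exceeds the length cap (30 kb or
45 kb depending on protocol) is cut between covered sites into the
minimal number of balanced site groups whose tight spans fit the cap.
Daughters of length-splitting span exactly their covered sites; het-call
splitting keeps the cluster's outer boundaries and cuts at the dropped
site. The aliquot's average coverage, when not supplied, is the mean
over the aliquot's clusters of total reads per covered site.

Clusters convert to SNP fragments by per-site majority; tied and
zero-read sites are dropped (ambiguous evidence should not fabricate an
allele), and empty conversions are discarded.

The baseline chimera scores are the physical cluster length and three
minority-allele summaries: total (summed minority reads), maximum and
average per-site minority rate (zero-read sites excluded from the
rates).

## Truth labeling by trio chimerity

With trio-determined haplotypes `(h¹, h²)` the chimerity of a fragment
is `ln C − ln N` with `N = max_d P(f|hᵈ)` and `C` the max over split
points and orderings of `P(f≤k|hᵈ)·P(f>k|hᵈ')`, `d ≠ d'`, at error term
α₀ = 0.01. Max (not sum) is used in both numerator and denominator: it
yields clean closed forms — a pure fragment scores `ln(α₀/(1−α₀))`, a
perfect single-switch chimera with m minority-side sites scores
`−m·ln(α₀/(1−α₀))` — and matches the threshold's error-count reading.
The label cutoff defaults to `−2·ln(α₀/(1−α₀))` (≈ 9.19): at least two
error-equivalents of support for the switch. Note the sign: the cutoff
printed in the source literature is its negation, which is negative for
α₀ < 0.5 and would label nearly everything chimeric under this score;
both the direction and the cutoff are exposed as configuration. The
comparison carries a 1e-9 tolerance because the boundary case — a
perfect two-site switch — is mathematically *equal* to the cutoff and
float cancellation over long fragments must not flip it. Fragments
covering any trio-undetermined site are excluded from labeling and from
all assembly metrics.

## Assembly, connectivity, recovery

The assembler is deliberately simple: sites sharing a fragment form
connected components; within a component fragments are processed
largest-first among those overlapping the already-voted sites (so
orientation propagates through the component; input order breaks ties),
each fragment takes the orientation agreeing with the running consensus
at more covered sites (ties keep orientation A), and the consensus is
the per-site majority (ties vote allele 0). It is deterministic and, on
conflict-free input, recovers the true haplotypes up to per-block
orientation. It is a stand-in for likelihood-based assemblers, not a
reimplementation of any of them; the confidence machinery is what
matters downstream.

Connectivity at site j₀ is the log-likelihood margin
`L(H) − L(H')` where `H'` swaps the two haplotypes at all block sites
≥ j₀ and `L(H) = Σ_i ln ½[P(fᵢ|h¹)+P(fᵢ|h²)]` over fragments touching
the block ("ratio of marginal log likelihoods" is read as a difference
of logs — the only reading compatible with an additive MC threshold on
a 0–10 scale). Block extraction cuts at every interior site below the
MC threshold, so every emitted block's minimum connectivity meets it.

CF-candidate recovery addresses natural fragments that merely deviate
from population haplotypes (rare variants, real recombination): since
chimeras arise from random co-aliquoting, many candidates stacked over
one region are implausible as chimeras. A candidate is provisionally
recovered iff every site it covers is covered by at least
`recovery_coverage_threshold` (default 3) non-candidate fragments; the
provisional set is assembled together with the non-candidates, and each
recovered fragment is re-checked by chimerity against the inferred
haplotypes (threshold mirrors the truth-labeling default), re-removing
those that still switch. A recovered fragment spanning two assembly
blocks has no defined chimerity and is kept.

## Evaluation measures

* **Pairwise precision**: within each block, a pair of trio-determined
  sites is consistent iff the inferred relative phase matches the true
  relative phase; precision = CP/(CP+IP) over all blocks, undefined
  (reported missing) when no pairs exist.
* **Switch error rate**: per block, each determined site's orientation
  is the truth haplotype matching hap1; the rate is orientation flips
  between adjacent determined sites over all adjacent determined pairs,
  pooled across blocks (a per-block denominator; per-genome junction
  counting would differ only by block-boundary effects).
* **QAN50**: blocks are cut at every switch error; each sub-block's
  physical span (first to last phased site, bases) is scaled by the
  fraction of spanned heterozygous sites it phases; QAN50 is the largest
  value q such that sub-blocks with adjusted span ≥ q hold at least half
  of all phased sites. The span adjustment is the reconstruction of the
  "N50 with adjustments" definition from the fosmid-pool literature.
* **ROC/AUC**: sensitivity and 1−specificity over the score threshold,
  excluded fragments ignored, missing scores ranked below every finite
  score, ties resolved trapezoidally (AUC equals the normalized
  Mann-Whitney U; the implementation delegates to scikit-learn and is
  cross-checked against a quadratic-time oracle in the tests).

## Synthetic data

The simulator emulates the whole upstream of the pipeline with one seed
driving three ordered sub-generators (population, fragment placement,
reads), so each stage is reproducible independently.

* **Population**: `n_founders` uniform binary founder haplotypes;
  each of `n_individuals` (default 61, the target included) is two
  independent founder mosaics switching founders with probability
  `recomb_per_site` between adjacent sites. Only sites heterozygous in
  the target are retained and re-indexed. The founder-mosaic model
  creates the limited local haplotype diversity statistical phasing
  exploits, with one knob, in place of a coalescent simulation.
* **Dilution**: `n_fragments` fragments with truncated-normal lengths
  land uniformly on the genome, each assigned a fair homolog and a
  uniform aliquot. Same-aliquot fragments with overlapping spans merge
  transitively into one cluster; a cluster is truly chimeric iff it
  merged both homologs. Abutting-but-not-overlapping fragments do not
  merge.
* **Reads**: coverage is sparse, as in real dilution data where a
  cluster's short reads leave many spanned SNPs uncovered: a fragment
  leaves no read at a spanned site with probability `site_dropout` and
  otherwise `1 + Poisson(coverage_per_site − 1)` reads, each carrying
  the homolog's allele flipped with probability `seq_error`.

Defaults (300 sites at ~1 kb spacing, 6 founders, 61 individuals, 60
fragments of ~40 kb into 32 aliquots, coverage 2.5 with dropout 0.5,
2% read error) give a small instance with a handful of true chimeras
per run. The two dataset-like presets differ where the modeled
protocols differ: `kaper-like` (196 aliquots, ~25 kb fragments,
coverage 1.7, dropout 0.4, 1.2% error) and `duitama-like` (32 aliquots,
~40 kb fragments, coverage 2.9, dropout 0.55, 4% error). The coverage
and dropout values are chosen so that simulated fragments reproduce the
reported per-cluster statistics of those protocols (mean SNP-fragment
sizes near 9–10 against ~15–23 spanned het sites, mean coverage
1.7/2.9); fragment-length distributions are order-of-magnitude choices,
as no quantitative distributions are published for either protocol.

What the simulator does **not** model: read-level sequences and mapping
artifacts, indels, genotyping error in the panel, non-uniform fragment
placement, cluster-calling heuristics that merge nearby non-overlapping
fragments. Passing tests on this data therefore show the scoring and
assembly machinery behaves as designed under idealized cluster calling;
they do not certify performance numbers on any real protocol, where
cluster boundaries and error structure are harsher.

## Problem sizes and numerical choices in the tests

The stochastic end-to-end checks run the `duitama-like` preset on five
seeds (about 230 fragments pooled) for the detector-comparison and
precision-gain properties, and ten seeds of the default parameters for
the aliquot-count contrast; these sizes keep the full suite under half
a minute while leaving the qualitative contrasts far from their
decision boundaries. Brute-force oracles (linear-space enumeration over
splits, orderings and pairs; a simplex-grid multinomial maximizer;
quadratic-time Mann-Whitney) pin the numerics at 1e-10 relative
tolerance on fragments of size ≤ 8. Degenerate inputs are resolved as:
size-1 fragments score missing; all-zero-read clusters have no
heterozygosity measures; singleton blocks contribute no pairs, switches
or QAN50 mass; ROC requires both classes present.

## Known limitations

* The greedy assembler has no error-correction objective; with dense
  conflicting data its consensus can lock in early mistakes that a
  likelihood-optimizing assembler would avoid. Its precision numbers on
  hard instances understate what MC-gated extraction achieves.
* The EM phasing stand-in ignores linkage beyond the window and cannot
  represent phase uncertainty between windows; real phasers produce
  better-calibrated pair probabilities on real panels.
* CSP windows are capped at 10 sites by the `2^|S|` enumeration; this
  is ample for W = 5 but rules out single-window scoring of very long
  fragments (sliding windows handle them instead).
* Heterozygosity baselines assume the simulator's read model; on data
  with correlated read errors their AUCs would differ.
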