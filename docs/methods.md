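# Methods

This note documents the models, estimators and defaults implemented in
`halopop`, the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## The scientific question

Many fungi are known only as asexual (clonal) lineages, yet may recombine
cryptically. Three genomic signatures distinguish a recombining population of
haploid genomes from a strictly clonal one:

1. **LD decay** — under clonality, linkage disequilibrium between SNP pairs is
   independent of physical distance; under recombination it decays with
   distance.
2. **Gene-tree discordance** — clonal genomes share one genealogy at every
   locus; recombination decouples gene trees, so few internal nodes survive a
   majority-rule consensus.
3. **Mating-machinery integrity** — a structurally intact (if rearranged)
   mating-type locus with pheromone precursors carrying the C-terminal CAAX
   prenylation signal is consistent with a functional sexual cycle.

`halopop` implements all three, plus the clonal-structure analyses (pairwise
SNP distances, clonal clusters, minimum spanning network, PCA) needed to
recognize and collapse near-identical strains first.

## The simulator (`simpop`)

**Model.** N haploid individuals, non-overlapping generations, evolved for G
generations from a monomorphic founder population. Per birth: crossover count
X ~ Poisson(ρ·L) over total genome length L; X = 0 copies one uniform parent,
X > 0 recombines two uniform parents at X uniform breakpoints, each contig
independently phased (contigs are unlinked). Mutations per birth ~
Poisson(μ·L), uniform positions, finite-sites biallelic: the first hit at a
site fixes its ALT allele, later hits toggle the carrier between REF and ALT,
so every segregating site is biallelic by construction. There is no
selection, gene conversion, indel mutation or demographic change.

**Sampling and planted structure.** At the end of the run, lineage founders
are drawn from the final generation; a greedy pass enforces a minimum
pairwise SNP distance between founders (`min_founder_separation`, default
1000) and each founder receives Poisson(`lineage_divergence`) additional
private mutations. Clone copies are a founder's genome plus Poisson(λ)
private mutations. The divergence planting realizes the sampling design being
emulated — strains from deeply isolated lineages (thousands of SNPs apart)
containing clusters of near-identical clones (tens of SNPs apart) — which a
panmictic Wright–Fisher background alone cannot guarantee: neutral pairwise
distances are roughly exponential, and their lower tail would merge lineages
in a non-negligible fraction of runs.

**Mating locus.** Inversion status is a lineage-level label (clonally
inherited); the set of lineages flagged inverted is the subset whose total
sample count is closest to `round(fraction_inverted × sample_size)` (the
nearest achievable count). The inverted form reverse-complements the central
half of the locus, leaving colinear flanks so the breakpoints are localizable
by synteny.

**Determinism.** One seeded NumPy generator serves every draw in a fixed
order (per birth: crossover count, parent index/indices, breakpoints and
contig phases, mutation count, mutation positions; then founder divergence,
clone mutations, ALT-base assignment in locus order). Identical config + seed
gives bit-identical datasets. Internally each individual is a sorted array of
positions differing from a moving baseline; differences fixed population-wide
are folded into the baseline every 100 generations (a speed optimization with
no effect on output).

**Truth labels.** Lineage assignment, clone parents, inversion flags and the
total crossover count are always recorded; for crossover-free runs the single
pedigree genealogy's sample clades are recorded too.

**What the synthetic data are not.** Alignments contain substitutions only
(no indels, so alignment = extraction), calls have no missing data or
genotyping error, and divergence planting puts lineage-private variation in
linkage equilibrium with nothing — it is distance-independent by
construction. Passing tests therefore validate the estimators' contracts and
their response to recombination, not robustness to alignment error, call
error or ascertainment in real data.

## LD statistics (`ldstats`)

Biallelic loci are those with exactly two observed alleles among non-missing
calls. For a pair on one contig, with haplotype frequencies from samples
complete at both loci and "A"/"B" the allele coded 1:

* `D = p_AB − p_A·p_B`
* `D_max = min(p_A(1−p_B), (1−p_A)p_B)` if `D > 0`, else
  `min(p_A·p_B, (1−p_A)(1−p_B))`; `D′ = |D|/D_max` (0 when `D = 0`) —
  unsigned, as commonly reported
* `r² = D² / (p_A(1−p_A)·p_B(1−p_B))`

Pairs with a locus monomorphic after missing-data exclusion are skipped (and
counted), not zero-filled. Pair enumeration covers each same-contig pair once
within `max_distance` (default 10 000 bp). Haploid genomes give observed
haplotypes directly; no phasing is involved.

**Binning.** Bins are `(0, w], (w, 2w], …` with `w = 100` bp by default (the
bin width is a free parameter of the published procedure and is exposed as a
flag); a bin is labelled by its upper edge, and a pair at distance exactly
`w` falls in the first bin. Empty bins are omitted.

**Decay interval.** With M the maximum bin mean and H = M/2: the left border
is the distance of the first bin whose mean drops strictly below H, the right
border the distance of the last bin whose mean is strictly above H. When no
bin mean falls below H the left border is undefined (censored).

**Decay distance.** The per-pair statistic is smoothed against distance; the
decay distance is the smallest distance at which the fitted curve falls to
half of *its own maximum*, searched from the curve's maximum onward and
refined by root bisection. Anchoring H to the curve's maximum (rather than to
the maximum bin mean or the maximum single pair, both of which were
considered) makes the estimator exact on closed forms — for noise-free
`r²(x) = exp(−x/1000)` it returns 694 bp against the analytic half-life of
693 bp — and well-behaved on flat curves, which are reported as censored
rather than assigned a boundary-artifact crossing.

**Smoother.** Default is a GAM-style cubic smoothing spline with its penalty
chosen by generalized cross-validation (`scipy.interpolate
.make_smoothing_spline`), fit to per-distance means weighted by pair counts
(weights normalized to mean 1, so duplicating every pair leaves the fit
unchanged). A local-quadratic LOESS with tricube weights (span default 0.5)
is available via `smoother="loess"`; at that span it is visibly stiffer
(~12% high on the exponential closed form), which is why the adaptive spline
is the default. The half-max contract is smoother-agnostic.

## Clonal structure (`variants`)

Pairwise distance is the haploid allele mismatch count over loci called in
both samples (missing excluded pairwise; equivalent to a bitwise distance for
haploids). Clonal clusters are connected components of the graph with edges
`d < threshold` (single linkage); the default threshold of 200 SNPs reflects
the empirical gap between within-lineage and between-lineage differences in
near-clonal haploid populations and is exposed as a flag. The minimum
spanning network collapses clusters to nodes (inter-node distance = minimum
member distance) and runs Kruskal by weight class: every edge of the current
weight that joins two components as they stood at the start of that weight
class is retained, so ties yield reticulations and the edge set always
contains a minimum spanning tree. SNP density is 100 × loci / genome length.
Core gene clusters are present (count ≥ 1) in every genome; soft-core in at
least `soft_min` genomes.

## Ordination (`ordination`)

PCA of the 0/1 call matrix: per-locus mean imputation of missing calls, column
centering, no variance scaling (allele indicators share one scale),
eigendecomposition via SVD. Eigenvalues use the n−1 denominator; percent
variance is each eigenvalue over the total variance of the centered matrix
and sums to 100 over all axes. Axis signs are fixed by making the
largest-magnitude loading positive.

## Gene trees and concordance (`treescan`)

Alignments are kept only if strictly longer than 200 columns *and* their mean
pairwise difference count (columns where both sequences have A/C/G/T) is
strictly greater than 15 — both inequalities strict, so 200/15.0 are
rejected. Distances: raw mismatch proportion, JC69
`−(3/4)ln(1 − 4p/3)`, or K2P `−(1/2)ln(1−2P−Q) − (1/4)ln(1−2Q)` (default);
saturated pairs raise an error naming the pair. Trees are built by
neighbor joining with lowest-index tie-breaking (bit-reproducible) and
negative branch lengths clamped to zero. Maximum-likelihood inference is
deliberately out of scope: the target statistic is the *concordance count*,
which consumes topologies from any builder, and the builder is pluggable.

Bipartitions are the nontrivial unrooted splits (canonical side: the one not
containing the lexicographically smallest leaf). The majority-rule consensus
tallies each tree's split set once; majority splits are those with frequency
strictly above 0.5, which are always mutually compatible and assemble into a
unique consensus tree containing exactly those splits. Concordance is counted
on unrooted bipartitions (rather than rooted clades, the other reading of
"internal nodes"); with n taxa a fully concordant set of binary trees yields
n−3 majority splits, and free recombination drives the count toward zero.

## Mating-locus synteny and CAAX (`matlocus`)

Anchors are maximal exact matches, unique in both sequences, of length ≥ k
(default 20, Mummer-like scale), found in forward and reverse-complement
orientation with a suffix-array + LCP sweep (each N is encoded as a unique
symbol so it never matches). The finder is exact — it agrees with brute-force
enumeration — not seed-heuristic. Greedy chaining joins anchors of the same
orientation with diagonally consistent subject progression and query/subject
gaps ≤ `max_gap` (500 bp); reverse chains become inversion intervals; an
inter-chain gap of ≥ `min_indel` (50 bp) on exactly one sequence is an indel
interval naming the carrier. Chaining is greedy rather than LIS-optimal,
which is sufficient at the 20–30 kb locus scale. Reported coordinates are
1-based inclusive, always on the forward strand. Per-chain divergence is an
anchor-coverage proxy (1 − matched/span); base-level alignment of the locus
is out of scope, and `aligned_divergence` computes the differing-column
fraction of externally aligned pairs with gap columns excluded from both
numerator and denominator.

The CAAX rule: terminal tetrapeptide with Cys at −4 and aliphatic residues
(set {A, V, I, L, M, F}, configurable) at −3 and −2; the final residue is
free. The two pheromone-precursor proteins of the *W. ichthyophaga* study
system (terminals CIIV and CIIT) both satisfy it.

## Pipeline, problem sizes and defaults

`run_pipeline` executes simulate → distances/clusters/MSN → PCA → LD → gene
trees → synteny → CAAX, writes every stage's outputs plus a fixed-schema
`report.json`, marks data-dependent failures as skips (e.g. "no variation"
when μ = 0), and is byte-deterministic under a fixed config + seed.

The bundled demonstration configuration (`SimConfig.study_default`) emulates
the study design at full scale: 21 strains from a 5 × 2 Mbp genome, N = 200,
μ = 2×10⁻⁶, ρ = 10⁻⁶ per base per generation, 400 generations, three clonal
lineages with 2–3 copies (λ = 10), twenty 25 kb gene windows, a 30 kb mating
locus inverted in 4/21 strains, and lineage divergence 2000 (between-lineage
differences ≈ 1.6–2.0 ×10⁴, within-lineage ≪ 200). μ and ρ are demonstration
values chosen so SNP density lands at a few tenths of a percent of the
genome, in the range reported for natural isolates; no organism-specific
rate estimates exist, and none are claimed. At this clonal-structured scale
the half-max LD decay is *censored* within the 10 kb window — planted
lineage-private variants sit in perfect LD at every distance, the same
gentle-slope regime that limits the precision of this estimator on real
clonal populations — so the acceptance script also runs a freely recombining
population (N = 100, 1 Mbp, ρ = 10⁻⁵, 500 generations), where the estimator
resolves a decay distance of a few hundred bp. Test and acceptance problem
sizes (tens of kb to 10 Mbp, 20–100 individuals, ≤ 500 generations) were
chosen so the full suite and the acceptance script each run in minutes on a
single CPU while keeping every contrast (clonal vs recombining) far from its
decision boundary.

## Known limitations

* Forward simulation from a monomorphic founder approaches, but does not
  reach, neutral equilibrium in G ≤ 2N generations; diversity is slightly
  below θ-based expectations.
* Finite-sites toggling makes homoplasy possible at high μ; gene trees from
  short windows are correspondingly noisy.
* The MSN tie policy (retain all tying edges per weight class) is one of
  several reasonable conventions; different tie policies yield different
  reticulation sets over the same minimum spanning weight.
* Inter-contig LD is undefined by design; contigs are treated as physically
  unlinked.
* `aligned_divergence` requires an externally produced alignment; the package
  does not align.
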