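# Methods

## Problem and overview

Horizontally transferred DNA segments often carry several genes. If two
gene families are repeatedly *gained on the same branches* of a strain
phylogeny, they were plausibly co-transferred on one segment, and the
genomic distance between them in extant genomes bounds the size of that
segment from below. `cotransfer` implements the full inference chain —
ancestral gain/loss reconstruction, pairwise co-gain statistics with an
empirical false-discovery rate, circular-genome distance analysis, and
autocovariance-based estimation of the pair-distance distribution inside
supra-operonic clusters (SOCs) — together with a generative simulator that
provides ground truth for every stage.

## Gain/loss model and reconstruction

Family presence evolves independently along branches as a two-state
continuous-time Markov chain: gain rate α (0→1) and loss rate β (1→0) per
unit branch length, with the stationary distribution
(β, α)/(α+β) as the root prior. For a branch of length *t* the transition
matrix is the standard binary-trait solution with relaxation rate α+β.

* **Fitting.** One global (α, β) is estimated by L-BFGS-B in log-rate space
  (bounds 10⁻⁴–10³, three deterministic multistarts) maximising the product
  of pruning-algorithm likelihoods. Only families that vary across the
  leaves enter the likelihood: invariant families carry no event
  information and only drag the stationary frequencies toward their state.
  With a large constant-present core this bias is not benign — the fitted
  stationary presence crosses 0.5 and repeated gains get re-explained as
  ancestral presence plus losses.
* **Posteriors and events.** Marginal posteriors come from an exact
  up–down pass (leaves pinned to observations; verified against brute-force
  enumeration on small trees to 1e−9). Event calling is two-tier:
  inclusive (presence iff *P* ≥ 0.5, the tie at exactly 0.5 counting as
  present) and high-confidence (gain iff *P*_parent ≤ 0.2 and
  *P*_child ≥ 0.8, symmetric for losses). Branch lengths are taken from the
  input tree and never re-estimated; rate mixtures across families are out
  of scope — the thresholded posteriors the downstream stages consume are
  robust to this simplification, and the high tier guards against model
  mismatch.

## Co-gain association and FDR

Gain vectors are indexed by the 2n−2 branches in preorder-of-child order.
The pair universe is all unordered pairs of families with ≥ 1 gain
(zero-gain families contribute only [0,0] patterns and p = 1). The score is
t = log₁₀ of the Fisher right-tail p-value of the 2×2 branch-pattern table,
computed exactly via the hypergeometric survival function (verified against
full enumeration for all tables with total ≤ 12).

Branches are phylogenetically dependent, so p-values are not interpreted
directly. The null model permutes every family's presences across extant
genomes independently (preserving per-family frequencies) and re-runs
reconstruction, calling and scoring with the empirically fitted (α, β)
(refitting per replicate is available but off by default, isolating the
association signal from rate variation). With strict `< t` counting on both
sides and the null count rescaled to the empirical pair-universe size,
FDR(t) = N_null(t)/N_data(t); t* is the largest threshold with
FDR ≤ α. The pipeline default of three null replicates averages the null
counts; a single replicate is the function-level default.

## Distances on the circular chromosome

Coordinates are 0-based, half-open, on circular chromosomes; a feature
wrapping the origin is encoded with end > genome length. The distance
between two genes is the gap between nearest boundaries along the shorter
arc (0 when they overlap) — under this convention "no intervening genes"
and "small distance" coincide, and adjacent co-transferred genes are at
distance ≈ 0. Midpoint and linear conventions were considered; the boundary
convention is fixed throughout, and its one consequence for cross-estimator
comparisons is discussed under *Autocovariance* below. Per genome, paralogs
are resolved by the minimum over allele pairs; the pair's distance is the
minimum over genomes (per-occurrence distributions keep one value per
genome instead). All distances are ≤ half the genome length by
construction.

Occurrences are split at the ordinary segment cap (close) and the phage
segment cap (distant). For each occurrence with ≥ 1 gene fully inside the
shorter-arc gap, the fraction of intervening genes that are
phage-associated is recorded; groups are compared with a two-sided Wilcoxon
rank-sum test (mid-ranked ties, via the Mann–Whitney U implementation).
Occurrences with no intervening genes are excluded from the fraction
comparison.

Phage association is three-state: *associated* (any allele with a phage GO
term or the case-insensitive substring "phage" in its product/note text),
*not associated* (GO-annotated, no evidence), *uncertain* (no GO terms, no
evidence). The family-level state is the OR over alleles. The "non-phage"
pair filter demands both members strictly *not associated* — uncertain is
excluded. The shipped phage GO-term list is a synthetic default matching
the simulator's vocabulary; real analyses should supply a curated list.

## Mutual information of phylogenetic profiles

Plug-in pattern probabilities over the species panel, base-2 entropies
(0·log 0 := 0), I = H(A) + H(B) − H(A,B). Base 2 is chosen because it is
the only base for which the bound 0 ≤ I ≤ 1 is tight for binary profiles.
No small-sample bias correction is applied; the plug-in estimator has a
bias floor of roughly 1/(2·N·ln 2) ≈ 0.003 at N = 233 species, which
matters when choosing MI cutoffs (below).

## Autocovariance and SOC distance distributions

For one genome, sites are sampled on a 10 bp lattice inside the genes of
eligible families (non-phage, no mobile-element overlap, carrying the data
the mode needs); g_i(x) = 1 iff the site at i+x (circular) lies in a
*different* gene forming a qualifying pair with the family at i —
co-occurring (MI ≥ cutoff) or co-functioning (≥ n shared GO terms),
optionally restricted to same-operon pairs. G(x) is the mean of g_i(x) over
the n lattice sites; an exact 1 bp mode exists for oracle tests, and the
10 bp lattice agrees with it to discretisation error. The published form of
the site condition ("x and x+1 are sites of two different genes") is not
self-consistent with x = j − i; it is implemented as: site i in gene A,
site i+x in gene B ≠ A.

G̃(x) = (G − ⟨G⟩)/(max G − ⟨G⟩), with ⟨G⟩ the mean over the evaluated grid
(default x_max 30 kb — the large-x plateau standing in for the background
G₀). G̃ is binned geometrically (25 bins/decade), truncated at the first
non-positive bin after the peak, leading bins below the first local maximum
dropped (intra-gene exclusion makes low distances noisy), and the remaining
per-bin mass normalised to 1. Medians are interpolated within bins.
Curves from several genomes (default 5) are averaged on the raw G grid
before rescaling.

One systematic offset matters at simulation scale: the autocovariance
measures *site-to-site* distances, larger than nearest-boundary pair
distances by about one gene length. The generator therefore uses genes much
shorter than cluster spans (see below) so that, as with real bacterial
genomes and 30 kb clusters, the offset is a small fraction of the
distribution's scale. Cross-estimator comparisons use the two-sample KS
distance on the merged breakpoint grid.

Note on MI cutoffs: a loose cutoff of 10⁻⁴ sits below the plug-in bias
floor, so essentially every pair qualifies and the cluster excess rides on
a large background (the rescaling absorbs it, at some cost in tail noise).
Where the analysis needs co-occurrence and co-function to pick out the same
pairs — e.g. when checking that the CO- and GO-based SOC estimates agree —
a cutoff of 0.01, above the floor, is used.

## The synthetic-data generator

The generator emulates a pan-genome shaped by recurrent segmental transfer:

* **Genome.** 2 Mb circular chromosome, 1500 families: 70 clusters of 5–8
  genes (SOC analogs) plus singletons, of which 15% are phage genes and 75%
  of the non-phage singletons form an essential core. Gene lengths are
  lognormal, median 300 bp (capped at 100–900 bp) — deliberately short
  relative to cluster spans for the site-vs-boundary reason above; only
  relative distances matter to the analysis. Clusters are split into
  operons of 1–3 genes with ~100 bp gaps inside operons and ~800 bp gaps
  between operons, so a SOC is a multi-operon island whose internal
  distances (up to ~4–5 kb) extend well beyond operon scale.
* **Annotation.** Each cluster shares 2 cluster-level GO terms and each
  operon 4 more; families also draw 0–2 background terms from a pool of
  200. GO annotation is withheld from 15% of non-phage families to populate
  the *uncertain* phage class. Phage families carry "phage" product text
  and, half the time, a phage GO term. 2% of eligible singletons are
  flagged as mobile-element overlaps.
* **Evolution.** Along each branch, deletion events excise whole accessory
  islands (the contiguous run of one cluster, or a single singleton gene);
  the core is never deleted. Acquisition events (Poisson, 140 per unit
  branch length) insert a contiguous segment drawn from the local
  pan-genome — the families currently absent from the lineage — grown along
  the canonical cluster order while it fits the 5 kb ordinary cap.
  With probability 0.15 an event is phage-mediated: phage genes are
  interleaved between the cargo genes with 100 bp gaps and the segment may
  extend to the 12 kb phage cap, mimicking imprecise prophage excision.
  Insertion points are uniform on the circle, never splitting a gene; 65%
  of events seed in clustered families (selection favours co-functioning
  toolbox genes). Deletion pressure (2.5 per accessory gene per unit branch
  length) balances acquisition so that accessory islands are present in
  roughly half the genomes and are independently re-acquired ~4–7 times
  across the 16-leaf tree — the regime in which repeated co-gains are
  informative. The event log, the same-segment pair set, cluster membership
  and the canonical intra-cluster distances constitute the ground truth.
* **Panel profiles.** 233 species; each species retains a cluster with
  probability 0.5 and, within a retained cluster, each operon with
  probability 0.85; singletons are independent coin flips; 1% flip noise on
  top. Same-operon pairs therefore exceed the 0.8 MI cutoff, same-cluster
  pairs sit lower, cross-cluster pairs at the bias floor.

**What the generator does not emulate:** nucleotide sequences, homologous
recombination, rate variation across families, tree uncertainty, genome
rearrangement after insertion, paralog duplication (families are
single-copy, though the distance code handles paralogs), and realistic
coding density. Passing tests show the chain recovers planted segmental
structure under these conditions; they do not certify performance on real
pan-genome matrices, where rates vary and reconstruction error is larger.

## Problem sizes and determinism

The study conditions (16 genomes, 1500 families, 30 branches, 5-genome
autocovariance averages, 3 null replicates) make the full chain run in
about half a minute on one CPU; the same configuration backs the test
suite's session fixture and `scripts/acceptance.py`. At 30 branches the
Fisher scores cannot reach the magnitudes a 104-branch tree supports;
FDR thresholds typically land between t* = −4.4 and −5.8 with a few
hundred significant pairs. All randomness flows from a single integer seed
(generator, fitting multistarts, null permutations); identical
configurations produce byte-identical outputs.

## Known limitations

* A single global (α, β) is a deliberate simplification of per-family rate
  variation; heavily skewed real datasets may need the high-confidence tier.
* The empirical FDR inherits the null's blind spot for block structure: one
  chance coincidence of two whole islands yields many correlated pair
  discoveries while the per-family shuffle prices them as independent.
* The SOC estimate is a genome-average; it cannot resolve individual
  cluster boundaries, only the distance distribution.
* The operon-restricted GO-AC validation is exact only when operon pair
  distances dominate gene length (the estimator's site-offset bias
  otherwise shifts the bulk to the right, as visible at simulation scale).
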