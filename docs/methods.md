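# Methods

`aeromyco` reimplements, as a tested library, a quantitative analysis chain
for spike-calibrated ITS2 fungal metabarcoding of paired air and soil
samples along urban–natural gradients. This note documents the models, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Quantification model

For sample *i* let *n<sub>i</sub>* be its total reads, *s<sub>i</sub>* the
reads matching a spike (synthetic internal-standard plasmid),
*p<sub>i</sub>* the non-fungal reads and
*f<sub>i</sub> = n<sub>i</sub> − s<sub>i</sub> − p<sub>i</sub>* the fungal
reads. Because every sample receives the same absolute amount of spike DNA,

> *w<sub>i</sub> = f<sub>i</sub> / s<sub>i</sub>*

is a dimensionless estimate of the total fungal DNA amount. OTU abundance
is *a<sub>ij</sub> = w<sub>i</sub> · r<sub>ij</sub> / f<sub>i</sub>*
(DNA amount times relative read abundance among fungal reads), and the
per-method normalization *â<sub>ij</sub> = a<sub>ij</sub> / Σ<sub>i′∈method(i)</sub> w<sub>i′</sub>*
makes the air data and the soil data each sum to one, putting the two media
— whose DNA units are not comparable — on equal footing.

Reads are called **spike** at ≥ 0.95 identity to any spike reference
(inclusive boundary), **fungal** when their taxonomic placement assigns a
fungal phylum with probability strictly > 0.90, and **non-fungal**
otherwise. Reliability at deeper ranks uses a prefix rule: a rank is
reliable only if all its ancestors are, which prevents a sequence
"reliable at genus" under an unreliable class from constraining the
clustering. Samples with fewer than 10,000 reads (strict) are excluded;
samples with *s<sub>i</sub>* = 0 have undefined *w* and are flagged and
excluded with a logged reason.

## Sequence similarity

The package replaces external mapping/clustering heuristics with an
explicit similarity model: global alignment with match +1, mismatch −1,
gap −1, and identity = identical aligned positions / alignment length.
Score ties are resolved toward more matches, then a shorter alignment;
these objectives are additive, so the lexicographic dynamic program is
exact, and — unlike a fixed traceback preference — symmetric in its
arguments.

Collections of uniform length (the normal case for merged amplicons of a
fixed-length synthetic reference) are scored gap-free: identity
= 1 − hamming/L, computed with 2-bit-packed XOR/popcount kernels and an
early-abandoning best-hit scan (numba). The gap-free value is a tight
lower bound of the DP identity; the DP can exceed it by ~1% only when a
shifted local repeat pays for two gaps, which is rare in
substitution-generated data and negligible relative to the margins at the
thresholds in use (0.90–0.995). Mixed-length inputs always take the exact
DP route.

## Taxonomy-constrained OTU clustering

Fungal reads are first pre-clustered at 99.5% identity (a cost-reduction
step, not an ecological unit): greedy centroid clustering in read-id order,
implemented as exact dereplication followed by first-occurrence greedy
clustering, which provably reproduces the per-read trajectory when all
reads weigh 1. Each representative carries its member count as weight,
per-sample member counts, and the modal member placement (ties: higher
summed placement probability, then smallest read id).

Clustering then proceeds level by level, class → species:

1. **Backbone**: representatives reliably placed at the level, whose
   placement's parent agrees with their current assignment (disagreements
   are demoted to unreliable and logged).
2. **Taxon representatives**: greedy centroids at 0.995 within each
   backbone taxon, weight-descending order, ties by id.
3. **Distributions**: for each backbone sequence, its best identity to its
   own taxon's representatives (*within*) and to representatives of
   sibling taxa under the same parent (*among*), pooled across parents.
4. **Threshold**: with FP(t) = #{among ≥ t} and FN(t) = #{within < t},
   both counts are constant on the half-open intervals between consecutive
   distinct pooled values; the optimizer picks the interval minimizing
   |FP − FN|, then FP + FN, then the lowest such interval, and θ is its
   midpoint. Balancing *rates* instead of counts is available
   (`fpfn_mode="rates"`) for levels with very unbalanced class sizes.
   If the within distribution is empty the level falls back to the
   previous level's θ (0.9 for the first level).
5. **Assignment**: every non-backbone representative with best identity
   strictly exceeding θ joins the arg-max backbone taxon under its parent
   (ties → heavier representative's taxon, then lexicographic label); the
   rest are greedy-clustered at θ into de novo taxa
   `parent.denovo_<level>_<k>`, which propagate downward and terminate in
   species-level OTUs like every other lineage.

Reliably placed sequences are never moved off their reliable taxon — the
constraint is structural, not a post-hoc filter. The final OTU is the
species-level node; every input receives exactly one.

A note on the fallback: when a level has *no* backbone (e.g. nothing is
reliable at species), θ<sub>species</sub> := θ<sub>genus</sub>, and the
genus-level threshold — the midpoint between ≈1 and sibling-*genus*
identity — lies below sibling-*species* identity whenever the per-edge
species divergence is smaller than the genus divergence. De novo species
recovery under a missing species backbone therefore requires species-level
divergence comparable to or larger than the genus edge; the recovery
experiments construct exactly that condition.

Threshold calibration may subsample the backbone (`calibration_cap`,
default 20,000 sequences per level in the pipeline configuration, a
deterministic stride over the weight-ranked backbone). This bounds the
cost of the distribution scans on large studies; it affects only the θ
estimate, never membership, and `calibration_cap=None` restores the exact
computation.

## Habitat and medium classification

Taxon abundances (normalized layer) are aggregated per rank by summing
member OTUs; totals are conserved at every rank. A taxon is predominantly
*air*-detectable if its summed abundance over air samples is at least ten
times (inclusive) the soil sum, and vice versa; natural/urban specialist
calls work identically pooling both media. A positive sum against a zero
sum yields a call; two zeros yield "neither". Taxa present in fewer than
five samples (strict) are excluded as unreliable. Classification is
scale-invariant by construction. Euler (shared/exclusive) counts between
two sample groups use the same ≥ 5-sample eligibility rule.

## Community statistics

Normalized abundances of OTUs present in ≥ 5 samples are
log(x + 10⁻⁶)-transformed; sample distances are Euclidean. Ordination is a
Sammon mapping minimizing S = (1/Σδ) Σ (δ − d)²/δ by diagonal-Newton steps
(step 0.3, halved until the stress decreases, ≤ 500 iterations, tolerance
10⁻⁹), initialized from classical metric scaling — a deterministic start,
so repeated runs are identical. Duplicate samples (zero distances) must be
collapsed by the caller.

PERMANOVA uses the Gower-centered inner-product matrix with sequential
(Type-I) sums of squares in the order the terms are given (the
all-data model: method, habitat, site, plot, and method's two-way
interactions; the per-medium models: habitat, site, plot). The identity
SS<sub>total</sub> = Σ<sub>i<j</sub> d²<sub>ij</sub>/n is asserted on every
call. P-values use the (1 + exceedances)/(1 + n_perm) estimator under free
row permutation (999 permutations by default; the design's nesting can be
respected with the `strata` option, and `n_perm="exact"` enumerates all
permutations for small n). Internally samples are processed in sorted-id
order so p-values do not depend on input row order.

The exports (`richness`, `hmsc_air_*`, `hmsc_soil_*`) are the model-ready
inputs for external mixed-model and joint species distribution fitting:
per-sample design factors, observed OTU richness, w and log sequencing
depth; and presence/abundance matrices for species occurring in ≥ 20
samples of a medium. Fitting those models is outside this package's scope.

## Synthetic study generator

The generator emulates the sampling design — five sites, each with two
natural-core, one natural-edge, one urban-edge and two urban-core plots,
sampled by cyclone air sampler and soil coring in three replicates
(180 samples, 90 per medium) — with known ground truth:

* **DNA amounts**: w\*<sub>i</sub> = 5 · (0.2 if urban) · LogNormal(0, 0.3).
  The urban multiplier 0.2 encodes the fivefold reduction the analysis is
  meant to recover; the lognormal is per-sample ecological noise.
* **Read composition**: depth ~ Poisson(20,000); category counts are
  multinomial with weights spike : fungal : non-fungal = 1 : w\* : 1. The
  spike share is a free parameter of the design (real studies tune spike
  input empirically); 1 : w\* : 1 keeps spike counts large enough that the
  ratio estimator's noise is negligible next to the ecological noise.
* **Taxonomy**: 2 phyla × 2 classes × 2 orders × 2 families × 3 genera ×
  3 species = 144 species; reference length 250; per-edge divergences
  0.15/0.10/0.08/0.06/0.045/0.03 phylum→species, applied as binomial
  substitutions along the tree. Sibling species then sit near 94%
  identity, far above the 0.2% per-base error rate.
* **Ecology**: 60% natural specialists, 2% urban specialists, 38%
  generalists; a specialist keeps its abundance at home and is 20× rarer
  in the other habitat, so the parameter is the species' own cross-habitat
  abundance ratio. (Scaling specialists *up* at home instead would, with
  60% of the community specialist, renormalize the measured DNA ratio down
  to ~11× — right at the 10× call boundary; the away-penalty formulation
  keeps composition sane and the measured specialist ratio compounds with
  the fivefold habitat effect to ~44×, generalists to ~2×.) Species mean
  abundances are LogNormal(0, 1); air/soil affinity weights are
  Dirichlet(2, 2).
* **Reads**: the species reference plus i.i.d. substitution errors at
  0.002/base (an optional indel rate exists for robustness tests and
  switches the dataset to variable-length mode). Non-fungal reads are
  random sequences — they must fail both spike matching and fungal
  placement.
* **Placements**: per read and rank, the true taxon with probability 0.95
  when a Bernoulli(ρ<sub>rank</sub>) draw marks the rank reliable, else
  0.50 — a two-point stand-in for a full posterior, sufficient because the
  pipeline only consumes the > 0.90 cut. Defaults
  ρ = 0.99/0.95/0.92/0.90/0.85/0.75 phylum→species, declining with depth
  as probabilistic placement does in practice.
* **Failures**: `n_failed_samples` (default 0) samples can be drawn at
  5–50% of nominal depth to exercise the < 10,000-read exclusion, mirroring
  the six technically failed samples such studies report.

What the generator does **not** emulate: real ITS2 length variation and
indel-rich evolution, chimeras, PCR/primer bias, tag-jumping, and
correlated (non-multinomial) overdispersion of counts. Passing recovery
tests therefore demonstrates the correctness of the analysis logic under
its stated assumptions, not robustness to every artifact of real amplicon
data.

## Problem sizes and numerical choices

The default synthetic study (~3.6 M reads, ~1.9 M fungal) runs end-to-end
in minutes on one CPU: screening and pre-clustering use the packed Hamming
kernels with an exact half-index for the 99.5% (hamming ≤ 1) regime, and
backbone scans use early-abandoning best-hit searches. The recovery
experiments in the test suite use a one-site replica (36 samples, depth
2,000–3,000) where full-scale behavior is not the point. Tolerances:
conservation invariants at 10⁻⁹; Monte-Carlo recovery checks at the
binomial scale of their sample sizes; the fivefold-ratio check at ±20%
(15 edge samples per cell of the design under σ = 0.3 lognormal noise give
the ratio a ~11% coefficient of variation).

## Known limitations

* De novo species recovery with an empty species backbone is bounded by
  the fallback threshold (see above); with a realistic monotone divergence
  profile the method lumps sibling species in that regime, as would any
  single-threshold de novo clustering at the genus-calibrated θ.
* The gap-free bulk similarity slightly underestimates the DP identity in
  the presence of local repeats; at the package's thresholds this has no
  effect on synthetic data, but indel-rich real data should be analysed
  with the (slower) DP route by supplying variable-length input.
* PERMANOVA permutes rows freely, mirroring the reference analysis;
  p-values for factors confounded with the nested design (site, plot)
  should be interpreted with the `strata` option in hand.
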