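# Methods

This note documents the statistical models, conventions and numerical
choices behind each analysis stage, what the synthetic-data generator does
and does not emulate, and the package's own resolutions of points where
standard tools differ.

## Missing data

Two conventions coexist, each matching the tool family that traditionally
produces the corresponding table:

- **Complete deletion** for haplotype collapsing, S, K, π, Φ-statistics and
  networks: any alignment column containing `-` or `N` in *any* sequence is
  removed before analysis. The number of excluded columns is always
  reported.
- **Pairwise deletion** for Kimura 2-parameter distances: each sequence pair
  uses the sites at which both sequences are called.

## Diversity indices

Haplotype diversity uses the small-sample-corrected estimator
Hd = n(1 − Σpᵢ²)/(n − 1) with the Nei (1987) large-sample variance

    V(Hd) = 2/(n(n−1)) · [2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²].

Nucleotide diversity is the raw p-distance-based π = K/L (no substitution
correction; corrected distances live in the distance module), with the
no-recombination **total** variance

    V(π) = (n+1)π / (3(n−1)L) + 2(n²+n+3)π² / (9n(n−1)).

The total variance includes the evolutionary (coalescent) component and is
therefore noticeably larger than the sampling-only variance some programs
print; the choice is deliberate and documented so discrepancies against
other software are explainable.

A pooled row treats all sequences as one sample; it is not the arithmetic
mean of the per-population rows.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); S = 0
raises a distinct "undefined" error rather than returning 0. Fu's Fs is
driven by θ_π (the observed K): S′ = P(K_alleles ≥ k_obs) under the Ewens
sampling distribution P(K=k) = |s(n,k)|θᵏ/(θ)ₙ, with unsigned Stirling
numbers of the first kind computed by the log-space recurrence
|s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| (finite well beyond n = 326, where the
raw numbers overflow doubles). k_obs = 1 gives S′ = 1 and Fs = +∞, reported
as such.

P-values are one-tailed (lower) by coalescent simulation: Tajima's D is
compared against samples conditioned on the observed S (mutations placed
multinomially on branch lengths), Fu's Fs against samples driven by θ_π.
Monomorphic simulated draws count as maximally non-negative Fs. The
customary reading of Fs significance (p < 0.02 for the "5% level") is left
to the caller; raw p is always reported. Default 10,000 replicates in the
CLI; a seed is mandatory everywhere.

## Mismatch distributions and the sudden-expansion model

For a stepwise expansion from θ₀ to θ₁ at mutational time τ = 2ut, the
expected pairwise-difference distribution is obtained by integrating the
Poisson mutation count over the pairwise coalescent time across the two
epochs; with λ = (θ₁+1)/θ₁ and F_eq(i;θ) = θⁱ/(1+θ)^{i+1},

    F(i) = F_eq(i;θ₁)·P[Pois(λτ) > i] + e^{−τ/θ₁} Σ_{j≤i} Pois(j;τ)·F_eq(i−j;θ₀),

which reduces to F_eq(·;θ) at τ = 0 and sums to 1 over all classes. The
Poisson terms come from scipy.

Fitting minimizes SSD = Σ(obs − exp)² over the observed class range. The
surface is scanned on a coarse grid (τ ∈ [0, 2·max class], 41 points; θ₀
from 0 up to the observed mean; θ₁ log-spaced up to 1000 plus the cap) and
polished with Nelder-Mead (fatol 1e−10). θ₁ is reported at the conventional
ceiling 99,999 whenever the capped fit is not measurably worse — star-like
data leave θ₁ unidentified above some value, and the ceiling mirrors how
such fits are conventionally printed. θ₀ is floored at 0. A single occupied
class returns the τ = 0 equilibrium fit. Bootstrap refits use a reduced
grid and looser polish (documented as `fit(coarse=True)`).

Harpending's raggedness index r = Σ(xᵢ − xᵢ₋₁)² is computed over classes
0..d+1 with zero padding on both ends, d being the largest occupied class.
Goodness-of-fit p-values are parametric bootstraps: samples of the same n
are simulated under the fitted expansion model (see simulator below),
refitted, and p = fraction of simulated statistics ≥ observed; default
1000 replicates, 100 minimum.

**Expansion time.** T = τ/(2μ) with μ = generation time × sites × per-site
yearly rate. The defaults (1.4 × 10⁻⁸ /site/year, 1.5-year generations,
674 sites) give μ per *generation*, so T is strictly in generations; the
field convention reads it directly as years, and this package follows that
convention (it reproduces published expansion-time columns exactly). The
dimensional looseness is noted here once.

## AMOVA, pairwise Φ_ST and the group search

Pairwise difference counts enter the molecular-variance decomposition as
squared Euclidean distances (the classic haplotype-level AMOVA; many papers
label the resulting indices F_ST). Sums of squares come from
SS(set) = Σ_{i<j∈set} d_ij / |set|; variance components by method of
moments with the usual unequal-sample-size coefficients; Φ indices from the
components. Negative components are retained — small negative Φ_ST
estimates are meaningful null results, not errors.

Permutation schemes: samples among populations (Φ_ST), samples among
populations within groups (Φ_SC), whole populations among groups (Φ_CT);
p = (1 + hits)/(1 + permutations). With every population its own group,
Φ_SC is undefined (signalled as None) and Φ_CT equals Φ_ST.

The SAMOVA-style search maximizes Φ_CT over partitions of populations into
K groups. With few demes (number of K-partitions ≤ 10⁵) the search is
exhaustive; otherwise simulated annealing with geometric cooling
(rate 0.995, 2000 steps, 100 random starts). Geographic contiguity is *not*
enforced: for a handful of scattered sampling sites a contiguity notion is
ill-defined, so the search is free and the user can check the optimum
against the sampling map (coordinates travel with the population map).

## Distances and trees

K2P: d = −½ln(1−2P−Q) − ¼ln(1−2Q) with P, Q the transition and transversion
proportions over pairwise-complete sites; a non-positive log argument
(saturation) raises a per-pair error. Between-population distance is the
mean K2P over all inter-population pairs ("average" mode, the default); a
net mode subtracts the mean within-population distances (Nei's d_A).

UPGMA merges the closest pair under size-weighted average linkage, node
heights d/2 (output is ultrametric to 1e−9); NJ follows Saitou–Nei with
standard branch lengths. Both break ties by the lexicographically smallest
label pair, making topologies deterministic. Negative NJ branch lengths are
clamped to zero with the deficit transferred to the sibling branch.
Midpoint rooting (root at the halfway point of the longest leaf-to-leaf
path) is provided because NJ trees are unrooted and display conventions
root them there; "taxon X separates from the rest" is assessed on the
midpoint-rooted tree.

## Statistical-parsimony networks

The network is the minimum-spanning variant of statistical parsimony:
haplotype pairs are processed in ascending mutational distance up to the
connection limit, and at each distance level every pair joining components
that were separate *before* the level is added, so equally parsimonious
alternative connections are retained as cycles. Multi-step edges are
subdivided by median (unsampled) nodes, one per intermediate mutation,
with intermediate sequences constructed by flipping differing sites in
site order (a deterministic tie-break; the intermediates are placeholders,
not inferences). Gaps never count as steps (complete deletion upstream).

The 95% connection limit is the largest j such that two haplotypes observed
to differ at j of L sites are, with probability > 0.95, separated by
exactly j mutations. The package computes that probability under an
explicit finite-sites multiple-hit model: successive mutations hit a
uniformly chosen site, a hit on an already-differing site reverts it with
probability 1/3 (Jukes–Cantor symmetry), giving a random walk on the
visible-difference count; the true mutation count carries the geometric
prior of a pairwise coalescent with mean equal to the observed j. Then
P(parsimony | j) = P(M = j | obs = j) by Bayes. The walk is evaluated
iteratively with the prior tail truncated at 10⁻¹²; an independent
matrix-power evaluation of the same model serves as the test oracle. For
L = 674 and 95% confidence the limit is 8 steps; at confidence 0 the limit
is L by construction, and the limit is non-decreasing in L.

The central haplotype is the sampled node of maximal frequency; ties go to
minimal eccentricity, then lexicographic id.

## The coalescent simulator

A haploid (mtDNA-style, maternally inherited; effective size semantics are
N_f) backward-time coalescent over demes:

- **Time** in units of N generations; per-deme scaled mutation rate
  θ = 2Nu for the whole locus, so lineages mutate at rate θ/2.
- **Island migration**: each lineage migrates at rate M/2 to a uniformly
  chosen other deme. For d demes the expected pairwise Φ_ST is
  (d−1)/(Md + d − 1), i.e. 1/(1+2M) for two demes — the calibration target
  used in the tests.
- **Sudden expansion** at time t (all demes): looking backwards, deme sizes
  drop by the fold factor, so the true mutational expansion age is
  τ = θ·t.
- **Diverged deme**: one deme exchanges no migrants until its split time,
  at which point (backwards) all lineages merge into a single ancestral
  deme. This produces the "one strongly differentiated population" pattern.
- **Mutation**: finite-sites by default with a transition:transversion
  ratio of 10:1 (typical of COI), applied by replaying each branch's
  mutations oldest-first so reverse and parallel hits behave correctly; an
  infinite-sites mode (each mutation a fresh site) drives the neutrality
  p-values, mismatch bootstraps and oracle tests. The root sequence is
  uniform random, so base composition is even — real COI is AT-rich, which
  affects no statistic computed here.

The study-shaped default (`PAPER_LIKE`) is seven demes of 46/44/47/47/48/
48/46 samples, 674 sites, θ = 0.8, a 100-fold sudden expansion at t = 2.5
(τ = 2.0), migration M = 20 among six demes and a seventh deme isolated for
5 N-generations. These values were chosen once to land in the observed
ranges of a real low-diversity COI survey: per-deme Hd ∈ [0.2, 0.85], π ∈
[0.0003, 0.003], a star-like genealogy around one modal haplotype, and
Φ_ST > 0.4 between the isolated deme and every other.

**What the generator does not emulate:** recombination (appropriate for
mtDNA), selection, rate heterogeneity among sites, biased base composition,
sequencing error and sampling artifacts. Passing tests therefore
demonstrate the estimators' correctness and calibration under the neutral
demographic models they assume — not robustness to selection or data
artifacts in real surveys.

## Problem sizes and determinism

Simulation-backed checks run at: 1000 neutral replicates (n = 40, θ = 2)
for the Tajima's D calibration with per-S null tables of 1000 draws; 200
replicates for the island-model Φ_ST expectation; 50 replicates (n = 48)
for sudden-expansion τ recovery; 100-replicate parametric bootstraps in
pipeline examples. These sizes keep every Monte-Carlo band comfortably
wider than simulation noise. All randomness flows from explicit seeds
(numpy Generator); rerunning any stage with the same seed reproduces
outputs byte for byte.

## Known limitations

- Fu's Fs p-values simulate conditional on θ_π rather than jointly with
  the uncertainty in θ̂; this matches common practice but understates
  variance for very small samples.
- The mismatch SSD fit is least squares, not the generalized least squares
  some programs use; fitted τ values agree closely in practice (the τ
  recovery calibration bounds the difference) but exact per-dataset
  agreement with other software is not guaranteed.
- The connection-limit probability model is an explicit reconstruction of
  statistical parsimony's premises; other implementations of the limit can
  differ by a step or two at a given L.
- π's standard deviation uses the total (evolutionary + sampling) variance;
  programs reporting only the sampling component will print smaller SDs.
- The AMOVA permutation p-values are conservative on near-monomorphic data
  (ties produce atoms at p = 1).
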