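# Methods notes

These notes record the models implemented in `rhizoecol`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Canonical data flow

All analyses consume a `FeatureTable` (samples × taxa integer counts).
The intended order is **rarefy → abundance filter → analysis**: rarefaction
(multivariate hypergeometric, i.e. subsampling without replacement, seed
mandatory) equalises depth, then taxa whose share of the grand total falls
below 0.005% are removed. The filter interprets the threshold as a share of
the pooled counts over all samples, because it is applied once before
diversity computation; a per-sample mode exists behind a flag. The order of
rarefaction and filtering is not uniquely determined by common practice, so
both orders work; the default above is what the drivers use. File
orientation (samples-as-rows vs taxa-as-rows) must be stated explicitly —
auto-detection is refused because silent transposition is a classic
amplicon-pipeline failure.

## Diversity

Richness is the count of detected taxa; Chao1 uses the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)) so it stays finite without doubletons (classic
form behind a flag); Shannon is −Σ p ln p in nats. Bray–Curtis is
Σ|x−y| / Σ(x+y). PCoA is classical metric scaling of −½D² after double
centring; negative eigenvalues (the non-Euclidean part of Bray–Curtis) are
reported, not corrected, since only the leading axes are interpreted.

PERMANOVA is the one-way distance-based pseudo-F (total sum of squares from
all pairs, within from within-group pairs), with label permutations and
p = (1 + #{F* ≥ F}) / (1 + n_perm). It is implemented in-package so the
permutation stream is seedable; a test cross-checks the statistic against
scikit-bio's implementation. Field reports sometimes print a bare "R" for
this test without defining it; this package reports both R² and pseudo-F
explicitly.

The similarity contrast converts distances to similarities (1 − BC),
partitions all sample pairs into per-group "within" sets and per-group-pair
"between" sets, and tests every pair of sets with a two-sided Wilcoxon
rank-sum test, BH-corrected across all contrasts. The test choice is a
package decision (the analysis class it reproduces does not fix one).

## Neutral community model

For a taxon at metacommunity relative abundance p, Sloan's model gives the
stationary local relative abundance the Beta(Nm·p, Nm·(1−p)) distribution,
Nm being local community size × immigration rate. `predicted_frequency`
is the classic tail form f̂ = 1 − I_d(Nm·p, Nm·(1−p)) with detection limit
d (default one read at the rarefied depth, d = 1/N).

`fit_ncm` estimates Nm by unweighted least squares of the model occurrence
curve against observed detection frequencies, via bounded scalar search
over log Nm ∈ [0, log 10⁷] (a one-parameter problem; bracketing is more
robust than gradient methods). R² is about the mean of observed
frequencies. Two detection models are available:

* `"sampling"` (default): the exact probability of drawing at least one
  read among N from a beta-distributed composition,
  f̂ = 1 − B(Nm·p, Nm·(1−p)+N) / B(Nm·p, Nm·(1−p)). For count tables
  rarefied to depth N this is the unbiased detection model: on synthetic
  neutral surveys it recovers Nm to a few percent across Nm ∈ [500, 2000].
* `"threshold"`: the classic tail approximation P(x > d). It is retained
  for comparability with the widely used fitting scripts, but it is
  systematically biased on multinomially sampled counts whenever Nm is far
  from the sequencing depth (we measure 30–40% bias at Nm = 500 or 2000
  with depth 1000), because real detection follows the beta-binomial
  zero-class, not a hard threshold on the latent proportion.

Confidence bands resample taxa with replacement (default 999 replicates),
refit Nm each time, and take pointwise 2.5/97.5 percentiles of the refit
curves on a log-spaced abundance grid; the band is closed over the
point-estimate curve so it always contains it. Fits on clouds where every
taxon is detected everywhere are flagged unreliable (no information about
Nm). The caller must supply a table at a common depth; mixing depths is
refused rather than approximated.

## Assembly-process partition

Taxa are grouped into phylogenetic bins by complete-linkage clustering of
patristic distances cut at ds = 0.2 substitutions/site, with bins smaller
than 24 taxa merged into the bin at smallest mean between-bin distance
(both defaults follow the convention of the established binning framework
and are configurable). Complete linkage guarantees the within-bin distance
ceiling wherever the cut produces a cluster.

Per within-group sample pair and bin:

* **βNRI** — abundance-weighted βMPD (Σᵢⱼ wxᵢ wyⱼ dᵢⱼ with within-bin
  normalised weights) is compared to a null that shuffles taxon identities
  across the bin's tips (999 draws by default); βNRI is the z-score. A
  zero-variance null (e.g. a star subtree) yields βNRI = 0 with a warning.
  Unweighted mode is available.
* **RC** — null communities are reassembled per sample by drawing the
  observed bin richness (taxa chosen ∝ occurrence frequency) and filling
  individuals to the observed bin abundance (∝ mean relative abundance);
  RC = 2·[#(null BC < obs) + ½·#(ties)]/n_null − 1.

Classification follows the standard order: |βNRI| > 1.96 ⇒ selection
(heterogeneous if positive, homogeneous if negative); otherwise RC > 0.95 ⇒
dispersal limitation, RC < −0.95 ⇒ homogenising dispersal, else drift.
(The published condition for homogenising dispersal is sometimes printed
with a vacuous |βNRI| ≥ −1.96 clause; the order above is the standard
resolution.) Pair-level fractions weight each bin by its share of the
pair's summed relative abundance; group fractions average over pairs. RC is
computed per bin (community-wide mode is an explicit option), and the pair
universe is within-group (cross-group mode available).

Performance: within `partition_assembly` the βMPD null permutations are
shared across pairs within a bin, and RC null communities are generated
once per (sample, bin), making the cost linear in samples rather than
pairs. The standalone `bnri`/`rc_bray` functions generate their own nulls.

**Calibration and its limits.** Both nulls are well calibrated per
pair-bin: under their own null processes, βNRI is standard-normal-like and
RC is centred (checked by dedicated tests). Whole-survey process fractions
are nonetheless volatile across simulated surveys, because all pairs share
one realised assignment of abundances to the phylogeny: if a bin's dominant
taxa happen to sit clustered on the tree, every pair in that bin crosses
the selection threshold together. Averaged over replicate surveys the
spurious selection fraction is at the nominal few-percent level, and the
acceptance script therefore reports fractions averaged over five surveys.
Detecting injected selection requires the selected clade to be nested
*inside* a bin (uniform boosts to an entire bin cancel in the within-bin
weights) and to differ across the samples being compared.

## Co-occurrence networks and keystones

Per group: taxa are pre-filtered to prevalence ≥ 20% and mean relative
abundance ≥ 0.01% (sparse vectors make rank correlations unstable; both
thresholds exposed), then all pairs are screened with Spearman correlation
(average ranks for ties, two-sided t-approximation p) and BH-adjusted.
Edges require |ρ| > 0.6 **and** q < 0.05, both strict as printed in the
reproduced analysis class. Constant taxa are untestable and skipped.

Modules are Louvain partitions on |ρ| weights (networkx implementation,
seeded; module ids stable-sorted by size). Topology reports node/edge
counts, average degree 2E/N, unweighted diameter of the largest connected
component (the practical convention for disconnected graphs), modularity,
module count and the positive-edge fraction. Zi (within-module degree
z-score) and Pi (participation coefficient, 1 − Σ(k_is/k_i)²) use
unweighted degrees, following the original role taxonomy; roles use
Zi = 2.5 and Pi = 0.62 as strict thresholds, and every non-peripheral node
is a keystone.

## Core microbiome and isolate matching

Prevalence is computed over all samples pooled; the core rule is the
inclusive OR: prevalence ≥ 85% or mean relative abundance ≥ 0.1%. Keystone
sets from per-group networks are intersected with exact Venn-region
accounting. Candidates in both the all-group keystone intersection and the
core set are ranked by (prevalence, mean abundance) descending with taxon
id as tie-break.

Isolate-to-ASV matching is global Needleman–Wunsch alignment (match +1,
mismatch −1, gap −2 by default — appropriate for near-identical 16S
fragments; configurable). Identity is reported both over all aligned
columns and over substitution columns only; the two coincide for the
gapless alignments typical of this comparison. A reverse-complement
orientation check is available and reports the orientation used.

## Synthetic-data generator

What it emulates: a log-series metacommunity (shape 0.999, the heavy tail
typical of soils); local communities drawn from Sloan's stationary beta
marginal, jointly renormalised, and sequenced as fixed-depth multinomials;
a pure-birth phylogeny rescaled to root height 0.3 substitutions/site so
patristic distances sit on the scale of a 16S gene tree and the default
bin ceiling (0.2) delineates genuine clades; clade-level selection as a
multiplicative fitness factor applied to expected counts with depth
preserved; and 16S-like sequences evolved along the tree by per-site
Jukes–Cantor-style substitution (no indels, so alignment length is fixed;
default length 427 to mirror the isolate-comparison scale).

The local community size N and the sequencing depth are distinct
parameters (default equal): the beta marginal depends only on the product
Nm, so surveys with Nm above the sequencing depth are generated with m = 1
and a larger N.

What it does not emulate: PCR/primer bias, chimeras, read-level error,
kingdom-specific differences, or Hubbell-style birth–death dynamics (the
stationary beta is sampled directly — it is the exact distribution the
neutral fit assumes, which is what makes parameter recovery a clean
oracle, at the cost of not testing convergence to stationarity).
Consequently, passing tests demonstrate the statistical machinery is
correct and calibrated under the stated models, not that real surveys
satisfy those models.

The planted-core benchmark (`simulate_planted_core`) is a latent-factor
log-normal/multinomial community: one high-abundance hub taxon tracks a
shared factor tightly; 28 "spoke" taxa track it loosely enough (pairwise
spoke correlation ≈ hub–spoke² ≈ 0.45 < 0.6 < hub–spoke ≈ 0.65) that the
hub accumulates within-module degree while spokes stay sparse, making the
hub a module hub (Zi > 2.5) in every group's network; three tight blocks
per group form ordinary modules, and a broad stable background dominates
the sequencing denominator so compositional closure does not erode the
planted correlations. Loadings were chosen for reliable discrimination of
the planted structure, not for realism.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at deliberately modest sizes chosen as the
package's own trade-off between statistical resolution and turnaround:
neutral-model recovery at S = 300 taxa × 300 samples × depth 1000 (20
seeds per Nm value in the test suite, 10 replicates in the script);
assembly partitions at 150 taxa × 20 samples with 199 nulls; null-model
self-calibrations at 200 replicates; PERMANOVA calibration at 200
simulations × 199 permutations. All random streams derive from explicit
seeds, and every generator is a pure function of (parameters, seed).

## Known limitations

* The threshold-detection neutral fit is biased off the Nm ≈ depth regime
  (see above); it remains available for comparability only.
* Whole-survey assembly fractions carry the shared-assignment volatility
  described above; single-survey fractions should be read with that in
  mind.
* Raup–Crick nulls condition on observed richness and abundance; very
  small bins (a handful of taxa) give coarse, tie-heavy RC values.
* Louvain module assignment is seed-stable but not unique; Zi–Pi roles
  near the thresholds can flip under a different partition.
* The alignment scorer is tuned for near-identical 16S fragments; distant
  homologs would need different gap scoring.
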