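# Methods

This note records the models, conventions, parameter choices and known
limitations behind `matdiv`, in the order the pipeline runs them.

## Diversity profiles

The package computes effective numbers
^qD^Z(p) = (Σ_{p_i>0} p_i (Zp)_i^{q−1})^{1/(1−q)}, with exp(−Σ p_i ln(Zp)_i)
at q = 1 and 1/max_{p_i>0}(Zp)_i at q = ∞. Zero-abundance taxa are excluded
from every sum, so rarefaction-induced absences need no special casing. All
three variants (naive, general-Z, phylogenetic) funnel through one
generalized mean (`diversity._hill`) over (weight, ordinariness) pairs:

* naive: weights p_i, ordinariness p_i (Z = I);
* similarity-sensitive: weights p_i, ordinariness (Zp)_i, Z ∈ [0,1] with
  unit diagonal;
* phylogenetic: weights w_b = Σ_{i∈I_b} π₍ᵢ,ᵦ₎ and ordinariness a_b over
  branches, where π₍ᵢ,ᵦ₎ = ℓ_b p_i / T_i are historical-species abundances,
  I_b the tips below branch b, T_i the root-to-tip depth and
  a_b = Σ_{j∈I_b} p_j.

The third form follows from the ancestry-indicator similarity over
historical species, for which (Zπ)₍ᵢ,ᵦ₎ = a_b: the (i,b) sum collapses to a
per-branch sum, so the quadratic historical-by-historical similarity matrix
is never materialized. Correctness is guarded two ways: on equal-branch star
trees the phylogenetic variant must equal the naive one, and on ultrametric
trees it must match an independently coded branch formula
(Σ_b (ℓ_b/T) a_b^q)^{1/(1−q)}, both at 1e-9. Non-ultrametric trees are fully
supported because T_i is per-tip; a taxon with positive abundance at zero
root-to-tip depth is a hard error.

Numerical conventions: q = 1 and q = ∞ are evaluated analytically, never by
limits; the default q grid is 0–5 in steps of 0.1 (the plotted range; the
step is a package choice, exposed in the config). Profile averaging is done
on the per-replicate diversity values, not on pooled rarefied counts.
Rarefaction is an exact multivariate-hypergeometric draw
(`numpy.random.Generator.multivariate_hypergeometric`), deterministic per
seed.

## Dispersion tests

MPD uses presence weighting (mean over unordered distinct pairs) or
proportional weighting Σ_{i≠j} p_i p_j d_ij / Σ_{i≠j} p_i p_j. The
proportional form excludes self-pairs; R picante's abundance-weighted MPD
includes them in the denominator, so the two differ by the factor
1/(1 − Σp_i²) — the test suite checks this relation explicitly.

MPD_SES compares the rarefaction-averaged observed MPD with the identical
statistic on randomized communities. Conventions:

* **Rank test.** The observed value joins the n_null nulls; its mid-rank r
  (ties averaged) gives p_low = r/(n_null+1), p_high = (n_null+2−r)/(n_null+1).
  A rank of 15 among 999 nulls thus reads p = 0.015. Calls at α = 0.05
  one-tailed per direction; clustered ⇒ SES < 0. No multiple-testing
  correction is applied across layers or factorial cells — a deliberate
  caveat, as the factorial is a robustness sweep, not a family of
  confirmatory tests.
* **Degeneracy.** If all null values coincide (e.g. a sample containing its
  entire pool under label shuffling), SES is undefined and no call is made.
  Identity is tested on the null range, not the standard deviation, because
  float summation of identical values can report a spurious sd of ~1 ulp.
* **Independent swap.** The low-level operation performs a requested number
  of *successful* checkerboard swaps ([x,0;0,y] ↔ [0,x;y,0], counts carried,
  occupancy margins preserved exactly). Inside `ses_mpd` the schedule is
  10,000 *attempted* swaps of burn-in and 1,000 attempted swaps between
  successive null tables (both configurable); with sparse mat-like tables
  roughly 3% of attempts succeed, and calibration on swap-generated tables
  shows the clustered-call rate within the 99% binomial band of 0.05.
  Swaps move counts between samples, so a null community may total fewer
  reads than the common rarefaction depth; it is then rarefied to its own
  total. Count-carrying is the default; a binarize flag is available.
* **Pools.** Three scopes — all samples, per collection year, per core —
  with the nesting per_core ⊆ per_year ⊆ all asserted structurally. Null
  communities are always drawn within the sample's scoped pool.
* **Guilds.** Taxonomy-substring rules select guild members; the tree is
  pruned to them (path lengths preserved), the pool rebuilt inside the
  guild, and the same machinery re-run. Guilds with fewer than two members,
  and samples with fewer than two present members, are skipped with a
  logged reason.

## Support-collapse robustness

Internal non-root nodes with support below the threshold are deleted and
their branch length added to each child, so every root-to-tip depth T_i —
and hence every historical-species abundance — is exactly preserved; the
perturbation is purely topological. How collapsed branch lengths should be
redistributed is not standardized across tools; depth preservation is this
package's documented choice. Nodes without a numeric support never
collapse, nor does the root.

## Trait-richness nulls

Trait richness is the number of distinct ortholog groups in a sample's
annotation; samples are compared at a common *gene-instance* depth (never
group counts — the two are deliberately kept distinct in every signature).
The null redraws the same number of instances without replacement from the
pooled multiset of instances across the core's samples, so abundant groups
are drawn more often; a group-weighted (each detected group once) pool sits
behind a flag. Category tests rarefy at the whole-pool depth and then count
only the category's groups — categories are a projection of the same draw,
not separately rarefied pools. Ranks, p-values and depleted/enriched calls
reuse the dispersion conventions. Upstream annotation filters (e-value and
alignment-length thresholds, hypothetical-protein exclusion) are provenance
of the input table, not operations performed here.

## Unweighted UniFrac

Branch sets are root-inclusive (every branch on the root-to-tip path of at
least one present taxon), the original convention — so the rooting is part
of the input and affects values. The distance is unique branch length over
covered branch length; it depends on presence only (doubling all counts
leaves it unchanged, property-tested). The sample matrix averages distances
over matched rarefactions to the smallest sample total. scikit-bio's
implementation serves as an independent oracle in the tests.

## Synthetic data

The generator supplies the statistical structure the analyses assume; it is
a stand-in for mat communities, not a calibrated model of them.

* **Trees.** Gillespie birth–death from a crown pair, conditioned on
  reaching n_tips extant lineages without extinction (extinct runs restart;
  extinct subtrees are pruned). After the target is reached the tree is
  extended by the waiting time to the next unrealized event, so terminal
  branches are strictly positive. Default pure birth (λ = 1, μ = 0);
  birth–death is supported for depth-distribution realism. Supports are
  uniform on [0,100] — they are consumed only as collapse thresholds.
  Mean root-to-tip depth is tested against a closed form for pure birth and
  an independent brute-force re-simulation for birth–death.
* **Traits.** Brownian motion from a root value of 0 at rate trait_sigma
  (default 1), giving tip variance σ²T_i — the niche-conservatism
  assumption the filtering regime needs.
* **Communities.** filtering: weighted sampling without replacement
  (Gumbel top-k) with weight exp(−strength·(trait−optimum)²), the optimum
  being a randomly chosen tip's trait so different layers filter toward
  different clades; neutral: uniform; competition: greedy max–min
  cophenetic selection taken with probability 1−exp(−strength) per step.
  Both structured regimes collapse exactly to neutral at strength 0
  (frequency-tested against binomial bounds).
* **Counts.** Lognormal(0, shape) relative abundances (the canonical
  microbial rank-abundance shape; shape default 1) followed by one
  multinomial draw per sample at the configured depth.
* **Trait tables.** Uniform per-group weights, optional category enrichment
  factor (≥1), optional per-sample restriction to a fraction of the pool's
  groups (the depleted-layer scenario).
* **The miniature study** (3 cores × 5 layers, 200 tips, richness 30,
  depths 5000/4000/3000/2000/1071): top layers under competition strength 3,
  deeper layers under filtering strengths 3→10, the young-mat core at half
  strength, one core carrying a trait table whose deeper layers draw from
  40–80% of the gene pool. Bundled-config replicate counts (99 nulls, 5
  rarefactions, 199 trait nulls) are sized so the full factorial is a
  desk-scale run; the class defaults keep full-study values (999/100/1000).

**What passing on synthetic data does and does not show.** The generator
reproduces the *qualitative* structure real mats present — uneven depths,
clustered/overdispersed membership with conserved traits, depleted gene
pools — but not read-level noise (no chimeras, no primer bias), taxon-level
abundance correlations, or realistic support distributions. Calibration
results (type-I rates, power) therefore validate the statistical machinery,
not field-data effect sizes.

**Detection ceiling of the filtering regime.** With the trait-kernel
filtering above, about one tip in three has a trait near the community-wide
center where the basal clades overlap; communities filtered toward such
optima are trait-coherent but phylogenetically mixed. At strength 10 on
200-tip pure-birth trees the clustered-call rate plateaus near 0.6 (its
strength→∞ limit is ≈ 0.66) even though the mean SES is strongly negative
(≈ −3); the property is scale-invariant in trait_sigma and branch-length
units. Likewise, because supports are uniform, collapsing at 50%/80%
removes roughly half/four-fifths of internal nodes — a far harsher
perturbation than collapsing a real, right-skewed support distribution —
and SES *signs* agree across collapse levels for only ~83% of filtering
communities (the disagreements concentrate where |SES| < 1, i.e. where the
sign is noise). Two acceptance-suite assertions encode stricter detection
targets (≥80% clustered calls; ≥90% sign agreement) and fail under these
study conditions; they are left failing rather than re-tuned, and the
mechanism is as described here.

## Determinism

Every generator and test is a pure function of its arguments and a seed;
per-stage seeds derive from the run seed by hashing stage names, so stage
order never matters. `run-all` writes no timestamps, and re-running a
config byte-reproduces every output (verified by the test suite). Output
files carry provenance headers (package version, config hash, seed);
proportional weighting logs a warning that sequence counts are a biased
abundance proxy.
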