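# matdiv

Phylogenetic diversity profiles, community-phylogenetics null models, and
trait-richness nulls for millimeter-scale layered microbial communities.

Laminated microbial mats stack sharply distinct geochemical niches within a
few millimeters: oxygenic phototrophs at the surface, purple sulfur bacteria
and sulfate reducers below. `matdiv` implements the analysis stack used to
ask how such communities assemble — whether each layer is a random draw from
the regional taxa pool, a phylogenetically *clustered* subset (the signature
of habitat filtering acting on conserved niches), or an *overdispersed* one
(the signature of limiting similarity) — and whether a layer's functional
gene repertoire is richer or poorer than a random slice of the core's gene
pool. It is aimed at microbial ecologists working from an OTU count table, a
rooted phylogeny with support values, a taxonomy map, and (optionally) an
ortholog-annotation table.

## What it computes

**Similarity-sensitive diversity profiles.** For a community with relative
abundances **p**, the effective number of order *q* is

    ^qD^Z(p) = ( Σ_{i: p_i>0} p_i (Zp)_i^{q-1} )^{1/(1-q)}

with the analytic limits exp(−Σ p_i ln (Zp)_i) at *q* = 1 and 1/max (Zp)_i
at *q* = ∞. With **Z** = **I** these are the naive Hill numbers (*q* = 0 is
richness *S*; *q* = ∞ the reciprocal Berger–Parker index). The phylogenetic
variant ^qD^Z(π) works on *historical species* (*i*, *b*) — an extant taxon
*i* paired with a branch *b* on its root-to-tip path — with abundances
π₍ᵢ,ᵦ₎ = ℓ_b · p_i / T_i and ordinariness (Zπ)₍ᵢ,ᵦ₎ = a_b, the relative
abundance of the clade below *b*. Profiles are plotted over *q* ∈ [0, 5]
and averaged over rarefied subsamples so unevenly sequenced layers are
comparable. Trees need not be ultrametric (T_i is per-tip); on ultrametric
trees the profile reduces to the branch-length formula
(Σ_b (ℓ_b/T) a_b^q)^{1/(1−q)}.

**Phylogenetic dispersion (MPD_SES).** The mean pairwise cophenetic distance
of each layer, rarefaction-averaged, is compared against 999 randomized
communities: MPD_SES = (MPD_obs − μ_null)/σ_null. Three randomizations are
provided — `independent_swap` (checkerboard swaps of the taxa × sample
table, preserving occupancy margins), `phylogeny_pool` (random draws of the
observed richness from the taxa pool), and `taxa_labels` (label shuffles of
the distance matrix) — crossed with three taxa-pool scopes (all samples /
per collection year / per core), presence or proportional weighting, and
support-threshold polytomy collapsing (50%, 80%) as a topology-robustness
check. Significance is a one-tailed rank test at α = 0.05 per direction;
guild-level tests prune the tree to taxonomy-defined guilds first.

**Trait-richness nulls.** Ortholog-group (KO/COG/NOG) richness per layer is
rarefied to a common gene-instance depth and compared with 1,000 re-sampled
sets drawn without replacement from the core-wide instance pool, overall and
within gene categories (photosynthesis, sulfur metabolism, ...).

**Beta diversity.** Unweighted UniFrac distances between matched-rarefied
layers, emitted as a labeled matrix for external clustering or ordination.

Because the motivating datasets cannot be bundled, the package ships a
first-class synthetic generator (`matdiv.synthetic`): birth–death trees with
bootstrap-like supports, Brownian niche traits, and per-layer communities
assembled under habitat filtering / neutrality / limiting-similarity
regimes of tunable strength, plus ortholog tables with per-category pools.

## Worked example

```bash
python analysis/01_simulate_study.py   # 3 cores x 5 layers, 200 OTUs
python analysis/03_dispersion_nulls.py
```

The simulated study assembles the top layer of each core under mild
competition and deeper layers under increasingly strong filtering, then runs
the full dispersion factorial (3 null models × 3 pools × 2 weightings × 3
collapse thresholds). The second command prints:

```
mean SES and clustered-call rate by generating regime and null model:
                              mean_ses  clustered
regime      null_model
competition independent_swap      0.61       0.00
            phylogeny_pool        0.74       0.00
            taxa_labels           0.73       0.00
filtering   independent_swap     -1.04       0.21
            phylogeny_pool       -0.82       0.17
            taxa_labels          -0.79       0.16
```

Competition-assembled surface layers sit above the null mean (positive SES,
never called clustered) and filtering-assembled deep layers below it, with
clustered calls concentrating in the strongest-filtered layers — the
depth-structured dispersion pattern the method is built to expose. (The
fixture mixes strengths 1.5–10, so the average call rate is far below the
strength-10 detection rate.) `02_diversity_profiles.py`,
`04_guild_dispersion.py`, `05_trait_richness.py` and `06_beta_diversity.py`
continue the narrative: e.g. the trait stage prints every restricted deep
layer as `depleted` (observed 240–480 distinct KO groups against a null
mean of ≈ 599.5), and the UniFrac stage finds the two old-mat surface
layers most similar (d = 0.145) across cores.

The same stages are scriptable via the CLI (`matdiv simulate | profile |
dispersion | traits | unifrac | run-all`) from a flat key = value config;
`run-all` writes a manifest and is byte-reproducible under a fixed seed.

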