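# Methods

`symdiv` models the analysis chain for ITS2 amplicon profiling of
Symbiodiniaceae communities in coral early life stages under heat stress:
collapsing intragenomic sequence variants onto DIV profiles, community
diversity statistics, and interval-monitored survival. Because every
statistic is exercised on a built-in generator with known structure, the
package's tests measure operating characteristics (calibration, power,
recovery) rather than re-describing any one dataset.

## The DIV overlay

ITS2 is a multi-copy marker: one Symbiodiniaceae genome carries several
distinct sequence variants, so a single symbiont taxon appears in a
denoised variant table as a family of co-occurring columns (a DIV profile
such as `C15-C15dq-C15dr-C_1365`; members joined by `-`, variant names may
contain `_` but never `-`). Diversity computed on raw variant columns
over-counts taxa; profile-calling pipelines that fix this typically also
discard low-abundance background sequences, which hides exactly the taxa
expected to expand under stress in repeated-measures designs. The overlay
keeps both properties:

1. **Dominance.** Per sample, a profile member is *detected* when its
   reads are at least `detection_fraction` (default 0.01) of the summed
   reads over all registered member variants in that sample. The dominant
   profile is the registered profile with the most members among those
   fully detected; ties break by summed member count, then name. A sample
   exhibiting no registered profile falls back, flagged, to the singleton
   of its most abundant variant. Detection is relative rather than
   absolute so a sample can be dominated by bare `C15` while carrying
   trace `C15dq` reads that stay in their own column. The external
   profile-caller's own member-inclusion rule is not public; this relative
   rule is the package's documented stand-in, and externally computed
   dominance can be supplied as a two-column TSV instead.
2. **Collapse.** The members of the sample's *own* dominant profile are
   summed into one column named by the profile; every other variant —
   trace members outside the dominant profile and all background
   variants — keeps its reads in an individual column. Row totals are
   conserved exactly (integer equality, a tested invariant).
3. **Background labelling.** Columns whose dataset-wide total is ≤
   `background_read_threshold` (default 200 reads) are *labelled*
   background, never removed. Whether the 200-read rule should apply
   per sample or dataset-wide is ambiguous in the source material;
   dataset-wide was chosen and documented. Samples under
   `low_depth_threshold` (default 1000 reads) are flagged; dropping them
   is an option, default off.
4. **Co-occurrence inference** (optional): variants above the read
   threshold are greedily agglomerated into candidate profiles when the
   Jaccard similarity of their per-sample detection vectors (detected =
   relative abundance ≥ `detection_fraction`) is ≥ 0.9 with every current
   member. This is a deliberately simplified emulation of
   co-occurrence-based profile discovery, adequate for nested families on
   simulated data; it is not a replacement for a real profile caller.

## Diversity statistics

* **Shannon index** H = −Σ pᵢ ln pᵢ in nats, zero categories excluded
  (the base is a convention; nats are the package default).
* **Evenness and the unit interval.** Beta regression needs a (0,1)
  response, but H is bounded by ln(richness) > 1. The default maps H to
  Pielou evenness H/ln(S_total) with S_total the dataset-wide column
  count, then applies the boundary squeeze (y(n−1)+0.5)/n; squeezing raw
  values already in [0,1] is available separately. Which variant a given
  study used is usually unstated; both are exposed.
* **Beta regression** (logit mean link, single log-linked precision φ) is
  fit by ML via statsmodels' `BetaModel` (BFGS from method-of-moments
  starts); SEs come from the inverse observed information. Boundary
  responses are rejected, non-convergence is flagged.
* **Pairwise contrasts** are Wald z statistics on logit-scale mean
  differences, Holm-adjusted. Their default null reference is a
  label-permutation distribution (model refit per permutation, +1
  convention): at n ≈ 20 per group with boundary-adjacent evenness values
  the asymptotic normal reference measurably over-rejects (≈0.08 at
  nominal 0.05 in the package's own null calibration; LR and t variants
  ≈0.075), while the permutation reference is exact under group
  exchangeability (measured ≈0.055). The normal reference remains
  available via `p_mode="wald"`. Holm replaces Tukey's HSD because the
  studentized-range distribution is not defined for beta-regression
  contrasts.
* **Bray-Curtis** d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ), via scipy's `pdist`.
* **NMDS** minimises Kruskal stress-1 by alternating isotonic (PAV, ties
  averaged) regression of configuration distances on the input
  dissimilarities with Guttman-transform updates. Defaults: 20 restarts
  (one seeded from the classical/PCoA embedding, the rest Gaussian),
  tol 1e-6 on stress, 300 iterations max; an iteration that would raise
  stress terminates the restart, so stress is non-increasing by
  construction; the best restart is returned, deterministic under seed.
* **PERMANOVA** pseudo-F from squared-dissimilarity sums
  (SS_total = (1/n)Σ_{i<j} d²ᵢⱼ; within-group analogues per group), one
  factor only, tested by permuting group labels with the +1 convention.
  Small designs can be tested exhaustively (every distinct labeling
  enumerated; the identity labeling is included, so the exact p is the
  tail proportion).
* **ANOSIM** R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) over the ranks (ties averaged) of all pairwise
  dissimilarities; permutation p as above.
* **Dispersion (betadisper-style).** The distance matrix is embedded by
  principal coordinates; if negative eigenvalues arise, a Lingoes-style
  additive correction (add 2·|λ_min| to off-diagonal squared distances)
  restores positive semi-definiteness. Each sample's Euclidean distance
  to its group *centroid* (mean — the simpler of the two common options)
  feeds a one-way ANOVA F with a parametric p and an optional permutation
  p. On Euclidean inputs the embedding reproduces the original distances
  and the F matches vegan's `betadisper(..., type="centroid")` to
  numerical precision.

All permutation p-values use p = (#{permuted ≥ observed}+1)/(n_perm+1)
and are reproducible under an explicit seed.

## Survival

Individuals are checked at scheduled visits; one absent at visit t and
present at the previous visit is scored dead at t (right endpoint of the
interval — interval-censored likelihoods are out of scope). The
Kaplan-Meier product-limit estimator (via lifelines) reports S(t), a
median defined as the smallest t with S(t) ≤ 0.5 (NaN when never
reached), and informational Greenwood/log-log 95% intervals. The
two-group log-rank test is computed directly — observed, expected and
hypergeometric-variance terms per event time are exposed — with a
chi-square (1 df) p and an optional seeded permutation p; it matches
lifelines on shared instances.

## The synthetic-data generator

The generator emulates the statistical structure of the study system, not
its sequences:

* **Community.** Every sample hosts the nested family C15 (0.70), C15dq
  (0.15), C15dr (0.10), C_1365 (0.05) — proportions of the host-profile
  fraction, invented but consistent with a nested family — plus 8
  background variants spanning *Symbiodinium*, *Breviolum*,
  *Durusdinium*, *Fugacium* and extra *Cladocopium*, totalling 3% at
  baseline (the source reports only "< 5%"; 3% split evenly is the
  package's choice). Heat multiplies expected background abundance by 8
  in larvae and 1 in juveniles; the larval value is a calibration chosen
  so the effect is detectable at 20 samples/group while the juvenile null
  holds, not a measured quantity. Realised compositions are Dirichlet
  around the cell expectation with concentration 100 (moderate
  compositional overdispersion, a realistic middle ground: large enough
  that the dominant family is always detected, small enough that
  replicate samples scatter visibly); counts are multinomial at a
  log-normal library size (median 5000 reads, log-sd 0.4, matching
  typical post-filter amplicon depths).
* **Survival.** Latent death times are exponential per stage × treatment
  cell — the simplest model matching only a median — with heat medians 20
  d (juveniles) and 57 d (larvae) and ambient medians 200 d. Ambient
  medians are acknowledged inventions: the source shows high ambient
  survival but prints no number, and 200 d pushes most ambient
  individuals past the end of monitoring into censoring. Default
  schedules: 21 larval visits over 0–57 d, 3 juvenile visits over 0–20 d.
  Observed times are discretised to the first visit ≥ the latent time, or
  censored at the last visit. With the default schedules ending near the
  heat medians, KM medians are frequently undefined (S(end) ≈ 0.5) —
  deliberate, as the real experiments terminated at ~50% survival;
  calibration checks therefore use dense daily grids (to day 80/120).
* **Seeding.** One global seed drives independent community and survival
  substreams, so either half can be regenerated alone.

What the generator does *not* emulate: sequencing error, chimeras, PCR
amplification bias, compositional correlations between specific
background genera, family (cross) structure in communities, or
non-exponential hazards. Passing tests therefore demonstrate that the
statistics are implemented correctly and behave as expected *given* this
structure — not that the pipeline is robust to artifacts real amplicon
data can contain.

## Problem sizes and numerical choices

Calibration experiments use 500 null replicates at 20 samples/group
(PERMANOVA with 999 permutations; contrasts with 199), power and recovery
experiments 100 replicates, and survival calibration 500 individuals per
cell — sizes at which Monte-Carlo error is small relative to the bands
being checked while the whole suite stays interactive. At n = 500 the
larval KM median has a sampling SD near 3.7 d (S(57) has SE ≈ 0.022 and
the hazard is shallow), so single-draw medians scatter by several days
around the configured 57; this is a property of the design, not of the
estimator. Degenerate inputs are rejected loudly (all-zero abundance
vectors, boundary beta responses, zero-total samples in Bray-Curtis,
groups smaller than 2 in permutation tests); exhaustive permutation mode
is intended for n ≲ 8; dominance ties break deterministically (member
count, then summed count, then name) for reproducibility.
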