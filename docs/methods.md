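# Methods

This note records the statistical model behind `chipsip`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Measurement model

A Chip-SIP experiment hybridizes isotope-labeled rRNA to a phylogenetic
microarray; each taxon is represented by a probe set (typically 5–30
spots). Two quantities are measured per spot: fluorescence (hybridization
strength, from a separately labeled, pooled-treatment hybridization) and
¹⁵N enrichment from NanoSIMS ion counts, expressed as

δ¹⁵N (‰) = (R_meas / R_standard − 1) × 1000,  R = ¹⁵N/¹⁴N,

with R_standard taken from unhybridized array regions. When raw counts are
supplied, replicate measurements are aggregated as the ratio of summed
counts rather than the mean of ratios — the Poisson-stable choice for
ion-counting data. Default R_standard is the natural-abundance ratio
0.003677 and is configurable.

Because hybridization efficiency scales fluorescence and isotope signal
together, spot δ is modeled as linear in fluorescence within a taxon and
treatment:

δ_ij = a_t + h_t · F_ij + ε_ij,

and the OLS slope h_t — the hybridization-corrected enrichment, HCE, in ‰
per fluorescence unit — is the taxon's incorporation measure under
treatment t ∈ {H, M, L} (5 µM, 500 nM, 50 nM added substrate). The slope's
OLS standard error is carried everywhere; plotted error bars span two
standard errors. One fluorescence value per probe is shared across the
three treatments, mirroring the pooled fluorescent labeling; per-treatment
fluorescence columns are accepted if a dataset has them.

**Enrichment flag.** "Significantly enriched" is operationalized as a
one-sided t-test of h_t > 0 at α = 0.05 (df = n_spots − 2) combined with
mean δ > 0; both pieces are configurable. A degenerate exact fit
(SE = 0) with positive slope counts as enriched. This is a declared,
testable stand-in for informal "conservative criteria": its purpose is to
exclude taxa indistinguishable from background.

## Classification

**Activity.** Taxa enriched at the reference concentration (default H) are
ranked by HCE; the HIGH/LOW split is at `activity_cutoff_fraction` × the
maximum (default 0.5). The ranked percent-change series is returned so the
user can check that the cutoff falls at a local high of that series, the
diagnostic that motivates the 50 % rule on lognormal-shaped HCE
distributions.

**Guilds.** Per taxon, the concentration effect is tested with an ANCOVA:
full model δ ~ fluorescence + treatment + treatment×fluorescence against
reduced model δ ~ fluorescence, by a joint F-test, so either a slope (HCE)
shift or an intercept shift registers. A common-slope (intercept-only)
variant is available via `ancova_model="intercept"`. Post-hoc, each pair
among (H,M), (H,L), (M,L) is tested with the same two-level ANCOVA; a pair
counts only if significant at α *and* the higher concentration's fitted
HCE exceeds the lower's — lower substrate availability should not drive
higher incorporation, so reversed contrasts are discarded rather than
interpreted. Pairwise tests are uncorrected by default (matching the
procedure the guild taxonomy was built with); `posthoc_correction="holm"`
is the conservative switch.

Decision table (total and deterministic):

| condition                                           | guild        |
|-----------------------------------------------------|--------------|
| overall p ≥ α                                       | NULL_HML     |
| (H,M) and (M,L) significant                          | COPIOTROPH   |
| (M,L) or (H,L) significant, (H,M) not                | INTERMEDIATE |
| anything else (incl. H>M≈L, direction-only patterns) | OTHER        |

OTHER exists to make the map total without distorting the three-guild
taxonomy; OTHER taxa are reported but excluded from guild tallies'
phylogenetic characters. Taxa with fewer than two usable treatment levels
are excluded and logged; with exactly two levels, the same table applies
to the computable pairs and the result is flagged partial.

## Ternary representation

Enriched taxa's (HCE_H, HCE_M, HCE_L) triplets are normalized to their sum
after flooring negative components (possible from regression noise) to
zero, since barycentric coordinates must be nonnegative; a taxon with no
positive component is excluded with a warning. Vertex orientation is fixed
(H apex at (0.5, √3/2), M at the origin, L at (1,0)) so layouts and the
coordinate columns in the results table are deterministic; the transform
is x = w_L + w_H/2, y = (√3/2)·w_H.

## Phylogenetic signal

Each guild defines a binary membership character on the leaves of the
(unrooted) 16S tree. The observed statistic is the parsimony score —
the minimum number of state changes — computed by Hartigan's frequency
generalization of the Fitch algorithm: at each internal node, keep the
states carried by the largest number of child state-sets at a cost of
(children − that count). On bifurcating trees this is exactly Fitch's
intersection/union rule; on polytomies, unlike naive pairwise
intersection, it still yields the true minimum (verified in the test suite
against exhaustive minimization over all internal assignments on every
≤ 6-leaf topology). The score is invariant to rooting, so the traversal
roots arbitrarily.

The null distribution reshuffles the observed states across tips uniformly
at random (preserving state counts) `n_reshuffles` times (default 1000)
and rescores; scoring is vectorized across permutations (bitmask state
sets, one postorder sweep for all permutations), so 1000 reshuffles on a
100-leaf tree take milliseconds. Significance is reported two ways:

* `p_empirical` = (1 + #{null ≤ observed}) / (1 + n), one-sided, since
  clustering means fewer changes than random placement. This is the
  headline decision statistic; the +1 convention keeps it valid under
  discreteness (it can never be 0) at the price of slight conservatism.
* `p_ftest`: F = (observed − null mean)² / null variance on (1, n−1)
  degrees of freedom — a variance-ratio comparison of the observed
  deviation to the null spread, reported because comparing an observed
  score to a randomization null with an F-test is an established (if
  statistically unusual) convention in this analysis tradition. It is NaN
  for a zero-variance null; `p_empirical` remains defined.

Ancestral states come from Hartigan's down-pass (root takes the
lowest-index state in its set; children inherit the parent state when
possible); nodes whose state set has more than one member are flagged
ambiguous. The reconstruction's implied change count equals the parsimony
score (tested).

Guilds with fewer than two members on the tree, or constant characters,
are skipped with a warning; taxa classified OTHER, and taxa absent from
the tree, are excluded from characters and reported.

## Synthetic-data generator

The generator is the package's study-condition definition, not a tuning
surface. It emulates: per-taxon probe sets with lognormal fluorescence
(log-mean log 30, log-sd 0.6 — spot values of tens of scanner units,
giving δ of a few hundred ‰ at slope 10); a shared fluorescence per probe
across treatments; linear δ-vs-fluorescence structure with slope triplets
by guild, defaults (10,10,10) / (10,10,2) / (10,5,1) ‰·fluor⁻¹ for
NULL_HML / INTERMEDIATE / COPIOTROPH (and (10,2,2) for OTHER-patterned
taxa); homoscedastic Gaussian noise on δ, default sd 10 ‰, set by the
calibration rule that the weakest slope (1 ‰/fluor at 20 probes) keeps
slope/SE ≈ 9, comfortably above the slope/SE ≥ 5 regime the recovery
analyses assume. A heteroscedastic mode scales the noise sd with
fluorescence relative to the lognormal median, bracketing
signal-proportional NanoSIMS counting error. noise_sd = 0 is allowed and
produces exact lines for identity checks; negative values are rejected.

Trees come from sequential random attachment (uniform random edge per new
leaf). Guild labels are either i.i.d. draws from the requested proportions
or, in `clade_seeded` mode, whole clades greedily chosen to approach
integer targets (largest-remainder apportionment; the largest-target guild
is the scattered background), producing characters with parsimony scores
far below their member counts. Unattainable clade splits fall back to
random fill with a warning. All three components draw from independent
streams spawned from one master seed, so a dataset is a pure function of
its seed.

What the generator does **not** emulate: cross-hybridization between
probes, probe-specific affinity differences beyond the shared fluorescence
value, Poisson ion-count noise at the spot level (except coarsely via the
heteroscedastic mode), compositional coupling between taxa, and any
sequence-level realism. Passing recovery tests therefore demonstrate that
the inference chain is correct under its own assumptions — linearity,
independent Gaussian errors, correct probe-taxon assignment — not that
those assumptions hold for a given array.

## Numerical choices

* Nested-model F-tests are computed from residual sums of squares with a
  relative tolerance of 1e−10 on the total sum of squares: an improvement
  below tolerance is "no effect" (F = 0, p = 1), and a full model fitting
  exactly while the reduced does not is an overwhelming effect (p = 0).
  This keeps noiseless data (exact fits on both sides) classified
  correctly instead of producing 0/0.
* R² is clamped to [0,1] and reported as 1 for exact fits where the
  centered total sum of squares vanishes.
* OLS goes through statsmodels on explicitly constructed design matrices
  (reference level H; dummies and fluorescence interactions for the other
  levels present).
* Ties in the activity ranking: the cutoff comparison is ≥, so a taxon
  exactly at 50 % of the maximum is HIGH; equal HCEs sort stably by the
  descending-value sort.
* Parsimony state sets are uint32 bitmasks (≤ 32 states); guild characters
  use 2.

## Default problem sizes

The bundled experiments run at 100 taxa × 20 probes for recovery, 500
replicates for classifier calibration, and 500 trials × 1000 reshuffles on
50-leaf trees for permutation-test calibration — sizes at which the Monte
Carlo error of each reported rate is a small fraction of the margins being
checked, while a full run stays under a minute on one CPU.

## Known limitations

* The post-hoc procedure is pairwise two-level ANCOVAs; contrasts within
  a single fitted model or Tukey-style simultaneous intervals would be
  defensible alternatives and can be slotted behind the same decision
  table.
* The F-style permutation statistic is reported for convention fidelity
  only; its null calibration is not guaranteed and decisions should rest
  on `p_empirical`.
* With only three concentrations the guild taxonomy cannot resolve more
  than the three monotone response shapes; no kinetic parameters
  (e.g. Michaelis–Menten constants) are inferred.
* The reader accepts spot-level summaries only; ion-image processing,
  dead-time/QSA corrections and spot segmentation are upstream of this
  package.
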