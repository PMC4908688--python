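# Methods

`loocomp` analyses paired longitudinal shotgun-metagenomics profiles —
the kind produced by marker-gene species quantification (mOTUs) and
KEGG functional annotation — for a small cohort sampled before and after
an intervention such as bariatric surgery. This note documents the
statistical procedures, the synthetic-data generator used to validate
them, and the numerical and design choices that were genuinely open.

## Relative abundances, filtering, and fold changes

Raw per-sample abundances are converted to relative abundances by
dividing each sample by its **total** abundance, including the
high-quality read mass that could not be annotated to any feature. A
relative table therefore satisfies, per sample,

    sum_j x_ij + u_i = 1,

where `u_i` is the unannotated fraction. Feature filtering keeps a
feature only if it is present (abundance strictly greater than zero) in
at least 10 % of all samples, pooled across time points, **and** its
mean relative abundance over all samples reaches a level-specific floor
(0.01 for taxa, 0.001 for functional units such as KEGG modules and
pathways). Presence uses a strict zero threshold because sequencing
detection limits are not modelled. The mass of removed features is
folded into the unannotated pool so the sum-to-one invariant is
preserved. Filters are deliberately order- and sample-order-invariant.

Fold changes between time points are computed per subject as

    log2((x_t2 + eps) / (x_t1 + eps)),

summarised by the median over subjects. The pseudo-count `eps` defaults
to the smallest nonzero relative abundance observed over the entire
cohort table. It is computed **once** from the full table and reused for
every contrast and inside the leave-one-out test (never recomputed after
renormalisation), which keeps fold changes comparable across exclusions.

## Paired differential testing

Each feature is tested between two time points with a two-sided Wilcoxon
signed-rank test over the subjects sampled at both (the paired design
absorbs the large between-subject variation these cohorts show).
Differences are taken on the relative abundances; zero differences are
discarded before ranking (Wilcoxon's original treatment, the common
statistical-package default). With at most 25 nonzero differences and no
tied magnitudes the P value is exact, computed from the full null
distribution of the positive-rank sum (a dynamic program equivalent to
enumerating all 2^m sign assignments); otherwise a normal approximation
with tie-corrected variance and a continuity correction is used. The
two-sided P is `min(1, 2 x one-sided)`.

One numerical guard matters for the compositionality test below:
differences smaller than `1e-10` of the pair's magnitude are treated as
zeros, so values that are equal algebraically but differ by floating-
point roundoff (as after exclusion and renormalisation of an unchanged
taxon) produce the degenerate result `W = 0, P = 1` rather than a
spuriously consistent sign pattern.

Multiple testing is reported two ways: Benjamini–Hochberg step-up q
values, and Storey q values `q = pi0 x BH`, where the null proportion
`pi0` is estimated from `pi0(lambda) = #{p > lambda} / (m(1 - lambda))`
on the grid `lambda = 0.05, 0.10, ..., 0.95`, smoothed by a
least-squares cubic polynomial evaluated at `lambda = 0.95` and clipped
to `(0, 1]`. The cubic smoother is a deliberate, documented spline-free
choice; on uniform-null P values it recovers `pi0` within a few percent
(checked by simulation at m = 10 000). Significance in reports follows a
fixed unadjusted cutoff `P < 0.05`, with the FDR attained at that cutoff
reported alongside, rather than thresholding on q: with 8–12 pairs the
study is underpowered for stringent q cutoffs and the attained FDR makes
that explicit. Fewer than ten tests fall back to `pi0 = 1` (the Storey
column then equals BH).

## The leave-one-taxon-out compositionality test

Relative abundances are closed (they sum to one), so a genuine change in
one taxon induces apparent opposite changes in all others. The package's
central procedure distinguishes the two: for each focal taxon found
significant, every other retained taxon is excluded in turn, the
remaining taxa are renormalised to sum to one again, and the focal
taxon's median log2 fold change and paired Wilcoxon P are recomputed.
The **least significant** (largest) P over all exclusions is the
robustness score: a closure artifact driven by a single dominant taxon
loses significance the moment that taxon is excluded, whereas a real
change survives every exclusion. A focal feature is `robust` iff its
largest P stays below the same alpha (0.05) used in the main contrast.

Choices pinned here, both of which the procedure's description leaves
open: the unannotated fraction is dropped before the test (the working
table is taxa renormalised to sum to one), and the pseudo-count is not
recomputed per exclusion. Exclusions iterate over **all** retained
features, not only significant ones. The per-exclusion fold-change
"cloud" is exported for plotting, with the most influential exclusion
(largest absolute fold-change deviation from the full-table value)
flagged — in communities with a dominant bimodal taxon (a
*Prevotella*-like distribution: high in some subjects, near-absent in
others) that taxon is typically the most influential exclusion for the
majority of focal taxa.

## Community-level analyses

Ordination is a plain PCA of `log10(x + eps)` relative abundances
(columns centred; `eps` reuses the cohort minimum), with a deterministic
sign convention: the largest-magnitude loading of each component is made
positive. Beta diversity uses the Canberra distance,
`sum_i |u_i - v_i| / (|u_i| + |v_i|)` with both-zero coordinates
contributing nothing — a metric deliberately sensitive to low-abundance
features.

PERMANOVA partitions the Gower-centred inner-product matrix
`G = -0.5 J D^2 J` against a single covariate's design (one-hot for
categorical, centred numeric otherwise): `pseudo-F =
(SS_model/df_model)/(SS_resid/df_resid)`, `R^2 = SS_model/SS_total`, and
`P = (1 + #{F_perm >= F_obs}) / (n_perm + 1)` over 10 000 label
permutations by default (the `+1` estimator avoids zero P values;
samples, not residuals, are permuted). Covariates are screened
**marginally** — one model per covariate with BH correction across the
screen — because sequential sums of squares depend on term entry order,
which is not an order-free quantity; marginal R² values will not match a
sequential multi-term fit and are labelled as such. Two numerical
guards: a residual SS that rounds to a tiny negative under perfect
separation is clipped so pseudo-F becomes +inf, and permuted F values
within `1e-10` relative tolerance of the observed F count as ties.

## Diversity and clinical trends

Species richness counts strictly positive features; the Shannon index is
`-sum p_i ln p_i` in nats over renormalised positive entries (natural
log, the dominant ecology convention; base is otherwise arbitrary). Gene
richness accepts any gene-level table; no rarefaction is performed.
Between-time-point change is summarised as `delta = median(t2) -
median(t1)` and the per-month rate `delta' = delta / months` (3 months
for baseline to 3 MO, 9 for 3 MO to 1 Y) — medians, not means, to match
the robust summaries used for these small samples. Meal-test curves
(glucose, GLP-1 over −10 to 240 minutes) are integrated with the
trapezoidal rule over the supplied points; total AUC is reported, not
baseline-subtracted AUC.

## The synthetic cohort generator

No raw data accompany the emulated study, so validation rests on a
generator reproducing the features the analysis relies on:

- **Design**: 13 subjects at baseline, 12 at 3 months, 8 at 1 year
  (nested, missing-at-random dropout by default).
- **Compositional structure**: log-normal absolute abundances
  `A_ijt = exp(mu_j + b_i + e_ijt) * delta_j^[t affected]`, with
  per-taxon locations `mu_j ~ N(0, 2^2)` (spanning several orders of
  magnitude, as real communities do), subject effects
  `b_i ~ N(0, 0.5^2)` and within-subject noise `e ~ N(0, 0.3^2)` on the
  natural-log scale; closure applied exactly (`read_depth = 0`) or by a
  per-sample multinomial draw.
- **Unannotated mass**: 20 % of each sample by default, emulating reads
  that map to no catalogued feature.
- **Spike-ins**: a configurable taxon subset receives a multiplicative
  effect `delta` from 3 months onward (persistent) or at 3 months only
  (transient); all other taxa have true effect exactly 1, giving exact
  ground truth for recovery and false-positive studies.
- **Bimodal dominant taxon**: one taxon drawn from a high mode
  (natural-log shift +4 by default) in a configurable subject fraction
  (0.3), emulating a *Prevotella*-type enterotype split.
- **Clinical covariates**: piecewise-linear per-month trends (steep over
  months 0–3, shallow over 3–12) around subject-specific baselines, with
  defaults at realistic scales (BMI ~42 kg/m² falling ~3 kg/m² per month
  initially; fasting glucose ~7.5 mmol/L; GLP-1 AUC rising).

A single seed drives all draws through deterministically derived
substreams, so cohorts are bit-reproducible. What the generator does
**not** emulate: phylogenetic correlation between taxa, over-dispersed
or zero-inflated count noise beyond the multinomial, informative
(non-random) dropout, and any coupling between clinical covariates and
the microbial profiles. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
performance on real sequencing data.

## Validation scale and calibration

The simulation studies behind the test suite and `scripts/acceptance.py`
use sizes chosen to estimate the quantities to well under their
tolerance: 200 replicate cohorts for the type-I-error band (measured on
spike-free cohorts, where the nominal 0.05 applies; under spiked cohorts
closure *correctly* inflates rejections on non-spiked taxa — that
inflation is the artifact the leave-one-out stage exists to flag), 200
replicates of the single-large-spike design (delta = 8, noise 0.2) for
the flag rate on closure-induced false positives, and 500 replicates at
999 permutations for PERMANOVA null calibration. A closure-induced false
positive is defined against the generator's ground truth: a non-spiked
taxon significant on relative abundances whose paired test on the true
absolute abundances is not significant. Noise-driven hits that are also
significant in absolute terms are genuine signals from the test's point
of view and are correctly retained as robust.

## Known limitations

- The exact Wilcoxon path requires untied magnitudes; heavily tied data
  (e.g. low-depth multinomial counts) silently use the corrected normal
  approximation, which is anticonservative below ~6 pairs.
- `pi0` estimation is unstable below a few dozen tests; the pipeline
  falls back to `pi0 = 1` under ten features.
- The leave-one-out test addresses single-taxon closure artifacts only;
  artifacts distributed over several co-varying taxa require log-ratio
  methods, which are out of scope by design.
- Marginal PERMANOVA does not adjust covariates for one another;
  collinear covariates (e.g. glycaemic status and fasting glucose)
  should be pruned by the analyst beforehand.
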