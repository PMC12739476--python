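# Methods

## The evaluation model

`droughteval` scores genotypes for drought resistance from a multi-indicator
stress time course. The input is a long-form table of replicate-level
measurements keyed by `(genotype, stage, replicate, indicator)`, where the
stages are ordered sampling days of a progressive-drought treatment
(default: day 0 control, then days 4, 8, 12, 16). Replicates are averaged
to a sample matrix **X** of one row per genotype × stage sample and one
column per indicator; the default 18 indicators cover leaf anatomy
(leaf/epidermis/palisade/spongy thicknesses), stomatal traits (density,
aperture, pore length/width, opening count), relative chlorophyll content,
and physiology (MDA, proline, soluble sugars/proteins, SOD/CAT/POD
activities).

The comprehensive evaluation is the membership-function (subordinate
function) method on principal-component scores:

1. **Standardization.** Each column of X is z-scored (mean 0, sd 1;
   denominator `n − ddof`, default `ddof = 1`). The final index is
   invariant to the ddof choice because the later min-max step absorbs any
   positive rescaling of a score column.
2. **Correlation-matrix PCA.** Eigendecomposition of the indicator
   correlation matrix R. Eigenvalues λ₁ ≥ λ₂ ≥ … sum to the number of
   indicators p; the variance contribution of component j is Vⱼ = λⱼ / p.
   Scores are the standardized samples projected on the orthonormal
   eigenvectors.
3. **Component retention.** The smallest leading set whose cumulative
   contribution reaches a threshold (default 85%) is kept; an explicit
   component count can be forced instead, since published analyses
   sometimes retain one component beyond the threshold.
4. **Membership transform.** Each retained score column is min-max
   normalized over *all* samples pooled (both genotypes, all stages):
   μ(x) = (x − min)/(max − min), so each column attains 0 and 1 at the
   extreme samples. The "anti" form 1 − μ is available per component for
   axes on which larger scores mean worse condition.
5. **Weights.** Wⱼ = Vⱼ / Σ V over the retained components; weights sum
   to 1.
6. **Composite index and ranking.** D(i) = Σⱼ μⱼ(i)·Wⱼ ∈ [0, 1] per
   sample; a genotype's score is the mean of D over its stages, and
   genotypes are dense-ranked by descending average D (rank 1 = most
   drought resistant). Exact ties share a rank, are flagged, and are
   ordered by genotype label.

### Eigenvector orientation

Eigenvectors are sign-ambiguous, and the membership direction depends on
the sign, so orientation must be deterministic. Three rules are provided:

- `max_loading` (default): the largest-magnitude coefficient of each
  component is made positive. Deterministic and assumption-free; used when
  reproducing an external loading table (combine with `anchors` to pin a
  named indicator's sign per component).
- `direction`: each component is flipped so that the indicators tagged
  *higher-is-resistant* (the structural/water block: thicknesses, stomatal
  geometry, chlorophyll) load net-positively. These indicators decline
  monotonically under stress, so the sign of their net loading identifies
  the "better condition" direction of the axis. Stress markers (MDA,
  osmolytes, antioxidant enzymes) rise both as damage and as active
  defense; their loadings are an ambiguous orientation signal and are used
  only to break an exact tie. This rule matters on the genotype-contrast
  axis, where structural state and defense response co-vary across
  genotypes and a vote over *all* indicators cancels to noise.
- explicit `anchors`: `{"PC1": "Lth"}` forces the leaf-thickness loading
  on PC1 positive.

A per-component `direct`/`anti` membership override is exposed on top of
the orientation rule; flipping a component's sign is exactly equivalent to
switching its membership orientation.

### Relation of per-indicator and per-component membership

The classical subordinate-function rule applies the anti form to any
indicator negatively correlated with resistance. Because membership here
operates on component scores (matching the published μ-per-component
layout this package reproduces), that rule is realized as component
orientation rather than per-indicator pre-flipping; the two differ only by
the sign bookkeeping absorbed in step 4.

## Derived indices

Derived leaf indices are computed from primary measurements before
evaluation when their inputs are present: relative water content
RWC = (FW − DW)/(TW − DW) × 100 (%), compactness CTR = PT/Lth × 100 and
sponginess SR = ST/Lth × 100 (%), elliptical stomatal aperture
SA = π/4 · SL · SW (μm²), and stomatal opening rate SAR = open/total
(stored as a fraction, formatted as % only in reports). Several of these
formulas are typeset with a "×" where a quotient is required in some
sources; the quotient is implemented since only it yields the stated
percentage range.

## Screening statistics

Per-stage genotype comparisons use the two-sided two-sample t test
(pooled-variance by default, Welch optional), across-stage differences the
classical one-way ANOVA, and indicator association the all-pairs Pearson
matrix with p from the t transform on n − 2 df. Degenerate inputs follow
explicit contracts (zero variance with equal means → t = 0, p = 1; with
unequal means → an infinite-t flag; constant columns → NaN entries flagged,
never silently zeroed). Significance bands default to
*, **, ***, **** at p < 0.05, 0.01, 0.001, 0.0001. No multiple-testing
correction is applied by default, matching common practice in this
literature; Benjamini–Hochberg adjustment is available explicitly.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes — a
2-genotype × 5-stage × 3-replicate × 18-indicator pot trial — so every
stage of the pipeline is testable without access to raw trial data. Each
replicate value is

    baseline + slope · genotype_modifier · (day / 4) + Normal(0, noise_sd),

truncated at a physical floor (0), with a warning when truncation fires
because it biases cell means upward. Defaults, chosen once as realistic
magnitudes for woody-ornamental leaf traits: baselines such as leaf
thickness 0.45 mm, stomatal density 260 mm⁻², SPAD 46, MDA 9 nmol/g;
structural/water indicators decline 6% of baseline per 4-day step and
stress markers rise 12% per step in the sensitive genotype; the tolerant
genotype declines at ×0.55 of that rate and responds at ×1.45; replicate
noise sd is 5% of baseline. Linear stage trends are the default, with an
optional saturating (exponential-approach) curve. All draws come from one
`numpy` Generator seeded per design, so tables are bit-reproducible.

What the generator does *not* emulate: replicate correlation within pots,
heteroscedasticity across stages, non-Gaussian measurement error,
indicator cross-correlation beyond what the shared stage trend induces,
and any biological process model (ABA signaling, wax biosynthesis).
Passing recovery tests therefore show that the pipeline detects a
designed monotone-trend contrast at realistic noise, not that it is robust
to every failure mode of real trial data.

The recovery experiment runs generate → aggregate → evaluate across seeded
sub-runs and reports how often the designed most-resistant genotype earns
rank 1. It evaluates with the `direction` orientation; with the default
contrast the recovery fraction is 1.0 over 100 runs, and with the genotype
effect set to 0 it falls to the coin-flip rate (within binomial bounds).

## Numerical choices and degenerate inputs

- Eigendecomposition via symmetric `eigh` on the correlation matrix;
  eigenvalues clipped at 0 to remove −1e-16-scale noise; the independent
  SVD cross-check in the tests agrees to 1e-8.
- Min-max membership requires max > min; a constant score or indicator
  column aborts with an error naming the offender rather than emitting
  NaN.
- Evaluation requires ≥ 3 samples and ≥ 2 indicators.
- Report CSVs round to 3 decimals; a sidecar JSON carries full precision
  so rounding never feeds back into computation.
- The packaged reference tables (loading matrix, variance percentages,
  membership values of a published two-species camellia drought trial) are
  regression inputs only: the raw replicate data behind them were never
  released, so loadings/μ are not recomputed from raw data, while weights,
  D values and ranking are recomputed from the tables. Reproducing the
  published average D of 0.338 / 0.551 is checked at the tables' printed
  precision (±0.001): the recomputed values are 0.33865 and 0.55098, the
  first of which the source table shows truncated rather than rounded.

## Problem sizes

The test suite and the acceptance checks run the full pipeline at the
design scale above (540-record tables, 10 × 18 sample matrices), 100-run
recovery and null-calibration experiments, and a 100-matrix PCA
cross-check; the whole suite completes in a few seconds on one CPU.

## Known limitations

- Component retention by a cumulative-variance threshold is a heuristic;
  no parallel analysis or cross-validated selection is offered.
- The `direction` orientation rule presumes the structural block's
  direction tags; for indicator sets without tagged structural indicators
  it degrades to the `max_loading` rule.
- Dense ranking with exact-tie flagging is the only tie policy.
- No factor rotation, grey relational analysis, or TOPSIS-style variants.
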