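# Methods

## Functional connectivity

An edge is the Fisher z-transform of the Pearson correlation between two
ROIs' mean BOLD series. The matrix diagonal is undefined and stored as 0.
Edge vectors use the row-major upper triangle with 0-based node ids and
i < j, fixed across the package and written into file headers; an N-node
parcellation has N(N−1)/2 edges (34,716 for 264 nodes).

Degenerate correlations (|r| = 1, e.g. duplicated ROIs) are capped at
1 − 10⁻⁷ before atanh, with a warning, so downstream sums stay finite
while the pathology is flagged. Constant ROI series are an error naming
the ROI. Motion scrubbing removes exactly the frames whose framewise
displacement (FD) exceeds the threshold (default 0.5 mm, strictly
greater), preserves frame order, and performs no adjacent-frame
augmentation; subjects retaining fewer than 30 frames (configurable) are
excluded with a logged reason. FD is consumed, not computed: conventions
for deriving FD from realignment parameters differ (Power vs. Jenkinson),
so the trace is an input.

## CPM

Edge selection uses the partial Pearson correlation between each edge and
the behavior, controlling for age, gender (0/1) and head motion, with the
two-tailed p from t = r√(df/(1−r²)), df = n − 2 − k. Edges with
p < threshold (default 0.01; sensitivity sweep {0.025, 0.01, 0.005,
0.001}) are split by correlation sign into the positively and negatively
correlated networks, each modeled separately. The fold model regresses the
raw behavior on the summed Fisher-z strength of the selected edges —
covariates enter selection, not the strength→score map, which is the
standard CPM protocol.

Selection runs inside every training fold, so held-out subjects never
influence feature selection or fitting (unit tests perturb a held-out
subject's edges and verify its fold's mask and coefficients are
untouched). Two descriptive masks are reported alongside: the consensus
mask (edges selected in every fold) and a full-sample selection whose edge
count is what anatomical summaries describe. Folds with an empty mask
yield missing predictions rather than zero-strength predictions; the
observed-vs-predicted r uses subjects with predictions, and a result with
more than 20% missing folds is flagged unreliable (package convention).

Cross-validation is leave-one-out by default; repeated k-fold (default
10 × 100) randomly partitions subjects per repeat (seeded) and averages
each subject's predictions over repeats before computing r. k = n with
one repeat reduces to LOOCV exactly (bitwise), because both schemes share
a single fold-loop implementation.

The permutation test permutes the behavior column alone (covariate rows
stay attached to subjects, so the test targets the edge–behavior link
conditional on covariate structure) and reruns the entire pipeline,
selection included, per permutation. The one-tailed plus-one estimator
p = (#{r_null ≥ r_obs} + 1)/(n_perm + 1) can never be 0. A permutation
whose pipeline builds no model (undefined r) counts as non-exceeding —
operationally r_null = −∞ — which keeps the p-value a valid permutation
p-value; if the *observed* pipeline builds no model the p is NaN and the
dimension is excluded from the FDR family. Inside the permutation loop a
vectorized LOOCV engine precomputes everything that does not depend on the
behavior vector (per-fold covariate Gram inverses and residualized-edge
sums of squares) and applies the selection threshold as |r| > r_crit, the
exact inverse of the t-test; it is unit-tested against the plain fold
loop to ~10⁻¹⁰ on both tails.

FDR is Benjamini–Hochberg, applied across the five subdimensions within
each tail; the questionnaire total score is reported uncorrected. Whether
correction should instead pool both tails is not determinable from the
reporting conventions this design follows; the family is a configuration
list.

## Network anatomy

Each masked edge is attributed to the unordered network pair of its
endpoints; the count matrix's diagonal holds intra-network edges, and
diagonal-once-plus-upper-triangle sums to the mask size. Node degree is
mask incidence (handshake identity: degrees sum to twice the mask size),
ranked with ties broken by node id. Coincidence between two dimensions'
networks is the exact boolean intersection of their masks — symmetric,
idempotent and monotone under union. The "UNC" (uncertain) label is an
ordinary network. Percentages are reported to two decimals.

## Mediation

The single-mediator model tests network mean FC (note: the mediation
independent variable is the *mean* of the predictive edges, while the CPM
model uses the *sum*) → subdimension score → outcome, controlling for age,
gender and head motion in every equation. x, m, y are z-scored once on the
full sample so coefficients are standardized; a comes from m ~ x + C, and
b, c′ from y ~ x + m + C. With identical covariate sets the OLS identity
c = c′ + a·b holds exactly (asserted to 10⁻¹⁰). The indirect-effect CI is
a percentile bootstrap (default 5,000 resamples of standardized rows,
refit end-to-end, seeded); percentile rather than bias-corrected was
chosen as the simplest defensible default, exposed as a switch, since
macro implementations of this model have changed their default across
versions. Degenerate resamples (constant column) are redrawn and logged.
The bootstrap is vectorized via batched normal equations with a
per-resample least-squares fallback.

## Longitudinal change

Follow-up intervals differ between subjects, so change scores are
annualized: ((t2 − t1)/interval_days) × 365. The ×365 convention is
applied uniformly (an unambiguous monotone rescaling; correlations are
unaffected when intervals are equal and properly time-normalized when they
are not). Subjects missing the second time point are dropped with logged
counts. Change prediction reruns CPM with the edge universe restricted to
a previously identified network; selection is re-applied within folds
inside that universe by default (the predictive subset is typically
sparser than the prior network), with a wholesale mode (all prior edges,
no re-selection) available. Restriction to the full universe reduces
exactly to unrestricted CPM.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: ~180 young
adults (age 19.09 ± 0.84, 57% female, head motion 0.12 ± 0.05 mm folded
at zero), an N-node atlas grouped into the 14 canonical networks when
n_networks = 14, behavioral scores affine-mapped from standardized
latents to plausible questionnaire ranges, and a follow-up after 12–18
months retaining 159/180 of subjects.

All latent structure is standardized. Each behavior b loads on its own
network factor g_b ~ N(0,1) with latent share α (default 0.8), on the
z-scored covariates with confound loadings γ (default 0.1 each), and on
independent noise so its variance is 1. A planted edge is
μ + σ_e(λ g_b + √(1−λ²) ε) with λ = effect_r/α, giving population
edge–behavior correlation exactly effect_r; non-planted edges are block
means plus independent noise. Block means are 0.25 (within-network) and
0.05 (between), with between-subject edge SD σ_e = 0.15 — typical
resting-state Fisher-z values. A mediated outcome is y = c′·g + b·m + ε
(variance-completing noise), which ties the mediator's latent share to the
a-path. Time-2 outcome scores are t1 + coupling·s + noise_sd·ε, where s is
the standardized mean planted-edge strength of the driver behavior and
noise_sd defaults to 1 (so coupling 0.4 implies a change–strength
correlation of 0.4/√1.16 ≈ 0.37). When time series are requested instead
of FC, per-subject multivariate-normal series are sampled whose population
correlation is tanh of the subject's z-matrix after
nearest-positive-definite repair by eigenvalue clipping.

Defaults the generator does not take from any stated design were fixed
once on field-typical values and are not tuned: α = 0.8 (behaviors
substantially but not fully determined by their network factor, and
admitting planted effects up to r = 0.8), the block means/SD above, and
the questionnaire affine maps. What the generator deliberately does *not*
model: spatial autocorrelation and volumetric hemodynamics, correlated
subdimension latents (behaviors are independent by default, unlike real
questionnaire batteries), item-level response processes, and non-Gaussian
score distributions. A green simulation test therefore establishes that
the estimators recover planted linear-Gaussian structure with correct
error calibration — not that any particular real-world effect exists.

Identical config + seed is bit-identical everywhere; the pipeline derives
per-stage seeds deterministically from the run seed.

## Numerical choices and degenerate inputs

- Symmetry tolerance for vectorizing FC matrices: 10⁻⁸ (hard error above).
- |r| cap before atanh: 1 − 10⁻⁷.
- Empty masks raise (summed/mean strength) or yield missing predictions
  (CV folds); they are never silently zero.
- Collinear covariates raise an error naming the offending column.
- Zero-variance behaviors, constant ROI series and zero-variance paired
  differences are hard errors.
- Degree-ranking ties break by node id; BH q-values are clipped at 1.

## Limitations

- The mediation model is a single-mediator design; no multiple-mediator,
  moderated or cross-lagged variants.
- Anatomy is limited to degree and edge counts (no modularity/efficiency).
- The fold model is plain OLS on summed strength — no ridge or Spearman
  selection variants.
- Volumetric preprocessing (slice timing through nuisance regression) is
  out of scope; the pipeline starts at ROI time series or FC matrices.
- The permutation and bootstrap replication counts in the test suite are
  scaled down (200 permutations, 1,000 resamples) from the analysis
  defaults (1,000 and 5,000) to keep runtimes in minutes; the estimators
  are identical.
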