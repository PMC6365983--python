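# Methods

`mmnloc` implements a source-localisation analysis of the auditory mismatch
negativity (MMN): a spherical-head EEG forward model, three inverse
solutions (an LCMV beamformer, eLORETA, and fixed four-dipole fitting), a
group-statistics layer, and a synthetic oddball-EEG generator that provides
ground truth for validating every stage. This note documents the models,
the defaults and why they were chosen, and what the synthetic validation
does and does not establish.

## Forward model

The head is three concentric spherical shells — brain, skull, scalp — with
radii 80/85/92 mm and conductivities 0.33/0.0042/0.33 S/m (the standard
~1:80 skull-to-soft-tissue ratio). The potential of a current dipole inside
the brain shell is computed analytically: the infinite-medium dipole
potential is expanded in Legendre harmonics and each order is propagated
through the shells by solving the 5×5 interface system (continuity of
potential and radial current at each boundary, insulating scalp surface).
The series is truncated at `n_terms` (default 100); for sources within
0.85·(brain radius) the truncation error at order 60 is already below 1e-6
relative. The implementation is verified against the closed-form solution
for a homogeneous sphere (to which the shell system reduces when
conductivities are equal) and against rotational symmetry.

A spherical head is a deliberate simplification: it requires no anatomical
template, is exactly reproducible, and supports the analytic unit tests
above. It cannot reproduce atlas-based grid counts or realistic skull
geometry; boundary-element models are out of scope.

Electrode montages are deterministic Fibonacci lattices on the scalp sphere
(labelled `A1…An`), a stand-in for the 128-channel cap used in oddball
studies; real electrode files (`label x y z` text, metres, or `.sfp` in cm)
can be supplied instead. All data are common-average referenced, and the
leadfield columns are projected accordingly.

Source grids are regular lattices (default 10 mm) clipped strictly to the
brain shell. A synthetic "white matter" core (radius < 0.45·brain radius)
exists solely to exercise the grey-matter-only analysis path used by
eLORETA; it makes no anatomical claim. Region labels come from a bundled
table of eight centroids (bilateral IFG and STG, left PPC, M1, DLPFC,
precuneus) with 15 mm spheres; the coordinates are atlas-like values
shrunk by a factor 0.9 to fit the spherical brain, with the DLPFC centroid
placed dorsally at (−36, 24, 46)·0.9 mm — middle/superior frontal gyrus
territory, deliberately well separated (~34 mm) from the IFG source so
that the two regions are resolvable at EEG point-spread widths.

## Synthetic oddball cohorts

The generator emulates a 3-session frequency-oddball experiment: 1500
trials, 10% deviants, at least two standards between deviants (sampled
uniformly over all admissible sequences by a stars-and-bars construction),
512 Hz sampling, epochs −100…+500 ms.

Source activity is a sum of Gaussian-windowed dipolar components:

| component | regions | scope | latency (SD) | amplitude |
|---|---|---|---|---|
| N1 | STG-L, STG-R | both conditions | 100 ms (15) | 30 nA·m |
| MMN | IFG-L/R, STG-L/R | deviant only | 170 ms (30) | 20 nA·m |
| P3a-like | PPC-L, M1-L, DLPFC-L | deviant only | 250 ms (25) | 7–7.6 nA·m |

The MMN/N1 generators are oriented toward the fronto-central scalp
((0, 0.31, 0.95)), as for sources in the supratemporal plane and inferior
frontal cortex; this is what makes the bilateral pair sum into the classic
fronto-central mismatch topography. (Radial orientations were rejected:
on a sphere the bilateral radial topographies largely cancel, which is
unphysiological and leaves the difference wave without a dominant global
field power peak.) The reorientation components are placed *after* the
mismatch peak, as P3a-type attention-switching responses are, and their
amplitudes are set so each contributes roughly equal scalp rms (~0.3 µV);
with these defaults the group-level mismatch peak, not the reorientation
response, dominates the 105–271 ms global field power in both groups.

Noise is an equal-power sum of sensor-white Gaussian noise and spatially
correlated noise generated by 50 random deep sources (sampled per subject,
realised through a Cholesky factor of their sensor covariance), totalling
5 µV single-trial rms — representative of preprocessed, artefact-free EEG.
The correlated part gives the covariance structure a beamformer actually
has to contend with.

Cohorts default to 39 controls and 58 patients. Patient gain multipliers
are 0.6 (IFG-L/R, STG-L), 0.85 (STG-R), and 1.5 (PPC-L, M1-L, DLPFC-L);
controls are 1.0. Per-subject gains add log-normal jitter (log-SD 0.15).
These multipliers are this package's defaults encoding the qualitative
pattern to be recovered (reduced frontotemporal mismatch sources, increased
left posterior/prefrontal activity); they are not measurements. Covariates:
age ~ N(59, 10²) truncated to 25–85; speech score 0–4 (controls 4, patients
skewed lower); patients' Colour-Word Interference inhibition-switching time
is 60 s + 50·(mean DLPFC/PPC gain − group mean) + N(0, 10²) s, clipped at
10 s, giving a generating rank correlation of ≈0.45 between posterior gain
and inhibition-switching time.

## ERP layer

Standard trials are randomly subsampled to the deviant count before
averaging, so both condition means share the same noise level. The MMN is
the deviant-minus-standard difference of the mean evoked potentials. Bad
channels can be repaired by spherical-spline interpolation (order m=4,
regularisation 1e-5, Legendre series to order 50 — standard EEG practice;
the operator is tested against an independent implementation). Interpolation
refuses when a quarter or more of the channels are bad. The global field
power (GFP) is the across-channel SD of the common-average topography; the
dipole stage fits a 40 ms window centred on the GFP argmax within
105–271 ms, with exact ties resolved to the earliest sample. Time windows
are half-open `[a, b)` in samples, with sample index `round((t−t0)·fs/1000)`.

## LCMV beamformer

Sensor covariance is estimated over 100–300 ms, by default as the mean of
per-trial sample covariances (denominator n; the per-trial option reduces
the influence of temporally correlated sources), pooled over the matched
standard+deviant trials so a single *common* spatial filter serves both
conditions. The covariance is diagonally loaded with 5% of the mean sensor
variance. Filters are the classic minimum-variance solution
`W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹` per grid point, satisfying `W·L = I` (unit gain);
numerically singular points are masked and the mask is carried through all
downstream statistics. The leadfield is block-normalised (unit Frobenius
norm per source) to suppress depth/norm artefacts in the power maps; the
deviant/standard *ratio* map, `10·log10(P_dev/P_std)` dB, is invariant to
this normalisation (it cancels), which is tested. Vector (3-component)
power is used without scalar orientation reduction; covariance denominator
n vs n−1 is immaterial to the filters (scale-invariant) and fixed at n for
determinism.

Two intrinsic properties of the deviant/standard ratio readout are worth
knowing (both are visible in the Monte-Carlo tests). First, perfectly
coherent deviant sources merge: two mismatch generators with identical
time courses appear as a single apparent source between them — the classic
correlated-source limitation of minimum-variance beamformers; temporally
staggered sources separate cleanly. Second, the ratio argmax carries a
bias of about one grid step away from a generating node whenever
standard-condition activity is co-located with the deviant source (it
inflates the denominator exactly there) and the ERP noise floor in the
denominator is spatially structured. An isolated deviant source at high
averaging SNR is localised within one grid step in ≥23/25 runs; with the
full N1 + mismatch network at the study's averaging SNR the argmax stays
within ~2.5 grid steps of a generating source. Group contrasts of region
power are unaffected by this bias because it is common to both groups.

## eLORETA

The weighted minimum-norm inverse with per-source 3×3 weights iterated to
the fixed point `W_j = (L_jᵀ M L_j)^{1/2}`, `M = (L W⁻¹ Lᵀ + αH)⁺`, where H
is the common-average centering matrix and `α = tr(L W⁻¹ Lᵀ)/(n_e·snr²)`
with SNR 10 (the LORETA-KEY-style parameterisation; isolated in one
function so an alternative can be swapped). Tolerance 1e-6 on the maximum
relative weight change, at most 100 iterations; non-convergence returns the
last iterate with a flag and warning rather than raising. The defining
property — zero localisation error for noiseless point sources at grid
nodes, for any α — is asserted over random nodes in the tests. eLORETA runs
on the grey-matter-only 10 mm grid, mirroring the statistical grids used
for volumetric comparisons.

## Fixed four-dipole model

Dipoles are fixed at the IFG/STG seed coordinates (atlas-like stand-ins,
configurable); only the moment time courses are estimated, by per-sample
least squares on the pooled 12-column leadfield (pseudo-inverse with
singular-value cutoff 1e-10). Nonlinear position search is deliberately
absent: on mismatch topographies it converges to local residual-variance
minima. Residual variance is pooled over the window
(`Σ_t‖v−L₄m‖²/Σ_t‖v‖²`, concatenated rather than per-sample-averaged), and
each dipole is summarised by its mean squared moment norm. A zero data
window raises rather than returning 0/0.

## Group statistics

Per unit (grid point or dipole), patients and controls are compared by the
Mann-Whitney U test — exact permutation enumeration for total n ≤ 12,
otherwise the tie-corrected normal approximation with continuity
correction. The AUROC is U/(n₁n₂), oriented as P(patient > control) + ½
P(tie), so AUROC > 0.5 means patients higher (the orientation is
configurable). Map-level screening uses Benjamini–Hochberg FDR at q = 0.10
with masked units excluded from the family; dipole families use a
Bonferroni threshold with m = 20 (4 dipoles × 5 group contrasts → 0.0025)
and bootstrap AUROC percentile intervals (B = 10,000, subjects resampled
within group) with a group-label permutation p-value (add-one rule), all
seeded.

The empirical-Bayes layer fits Efron's two-groups model to the per-unit
z-scores (from the tie-corrected normal approximation of U): the marginal
density is a Poisson-regression spline on the z histogram (90 bins, cubic
B-splines, df 12); the empirical null N(μ₀, σ₀²) and null proportion p₀
come from central matching — a quadratic in z fitted to the histogram
counts by Poisson likelihood over the central bins and then refreshed over
all bins that the current null explains (≥90% of smoothed counts), so
null-dominated flanks sharpen the fit without admitting real effects. The
local false discovery rate is `p₀f₀/f` clipped to [0, 1]; the per-unit
posterior probability of a true effect is its complement, and "achieved
power" is the mean posterior over units with posterior > 0.5. On the
benchmark mixture 0.8·N(0,1) + 0.2·N(3,1) with 2000 units the estimator
recovers p₀ with mean error ≈0.02 (SD ≈0.02 across seeds). The whole fit
sits behind one interface so a theoretical-null variant can be swapped.

Associations with neuropsychology use partial Spearman correlation: all
variables rank-transformed, x- and y-ranks residualised on the covariate
ranks (age, speech score) by least squares, Pearson correlation of the
residuals, t-test with n−2−k degrees of freedom. With no covariates this
is exactly the ordinary Spearman correlation.

## Pipeline and problem sizes

`run_pipeline` chains simulate → match → ERP/MMN → {LCMV, eLORETA, dipole}
→ per-method group statistics → a cross-method concordance table (sign and
significance of the patient-vs-control difference per region per method)
and, when beamformer maps exist, partial Spearman correlations of patient
posterior-region power against inhibition-switching time. Every stage is
seeded from one master seed (per-subject streams via `SeedSequence.spawn`),
and a rerun with the same config hash and seed reproduces the TSV/JSON
bundle byte for byte.

End-to-end validation runs use a desk-scale profile
(`mmnloc.config.reduced_scale_config`): the full 39/58 cohort but one
100-trial session, a 64-sensor montage and a 12 mm grid, with single-trial
noise scaled by √(100/1500) so the post-averaging ERP signal-to-noise ratio
matches the full-scale paradigm. On this profile, 20 of 20 simulated
cohorts recover the generated sign pattern (lower patient dipole power in
IFG-L/IFG-R/STG-L; higher patient beamformer power in PPC-L/M1-L/DLPFC-L).

## What the synthetic validation shows — and what it does not

Passing tests establish that the inverse solutions and statistics are
implemented correctly: unit-gain and exact-localisation guarantees hold,
exact linear recovery works, FDR is controlled at its nominal level, the
empirical-Bayes null recovery is calibrated, and known simulated group
effects propagate through the full pipeline with the right signs. They do
not establish performance on real patient EEG: the generator uses a
spherical head, a handful of discrete Gaussian-windowed sources, stationary
Gaussian noise, and no artefacts, eye movements, inter-subject anatomical
variability or non-stationarity. Absolute dipole powers, grid counts and
AUROC magnitudes are therefore not comparable with values from real
cohorts; only the logic and the qualitative behaviour of the analysis are.

## Known limitations

- Spherical three-shell head only; no BEM/FEM import, no MEG.
- The montage is an idealised full-sphere lattice unless real electrode
  positions are supplied.
- eLORETA's α-from-SNR parameterisation follows the LORETA-KEY convention;
  other conventions rescale α and change absolute (not relative) maps.
- The empirical-Bayes p₀ estimator assumes a unimodal central null; heavily
  discrete z-values (very small groups) make the histogram fit degenerate,
  in which case the EBI layer is skipped with a warning.
- BDF/EDF reading requires the optional `mne` dependency.
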