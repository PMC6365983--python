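# mmnloc

Source localisation of the auditory **mismatch negativity (MMN)** — the
deviant-minus-standard difference of auditory evoked potentials in an
oddball paradigm — with the three inverse methods used in clinical EEG
group studies, and a synthetic-cohort generator that provides ground truth
for validating every stage.

The package is aimed at EEG methods researchers and clinical
neurophysiology groups who want a fully reproducible, dependency-light
reimplementation of this analysis chain:

1. **Forward model** — analytic three-shell concentric-spheres EEG
   leadfield (truncated Legendre series), deterministic Fibonacci electrode
   montages, regular volumetric source grids with grey/white and region
   labels, common-average referencing throughout.
2. **ERP layer** — deviant/standard trial matching, evoked-potential
   averaging, the MMN difference wave, spherical-spline bad-channel repair,
   and global-field-power (GFP) peak windows.
3. **Inverse solutions**
   - **LCMV beamformer**: per-trial covariance over 100–300 ms, 5%
     diagonal loading, a common spatial filter
     `W(r) = (LᵀC⁻¹L)⁻¹LᵀC⁻¹` with unit gain `W·L = I`, and
     deviant/standard power-ratio maps `10·log₁₀(P_dev/P_std)` dB on a
     normalised-leadfield grid;
   - **eLORETA**: the weighted minimum-norm inverse whose per-source 3×3
     weights are iterated to the fixed point
     `W_j = (L_jᵀ M L_j)^{1/2}`, `M = (L W⁻¹ Lᵀ + αH)⁺`, with α set from an
     assumed SNR of 10 — exactly zero localisation error for noiseless
     point sources at grid nodes;
   - **fixed four-dipole fitting**: least-squares moment time courses at
     bilateral IFG/STG seeds over a 40 ms window around the MMN GFP peak in
     105–271 ms, with residual variance as goodness of fit and mean dipole
     power as the group-level measure.
4. **Group statistics** — Mann-Whitney U per unit, AUROC = U/(n₁n₂)
   oriented as P(patient > control) + ½P(tie), Benjamini–Hochberg FDR at
   q = 0.1 for map screening, Bonferroni (α/m, m = 20 → 0.0025) with
   bootstrap AUROC intervals for dipole families, an empirical-Bayes
   two-groups model (local fdr, per-unit posteriors, achieved power), and
   partial Spearman correlations against neuropsychology scores
   (controlling age and speech score).
5. **Synthetic cohorts** — a 1500-trial, 10%-deviant oddball paradigm at
   512 Hz; Gaussian-windowed dipolar sources (bilateral STG N1, bilateral
   IFG/STG mismatch response, left parietal/motor/prefrontal P3a-like
   reorientation activity); group-dependent regional gains with log-normal
   between-subject jitter; covariates (age, speech score) and a
   Colour-Word-Interference inhibition-switching time linked to posterior
   gains.

## Worked example

```python
from mmnloc import (default_head_model, make_standard_montage, build_source_grid,
                    compute_leadfield, normalize_leadfield, OddballParadigm,
                    default_components, simulate_subject, match_trials, average_erp,
                    compute_mmn, LCMVBeamformer, FixedDipoleModel)

head = default_head_model()                      # 80/85/92 mm shells
montage = make_standard_montage(64, head)
grid = build_source_grid(head, spacing=12.0)     # 12 mm lattice in the brain
L = compute_leadfield(head, montage, grid)

# one subject with reduced left-hemisphere mismatch sources
paradigm = OddballParadigm(n_sessions=1, trials_per_session=300, seed=1)
epochs = simulate_subject(default_components(), {"IFG-L": 0.6, "STG-L": 0.6},
                          paradigm, L, grid, noise_sd=2.0, seed=2)
matched = match_trials(epochs, seed=3)           # equal deviant/standard counts
erp = average_erp(matched)
mmn = compute_mmn(erp)

print(LCMVBeamformer(matched, normalize_leadfield(L), grid).fit().summary())
print(FixedDipoleModel(mmn, head, montage).fit().summary())
```

prints

```
LCMV beamformer results
  grid: sphere-12mm (1237 points, 1237 defined)
  window: [100, 300) ms, regularisation 5% (λ=0.213 µV²)
  max ratio: 9.85 dB at [12.0, 24.0, 0.0] mm (other)

Fixed four-dipole model
  window: [148.0, 187.1] ms
  residual variance: 2.55%
  dipole        x      y      z    mean power
  IFG-L     -41.4   27.0    9.0    0.0002363
  IFG-R      41.4   27.0    9.0    0.0003022
  STG-L     -48.6  -18.0    5.4    0.0002625
  STG-R     48.6  -18.0    5.4    0.0006229
```

The beamformer reports where the deviant/standard power ratio peaks (here
9.85 dB, meaning almost 10× more power in the deviant response); the
dipole model explains 97.5% of the mismatch topography in its 40 ms window
(residual variance 2.55%), and — because this subject's left-hemisphere
gains were reduced to 0.6 — the left IFG/STG dipole powers come out below
their right-hemisphere counterparts.

Whole-cohort runs, including group statistics and the cross-method
concordance table, go through the pipeline:

```bash
mmnloc run-all --config demo.yaml --seed 7 --out results/
# or staged: mmnloc simulate / erp / localize --method lcmv / stats / report
```

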