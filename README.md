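# pspdyn — dynamic brain-network analysis for progressive supranuclear palsy

Progressive supranuclear palsy (PSP) disrupts not only the brain's static
functional connectivity but the *dynamics* of how large-scale networks are
visited over time.  `pspdyn` is an end-to-end, fully tested reimplementation
of a resting-state fMRI dynamics pipeline for two-group (patient vs control)
cohorts of component timecourses:

1. **Quality control** — four motion/quality indices (max/median spike
   percentage, max framewise displacement, max DVARS) computed from motion
   traces and timecourses; subjects above mean + 1 SD on any index are
   excluded, and the average of the four z-scored indices becomes a
   composite motion nuisance covariate.
2. **Brain states** — a group-level multivariate Gaussian hidden Markov
   model with K states and one covariance matrix shared across states, fit
   by EM to concatenated standardized component timecourses.  Per subject:
   fractional occupancy (FO, the fraction of time each state is active),
   switching rate, and mean state lifetimes.  Because FO is compositional,
   group inference runs on principal components of the FO matrix
   (correlation PCA, Kaiser eigenvalue > 1 retention).
3. **Complexity** — multiscale entropy: sample entropy (template length
   m = 1, tolerance r = 0.35 in standardized units) summed over
   coarse-graining scales and averaged over channels.
4. **Connectomes** — wavelet correlation matrices from level-2 MODWT
   Daubechies detail coefficients (0.0625–0.125 Hz at TR 2 s), thresholded
   at fixed edge density; clustering coefficient and characteristic path
   length normalized against degree-preserving double-edge-swap null
   graphs; weighted degree on the retained weighted matrix.
5. **Statistics** — Freedman–Lane permutation GLM with max-statistic
   family-wise error correction, partial correlations, moderation
   (interaction) F-tests, Steiger's Z for dependent correlations, and
   summary-statistic demographic tests (pooled t, Pearson χ²).

Because no patient imaging data ship with the package, a first-class
**synthetic cohort generator** plants the full effect structure the
pipeline is designed to detect: patients' transition matrices are
exponentially tilted so stationary mass moves from subcortical/posterior
states to executive/frontoparietal states, a PSPRS-like severity score
loads on each patient's true occupancy contrast, structural covariates
track subcortical-state occupancy, and a latent per-subject motion level
drives both the motion traces and FD-coupled signal artifacts.  Every
stage can therefore be validated against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the default
synthetic cohort (22 controls vs 24 patients, 12 channels × 305 volumes,
4 states, occupancy shift 0.1, severity loading 0.6; one shared JSON
config):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_fit_brain_states.py
python analysis/06_group_statistics.py
```

The statistics driver prints (seed 20):

```
       outcome         t    p_unc    p_fwe  n_perm  seed
        FO_PC1  5.394420 0.000999 0.000999    1000    20
        FO_PC2  0.364852 0.703297 0.931069    1000    20
switching_rate -0.890599 0.394605 0.603397    1000    21
           mse -2.352262 0.025974 0.042957    1000    21

2 components with eigenvalue > 1 explain 79% of FO variance (eigenvalues: 1.94, 1.22, 0.84, 0.00)
discriminating component: FO_PC1 (group FWE p = 0.0010)
within-case severity correlation: r = -0.92 (t = -7.66, p = 0.0000)
```

Reading this: the first FO principal component separates patients from
controls (permutation t = 5.4, FWE-corrected p = 0.001) while switching
rate does not differ — the planted effect is a shift in *which* states are
occupied, not in how often states change.  The component is oriented so
patients score more negative; among patients it correlates negatively with
the severity score, i.e. more severe disease goes with a more abnormal
occupancy profile.  The `mse` row shows the group contrast in multiscale
entropy from the same permutation family.

The same stages are scriptable through one CLI:

```bash
pspdyn run-all --config analysis/cohort_config.json --outdir results/run --seed 20
```

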