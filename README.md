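# seqmorph

Statistical tooling for auditory statistical-learning studies that link
behavioral sensitivity to sequence structure with surface-based brain
morphometry. The package covers the full computational chain of such a
study:

1. **Stimulus design** — generate 32-token sound sequences over a 4-symbol
   alphabet from first-order Markov transition-probability (TP) matrices
   whose structure level is quantified by the Markov entropy
   `ME = −Σᵢ πᵢ Σⱼ Pᵢⱼ log₂ Pᵢⱼ` (bits). Three condition matrices (high /
   mid / low structure) share uniform marginals (each sound exactly 8 of 32
   tokens) and 25% self-transitions, so the zeroth-order Shannon entropy is
   identical (2 bits) across conditions and only the transition constraints
   differ. Sequences are rejection-sampled against exact symbol counts and a
   per-condition window on the plug-in (bigram) ME, and can be rendered to
   8.8-s WAV files (225-ms tokens, 15-ms raised-cosine fades, RMS
   equalization, 50-ms gaps).
2. **Behavioral inference** — proportional-odds (cumulative-logit) regression
   of 1–7 structure ratings on condition, `P(Y ≤ j | x) = σ(θⱼ − x′β)`, with
   repeated measures handled by subject-level cluster-sandwich covariance;
   odds ratios with Wald CIs, the parallel-lines (proportional odds) test,
   tolerance/VIF collinearity diagnostics, odd/even split-half reliability
   with Spearman-Brown correction, Shapiro-Wilk normality checks, and a
   per-subject sensitivity index: the 2-df omnibus Wald χ² from each
   subject's own ordinal regression.
3. **Surface morphometry statistics** — per-subject cortical-thickness maps
   on a shared triangulated mesh are smoothed with an FWHM-calibrated
   iterative heat kernel, regressed vertex-wise on the sensitivity index
   (age as covariate), and corrected for multiple comparisons by
   cluster-extent inference against the permutation null distribution of
   the maximum supra-threshold cluster size (family-wise error control).
4. **ROI statistics** — per-ROI regression of subcortical volumes (with ICV)
   or ROI-mean thickness on the sensitivity index, Benjamini-Hochberg FDR
   across regions.
5. **Synthetic data** — simulators for cohorts, ratings (latent-logistic
   ordinal model, proportional odds exact by construction), thickness maps
   with planted clusters, and ROI volumes, so the whole pipeline is testable
   without any participant data.

It is aimed at researchers in auditory cognition / neuroimaging methods who
want a reproducible, tested reference implementation of this analysis chain.

## Worked example

```python
import seqmorph as sm
from seqmorph import ordinal_inference as oi

# stimulus design ------------------------------------------------------
print(round(sm.markov_entropy(sm.HIGH_STRUCTURE), 4))   # 0.8113
seq = sm.generate_sequence(sm.HIGH_STRUCTURE, seed=1)
print("".join(seq.token_labels))  # CCDABBCDDDABBCDABCDAAABCDABCDABC
rep = sm.entropy_report(seq)
# empirical ME = 0.7617, shannon = 2.0, self-repetition = 0.226

# behavior -------------------------------------------------------------
cohort = sm.simulate_cohort(18, seed=101)
ratings = sm.simulate_ratings(cohort, seed=102)
fit, table = oi.fit_group_rmolr(ratings, "speech", aggregated=False)
print(table.round(4))
```

prints the contrast table of the group repeated-measures ordinal regression
(cluster-robust by subject):

```
   contrast  odds_ratio  ci_low  ci_high  wald_chi2  df   p
high_vs_low     16.4718  8.3061  32.6649    64.3250   1 0.0
 mid_vs_low      3.8780  2.5803   5.8284    42.5123   1 0.0
high_vs_mid      4.2474  2.8989   6.2232    55.0750   1 0.0
    omnibus         NaN     NaN      NaN    65.4345   2 0.0
```

An odds ratio of 16.5 for high vs low means the odds of giving a *higher*
structure rating are ~16× larger for high-structure than for low-structure
sequences; the 2-df omnibus Wald χ² = 65.4 is the group-level evidence that
ratings track structure at all. The per-subject version of that statistic is
the sensitivity index used downstream:

```python
idx = sm.sensitivity_indices(ratings)   # subject_id, wald_chi2, valid
model = sm.simulate_surface_study(cohort, effect_spec=[sm.PlantedCluster(100, 20.0, 0.15)], seed=5)
model = sm.smooth_model(model, fwhm_mm=10.0)
clusters = sm.cluster_correct(model, vertex_p=0.05, n_mc=1000, seed=6)
print(sm.cluster_table(clusters, model.mesh))
```

The cluster table lists, per connected supra-threshold component: peak
vertex coordinates (mm), peak t, vertex count, area (mm², summed barycentric
vertex areas) and the permutation-corrected p (fraction of null maximum
cluster extents at least as large).

A full run with one command:

```bash
seqmorph run --seed 7 --out runs/demo    # writes TSVs + manifest.json
```

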