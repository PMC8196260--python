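# axispls

Multivariate analysis of large-scale functional networks along the
hippocampal long axis, for resting-state fMRI + PET cohort studies.

The anterior and posterior hippocampus participate in partly dissociated
cortical networks relevant to episodic memory, and dopamine D2 receptor
availability (D2DR) may modulate how strongly an individual expresses
those networks. `axispls` implements the full analysis chain used to ask
such questions at cohort scale:

* **Seed connectivity maps** — per-voxel Pearson correlation with the mean
  time series of an anterior / middle / posterior hippocampal seed, Fisher
  z-transformed (`axispls.connmap`), with ROI signal-to-noise estimation
  and motion-based subject screening (mean FD > 0.5 mm).
* **Partial least squares** (`axispls.pls`) — the core engine. Mean-centered
  (condition-contrast) PLS decomposes the grand-mean-centred condition x
  voxel matrix of connectivity means by SVD; behavioural PLS decomposes the
  stacked condition-wise correlation blocks **R** = **Y**ᵀ**X** between
  behaviour (episodic memory, D2DR) and connectivity. Each latent variable
  (LV) pairs a voxel *salience* pattern with a condition/behaviour salience
  pattern; a subject's *brain score* is the projection of their map onto
  the voxel saliences. Inference is non-parametric: LV significance by
  permutation of the exchangeable unit, voxel reliability by bootstrap
  resampling of subjects, thresholded at bootstrap ratio |BSR| ≥ 3.3 (the
  two-tailed normal critical value at p = 0.001), with 26-connected cluster
  extraction (minimum 10 voxels, 10 mm peak separation) and 95% percentile
  CIs for condition-mean brain scores and correlation scores.
* **ICA parcellation** (`axispls.parcellate`) — group spatial ICA on
  temporally concatenated subject series restricted to a structure mask,
  component selection by longitudinal-axis centers, and assembly of
  disjoint anterior/middle/posterior ROIs.
* **Logan reference-tissue kinetics** (`axispls.kinetics`) — graphical
  estimation of the distribution volume ratio (DVR) from target/reference
  time–activity curves; BPnd = DVR − 1; bilateral averaging.
* **Cohort statistics** (`axispls.cohort`) — episodic-memory composite
  (task sums → z-standardise → average → T-score with mean 50, SD 10),
  mean imputation, ICV covariance adjustment
  (adjusted = raw − b·(ICV − mean ICV)), nuisance residualisation, MANOVA
  with covariates, Bonferroni-flagged correlation tables, sign-based
  axis-group classification, and one-tailed pooled-variance group tests.
* **Synthetic cohorts** (`axispls.synthgen`) — a seeded generator planting
  known axis networks, behaviour couplings and binding potentials, with a
  machine-readable truth record, so every stage is verifiable without any
  data download.

## Worked example

Generate a 40-subject synthetic cohort with planted anterior/posterior
networks, map seed connectivity, and test the axis contrast:

```python
import numpy as np
from axispls import synthgen, connmap, pls

cfg = synthgen.CohortConfig(n_subjects=40, make_tacs=False)
data = synthgen.gen_cohort(cfg, seed=4)

maps = [connmap.seed_map(data.series[i], data.truth.seed_masks[label],
                         subject=sub, condition=label)
        for i, sub in enumerate(data.table["subject"])
        for label in ("aHC", "mHC", "pHC")]
stack = pls.ConnStack.from_seed_maps(maps)
hippocampus = np.zeros(cfg.shape, bool)
for m in data.truth.seed_masks.values():
    hippocampus |= m
stack = stack.restrict(~hippocampus.reshape(-1))   # drop seed self-correlation

result = pls.orient_result(pls.mean_centered_pls(stack))
result.perm_p = pls.permutation_test("mean_centered", stack, n_perm=1000, seed=1)
boot = pls.bootstrap("mean_centered", stack, n_boot=1000, seed=2, reference=result)

print("variance explained (%):", np.round(result.pct_variance[:2], 1))
print("permutation p:", np.round(result.perm_p[:2], 4))
print("condition saliences (aHC, mHC, pHC):", np.round(result.row_saliences[:, 0], 2))
print("mean brain scores:", np.round(boot.cond_score_mean[:, 0], 2))
print("95% CIs:", np.round(boot.cond_score_ci[:, 0, :], 2).tolist())
```

Output:

```
variance explained (%): [98.8  1.2]
permutation p: [0.001 0.001]
condition saliences (aHC, mHC, pHC): [ 0.69  0.03 -0.72]
mean brain scores: [ 7.99  0.21 -8.48]
95% CIs: [[7.19, 8.83], [-0.9, 1.24], [-9.14, -7.89]]
```

LV1 is significant at the permutation floor (p = 1/1001) and contrasts the
anterior seed (salience +0.69, mean brain score +7.99) against the
posterior seed (−0.72, −8.48): each region's connectivity adheres to its
own planted network. The middle seed's salience is near zero and its mean
brain-score CI [−0.90, 1.24] covers zero — its connectivity mixes both
networks, exactly as planted.

The same stages are scriptable from a shell:

```sh
axispls simulate --n 40 --seed 4 --out cohort_dir
axispls connmap --data cohort_dir --out maps
axispls pls --maps maps --data cohort_dir --mode mean-centered \
        --n-perm 1000 --n-boot 1000 --seed 1 --out pls_out
axispls logan --target cohort_dir/tacs/sub000_target.tsv \
        --reference cohort_dir/tacs/sub000_reference.tsv --tstar 20
```

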