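# microdyn

Quantification of microglial morphodynamics from time-lapse two-photon
imaging, with a ground-truthed synthetic 4D simulator.

Cortical microglia continuously survey the brain parenchyma with highly
motile, ramified processes, and retract or extend them within minutes in
response to drugs, genotype, or focal injury. `microdyn` implements the
quantitative workflow used to measure these behaviours from single-channel
4D stacks (T×Z×Y×X) of labelled microglia:

- **Surveillance index** — for each frame transition, the voxels newly
  occupied by processes (extensions, PE) plus the voxels vacated
  (retractions, PR): `S(t) = |PE_t| + |PR_t|`, normalized to its mean over a
  baseline window (first 10 min by default). The conservation identity
  `|PE| − |PR| = ΔV` holds exactly at every transition.
- **Motility index** — `S(t)` divided by the mean projected cell area,
  removing the trivial dependence on cell size.
- **Cumulative surveillance, stationary processes, territory** — the union
  of projected masks over a window and its extrapolated between-condition
  delay; the temporal intersection of projections (soma excluded) as the
  non-motile backbone; the convex-hull area enclosing all distal process
  tips.
- **Chemotaxis** — after focal laser ablation, the "clear area" not yet
  covered by processes is computed per radial sector from the process front
  and fitted with `C(t) = A_∞ + (A₀ − A_∞)·exp(−t/τ)`; τ summarizes the
  speed of the directed response.
- **3D morphometrics** — skeleton extraction by topology-preserving
  thinning on an isotropically resampled grid; Sholl intersections `N(r)`,
  number of processes, total process length (sum of Euclidean node-to-node
  distances), cell volume, and process-to-soma compartmental signal ratios.
- **Statistics** — the test-selection decision tree (Shapiro-Wilk +
  Anderson-Darling normality, F-test variance equality, Student/Welch t,
  Mann-Whitney, Wilcoxon; ANOVA/Welch-ANOVA/Kruskal-Wallis with Tukey,
  Games-Howell or Dunn post hocs) and the noncentral-t power analysis for
  two-sample designs.
- **Simulator** — geometric cells (spherical soma + branch trees) rendered
  into anisotropic voxel grids with Poisson-Gaussian noise, rigid drift,
  oscillating process tips and converging chemotactic fronts. Every
  simulation carries exact ground truth (masks, per-transition voxel
  counts, branch counts and lengths, true τ), so each analysis stage can be
  validated against known answers.

## Worked example

Simulate eight control cells and eight cells whose tip dynamics drop to 40%
at minute 20 (emulating acute pharmacological blockade), quantify each
cell, and compare the groups:

```python
from microdyn.pipeline import RunConfig, run

report = run(RunConfig(seed=1, n_cells=8))
print(report.group_summary.to_string(index=False))
```

```
  group         metric  n        mean        sem
control   effect_index  8    1.021558   0.020477
control motility_index  8    0.064164   0.004985
control  territory_um2  8 3341.312500 380.859577
treated   effect_index  8    0.422494   0.011459
treated motility_index  8    0.027124   0.001152
treated  territory_um2  8 3146.812500 103.329870
```

The control group's effect index stays at ~1.0 (no change from baseline),
while the treated group drops to ~0.42 — the planted 60% reduction in tip
dynamics, recovered from the rendered masks. The decision tree routes this
comparison to Student's t (both groups normal, F-test p = 0.148, equal
variances) and reports p = 3.8e-13:

```python
d = report.decisions["effect_index"]
print(d["test_name"], d["p_value"])   # Student's t 3.84e-13
```

Sample-size planning for a standard experiment (control 100%, SD 25%,
effect 50%, power 80%, two-sided α = 0.05):

```bash
$ microdyn stats power --mean 100 --sd 25 --effect 50 --power 0.8 --alpha 0.05
n per group: 6
```

The CLI also exposes `simulate`, `preprocess`, `segment`, `surveil`,
`chemotax`, `morph`, `stats compare`, and `run` (YAML-configured
end-to-end pipeline); see `microdyn --help`.

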