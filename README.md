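# neurocouple

Voxelwise analysis of cerebral blood flow (CBF), functional connectivity
strength (FCS), and their coupling across groups with differing
white-matter-hyperintensity (WMH) load — plus a synthetic cohort generator
that exercises the whole pipeline end to end.

## The scientific problem

WMHs are bright white-matter lesions on FLAIR MRI, graded by the Fazekas
scale (total 0–6; here mild 1–2, moderate 3–4, severe 5–6). Higher WMH load
is associated with cognitive decline, and one candidate mechanism is
neurovascular dysfunction: blood supply (CBF, from arterial spin labeling)
and neural activity (FCS, a weighted degree-centrality measure from
resting-state BOLD fMRI) normally covary across the brain, and that
coupling may weaken as WMH load grows. The package implements the full
analysis chain:

- **ASL quantification** — single-compartment pCASL model,
  `CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·PD·(1−exp(−τ/T1b)))`
  in ml/100 g/min.
- **BOLD preprocessing** — frame discard, nuisance regression (trend,
  WM/CSF, motion), 0.01–0.08 Hz band-pass; framewise displacement and a
  3 mm / 3° motion-exclusion rule.
- **FCS** — per voxel, the mean of suprathreshold (r ≥ 0.2) positive
  Pearson correlations with every other gray-matter voxel.
- **CBF–FCS coupling** — per subject, the Pearson correlation between the
  6-mm-smoothed, z-scored CBF and FCS maps, globally and per atlas region.
- **Group inference** — Freedman–Lane permutation ANCOVA (group partial F
  over age/sex covariates, 1000 permutations, α = 0.01) per region, with
  post-hoc contrasts; chi-square / ANOVA / Kruskal–Wallis demographics;
  covariate-adjusted partial correlations.
- **Mediation** — WMH load → regional CBF → cognition, percentile
  bootstrap (5000 resamples) on the indirect effect.

Because real cohort MRI data are not shipped, a seeded synthetic generator
produces cohorts whose defaults mirror the emulated study design
(86 subjects split 32/24/30, group coupling strengths 0.225/0.209/0.156,
hub-region CBF deficits growing with WMH load), and the test suite
validates the estimators against independent oracles and checks the
frequentist calibration of every inferential procedure.

## Worked example

Generate the default synthetic cohort and run the complete analysis
(single CPU, ~2–3 minutes):

```python
from neurocouple.pipeline import run_all

results = run_all(seed=0)  # default spec: 86 subjects, 18^3 grid, 24 regions

measures = results["subject_measures"]
print(measures.groupby("group")[["global_cbf", "global_fcs", "global_coupling"]].mean().round(3))
print()
stats = results["region_stats"]["cbf"]
print(stats.loc[stats["significant"], ["region_id", "f_obs", "p_perm"]].to_string(index=False))
print()
print(results["demographics"].to_string(index=False))
```

Output:

```
          global_cbf  global_fcs  global_coupling
group
mild          49.999       0.203            0.472
moderate      48.444       0.202            0.417
severe        46.903       0.200            0.344

 region_id      f_obs   p_perm
         2 646.065031 0.000999
         6 658.762617 0.000999
         7 561.614219 0.000999
        10 748.153381 0.000999
        18 631.894390 0.000999
        19 518.152312 0.000999

       variable         mild     moderate       severe           test        p
            age 63.78 ± 5.35 63.43 ± 5.88 66.61 ± 4.68 Kruskal-Wallis 0.048313
education_years 11.04 ± 3.32 11.25 ± 2.39  9.65 ± 3.22 Kruskal-Wallis 0.148371
        mean_fd  0.18 ± 0.00  0.18 ± 0.01  0.18 ± 0.00          ANOVA 0.414192
            sex        16/16        13/11        15/15     chi-square 0.941661
   hypertension         24/8         4/20         7/23     chi-square 0.000004
       diabetes         29/3         21/3         24/6     chi-square 0.468968
        smoking         7/25         8/16         8/22     chi-square 0.631535
       drinking        21/11         22/2         24/6     chi-square 0.063266
```

Mean CBF and global coupling fall monotonically from the mild to the severe
group, and the six regions the permutation ANCOVA flags for CBF
(2, 6, 7, 10, 18, 19) are exactly the generator's hub regions — the central
quarter of the atlas, where the simulated WMH effect is placed.

The same pipeline is available from the shell:

```bash
neurocouple run-all --seed 0 --out-dir results/run0
neurocouple simulate --out-dir cohort/            # volumes + tables only
neurocouple cbf --asl sub-001_asl.nii.gz --pd sub-001_pd.nii.gz --out cbf.nii.gz
neurocouple fcs --bold clean.nii.gz --mask gm_mask.nii.gz --out fcs.nii.gz
```

See `neurocouple --help` for the remaining subcommands (`preproc`,
`coupling`, `groupstats`, `mediate`).

## Documentation

- `docs/methods.md` — model equations, parameter defaults with units, the
  generator's mechanisms, what the passing tests do and do not establish,
  and known limitations.
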