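# dynconn

Dynamic functional-connectivity analysis of resting-state fMRI ROI time
series: sliding-window network construction, multilayer temporal-graph
metrics, and covariate-adjusted group statistics — with a state-switching
cohort simulator for end-to-end validation.

## Who this is for

Researchers comparing the *temporal reorganisation* of functional brain
networks between a clinical group and controls (the motivating case is
major depressive disorder vs healthy controls in a multi-site
resting-state sample), where static connectivity averages away the effect
of interest.

## What it computes

Each subject's ROI time series (volumes × regions) is cut into overlapping
rectangular windows (default 100 s window, 6 s step); the pairwise Pearson
correlation matrix within window *t* forms layer *G<sub>t</sub>* of a
multilayer dynamic network. Three metric families are computed at global
and nodal level:

* **Temporal variability** — for node *k* with connectivity profile
  *g<sub>k</sub>(t)* (its correlation row, self entry removed):

  &nbsp;&nbsp;*V<sub>k</sub>* = 1 − (2 / T(T−1)) · Σ<sub>t&lt;t′</sub>
  corr(*g<sub>k</sub>(t)*, *g<sub>k</sub>(t′)*) &nbsp;∈ [0, 2]

* **Temporal correlation coefficient** (temporal clustering), on layers
  binarized to the sparsity-*s* strongest edges (a<sub>ij</sub> ∈ {0, 1}):

  &nbsp;&nbsp;*C<sub>i</sub>* = (1/(T−1)) Σ<sub>t</sub>
  Σ<sub>j</sub> a<sub>ij</sub>(t) a<sub>ij</sub>(t+1) /
  √(k<sub>i</sub>(t) k<sub>i</sub>(t+1)) &nbsp;∈ [0, 1]

* **Characteristic temporal path length** (inverse temporal efficiency) —
  the mean over ordered pairs of the fastest time-respecting arrival
  layer d(i, j) (strictly increasing layers, waiting free), with the
  unreachable-pair fraction reported alongside; d ≥ 1.

Binary-layer metrics are evaluated at sparsities 0.10–0.50 (step 0.01)
and averaged across the grid. Group inference is ANCOVA on the group term
adjusting for age, sex, education, mean framewise displacement and site
(the sparsity-profiled metrics via the between-subject effect of the
repeated-measures design), with Benjamini–Hochberg FDR per family,
partial Spearman correlations with symptom severity in patients, and
FEDN / non-FEDN / control subgroup contrasts. See `docs/methods.md` for
conventions, defaults and limitations.

## Worked example

```python
from dynconn import CohortConfig, DynamicNetworkStudy, generate_cohort

# synthetic cohort: 40 fast-switching patients vs 40 near-stable controls
ts_list, phenotype, truth = generate_cohort(CohortConfig(seed=1))
study = DynamicNetworkStudy(dict(ts_list), phenotype)
results = study.fit()
print(results.summary())
```

```
Dynamic functional-network group comparison
============================================================
Groups: MDD (n=40) vs HC (n=40); sites: 2
Window 100 s, step 6 s, TR 2 s; sparsities 0.10-0.50 (41 levels)

Group effects (ANCOVA, covariates: age, sex, education, mean FD, site)
              metric     F  df1  df2         p     p_fdr  direction
temporal_variability 9.834    1   73  0.002469  0.003704          1
temporal_correlation  26.5    1   73 2.144e-06 6.433e-06         -1
temporal_path_length  8.68    1   73  0.004315  0.004315         -1
...
```

The patient group shows higher temporal variability (`direction = 1`:
adjusted patient mean above controls), lower temporal correlation
coefficient and shorter characteristic temporal path length — exactly the
dynamic signature the simulator injects by making patients switch
connectivity states faster. All three survive FDR at 0.05.
`results.subject_metrics` holds the per-subject table,
`results.plot_sparsity_profile("temporal_correlation")` plots the group
mean ± 95 % CI across the sparsity grid, and
`results.to_csv("outdir")` writes tidy CSVs.

The same pipeline runs from the shell:

```sh
dynconn simulate --out sim --seed 1
dynconn metrics --data sim/timeseries --tr 2 --window 100 --step 6 \
    --sparsity 0.10:0.50:0.01 --out metrics
dynconn stats --metrics metrics --pheno sim/phenotype.csv \
    --families primary,subgroup --out stats
```

Real data drop in the same way: one TSV per subject (rows = volumes,
columns = regions, header = node labels) plus a phenotype CSV with
`subject_id, group, age, sex, education, mean_fd, site` (and optionally
`hamd, duration_months, fedn_status`), via
`DynamicNetworkStudy.from_directory(...)`.

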