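# Methods

## Overview

`dynconn` analyses resting-state ROI time series as *multilayer temporal
networks*. For each subject, overlapping rectangular windows are slid along
the scan; the pairwise Pearson correlation matrix within each window forms
one layer. Three families of spatio-temporal metrics summarise how the
layered network reconfigures over the scan, and a covariate-adjusted group
comparison tests whether a patient group differs from controls. A
state-switching simulator provides cohorts with known ground truth for
validating the whole chain.

## Dynamic network construction

* **Windows.** Window and step lengths are specified in seconds and must be
  exact multiples of the repetition time (TR); fractional conversions are
  rejected rather than rounded, since silent rounding would change the
  window placement without warning. Defaults are a 100 s window and a 6 s
  step; at TR = 2 s a 230-volume scan yields 61 windows. Only rectangular
  (untapered) windows are implemented.
* **Correlation layers.** Correlations are left untransformed (no Fisher
  z) and layer diagonals are fixed at zero — self-connections are not
  edges. A zero-variance node series inside any window is a hard error
  naming the node and the window: on properly preprocessed data it should
  never happen, and imputing a correlation there would silently corrupt
  every downstream metric.
* **Binarization.** At sparsity *s*, the `round(s·E)` strongest undirected
  edges of each layer are kept (`E = N(N−1)/2`; round half away from
  zero). Ranking uses the raw signed correlation by default — "strongest"
  means most positive, the usual convention in sparsity-thresholded
  connectome analyses — with magnitude ranking available as an option.
  Ties at the cutoff break by ascending `(i, j)` index, which makes the
  output deterministic and the edge sets nested across sparsities. The
  default grid is 0.10–0.50 in steps of 0.01 (41 levels); metrics defined
  on binary layers are computed at every level and also averaged over the
  grid.

## Temporal metrics

* **Temporal variability** (weighted layers). For node *k*, the
  connectivity profile in window *t* is the *k*-th correlation row with
  the self entry removed. The nodal value is one minus the mean Pearson
  correlation of the profile over all window pairs; it ranges from 0
  (frozen connectivity) to 2 (perfectly anticorrelated profiles). The
  global value is the unweighted mean over nodes; a whole-matrix variant
  (one minus the mean correlation of vectorised upper triangles) is
  available as an option.
* **Temporal correlation coefficient** (binary layers). The degree-
  normalised overlap of a node's neighbour sets in consecutive windows,
  averaged over the T−1 steps; values in [0, 1]. A step in which the node
  is isolated at either end contributes 0 rather than being skipped,
  which keeps the global mean's denominator fixed at N.
* **Temporal efficiency** (binary layers). A time-respecting path uses at
  most one edge per layer with *strictly increasing* layer indices;
  waiting at a node is free. The temporal distance d(i, j) is the arrival
  layer of the fastest such path (a direct edge in layer 1 gives 1), inf
  if j is never reached; it is direction-dependent even on undirected
  layers because paths cannot be reversed in time. The strictly-increasing
  convention matters: allowing unlimited hops within a layer would make
  every distance 1 whenever a single layer is connected, and at 10–50 %
  sparsity that degenerates the metric entirely. Distances are computed by
  layer-sequential frontier expansion (the reached set persists across
  layers; each layer absorbs its in-layer neighbours), vectorised as
  boolean matrix products over all sources, and verified in the tests
  against exhaustive path enumeration. The characteristic temporal path
  length averages the finite d(i, j) over ordered pairs and reports the
  unreachable-pair fraction alongside rather than imputing a ceiling
  value, so pathological subjects surface instead of being hidden. Nodal
  path length uses outgoing distances d(i, ·).

## Group inference

The primary family is the three global metrics. Temporal variability is
tested by ANCOVA: y ~ group + age + sex + education + mean FD + site, with
site as fixed-effect dummies (reference = lexicographically first site;
each site must contain both groups, checked). The test is the
extra-sum-of-squares F for the group term (1 df). The sparsity-profiled
metrics use the between-subject main effect of the repeated-measures
design, which for a complete balanced within-subject factor is exactly the
ANCOVA on each subject's sparsity mean; per-sparsity ANCOVAs are reported
alongside, and the group × sparsity interaction is deliberately out of
scope. Benjamini–Hochberg FDR is applied within families mirroring the
reporting structure: the 3 global metrics; the N nodes per nodal metric;
metrics × contrasts for the FEDN / non-FEDN / control subgroup
comparisons; and per metric across sparsities for the per-level tests.

Clinical associations use partial Spearman correlations in patients
(adjusting for age, sex, site): all variables *including the covariates*
are rank-transformed, the x/y ranks are residualised on the covariate
ranks by least squares, and the residual Pearson correlation is reported
with a t-approximation on n − 2 − q df. Ranking the covariates is the
standard construction; residualising ranks on raw covariates leaves a
residual confounding bias (≈ +0.09 in our strong-confounder simulation)
because a strong confounder enters the ranks nonlinearly. Missing
clinical scores are dropped listwise per correlation; fewer than 10
complete cases is an error.

## Synthetic cohorts

The generator is a hidden-Markov covariance-switching model: each subject
carries a latent connectivity state with geometric dwell times
(first-order Markov chain, uniform jumps); each volume is drawn from a
zero-mean multivariate normal with the current state's covariance plus
isotropic observation noise (sd 0.5). State covariances follow a
community-block recipe — unit variance, correlation 0.6 within each of 4
random blocks, 0 between — giving three positive-definite states that
differ in which regions co-fluctuate. The group manipulation targets
*switching rate only*, so the injected effect is specifically dynamic.

Dwell-time defaults were set from a design sweep of the metric response:
temporal variability is non-monotone in dwell time, peaking when dwell is
comparable to the window length. When both groups dwell far below the
window (e.g. 10 vs 30 volumes under a 50-volume window) every window
averages over many states and the *faster* group shows *lower*
variability — the opposite of the intended effect. The defaults therefore
put controls in a near-stable regime (median 115 volumes, ≈ 2 transitions
per 230-volume scan) and patients in a frequently reconfiguring one
(median 35 volumes). Each subject's mean dwell is drawn lognormally
around the group median (σ_log = 0.45 patients, 0.30 controls): real
subjects are heterogeneous, and without within-group spread the symptom
link below would not be recoverable (variability is locally flat in dwell,
so homogeneous groups give a ≈ 0 within-group association). With these
defaults the three group effects are d ≈ +0.6 (variability), −1.2
(temporal correlation), −0.6 (temporal path length).

A HAMD-like severity score is linked linearly to the subject's *realised*
switching rate (score = 14 + 120·rate + N(0, 3), floored at 0). The
induced severity–variability association in patients is positive in
expectation but small (partial ρ ≈ +0.05 across seeds): per-subject
variability estimates carry substantial state-geometry and sampling
noise, so the within-group dwell signal is heavily attenuated. This is a
property of the measurement, not of the symptom link — halving the
symptom noise leaves ρ essentially unchanged — and mirrors the small
severity correlations typical of real cohorts at comparable n. Covariates (age, sex, education, mean framewise displacement,
site) are drawn from simple parametric models and by default have no
effect on the signal (an optional motion → noise gain exists); sites are
assigned round-robin within group so every site contains both groups.
Randomness is split into per-subject substreams spawned from the cohort
seed, so any subject is reproducible independent of generation order.

What the generator does **not** emulate: hemodynamic convolution and
autocorrelation, scanner noise spectra, motion artefacts, real site
effects, spatial atlas geometry, and any coupling between covariates and
connectivity. Passing recovery tests therefore show that the pipeline
detects genuinely dynamic group differences of plausible size under
idealised noise — not that it would do so against realistic confounds.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run cohorts of 40 + 40
subjects, 20 regions, 230 volumes at TR 2 s with the full 41-level
sparsity grid — large enough for stable effect directions while keeping a
full 100-cohort recovery run in minutes. Direction recovery is assessed
over 100 cohorts (≥ 90 % required), null calibration over 100 cohorts
(3 tests each, rejection rate expected near 0.05). Numerically: window
correlations are clipped to [−1, 1] and variability to [0, 2] to absorb
floating-point excursions; "zero variance" means sd below 1e−12 relative
to the data scale; F-tests with a vanishing extra sum of squares return
F = 0, p = 1; rank-deficient designs raise an error naming the collinear
columns rather than silently pseudo-inverting.

## Known limitations

* Fixed-effect site adjustment only; no random-site models or
  harmonisation (e.g. ComBat).
* Temporal clustering/efficiency are defined for binary layers only; no
  weighted generalisations, temporal small-worldness, community dynamics
  or FC-state clustering.
* The repeated-measures equivalence used for the sparsity profile holds
  only for complete grids; missing cells are an error, not imputed.
* The strictly-increasing path convention is one member of a family of
  temporal-distance definitions; results at very high densities depend on
  that choice.
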