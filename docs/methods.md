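# Methods

This note records the statistical models implemented in `spatcc`, the
numerical choices behind them, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Point-pattern model and K estimation

All analyses treat the data as a finite planar point pattern observed in a
simple polygonal window `A` (coordinates in projected meters; the CRS tag is
carried as metadata, never interpreted). The K function is estimated as

```
K̂(s) = (|A| / n²) · Σ_{i≠j} w_ij · 1[d_ij ≤ s]
```

with `w_ij = 1` for the uncorrected estimator and, for the default isotropic
(Ripley) correction, `w_ij` equal to the reciprocal of the proportion of the
circle centered at point `i` with radius `d_ij` whose circumference lies
inside `A`. The `1/n²` normalization (rather than `1/(n(n−1))`) follows the
plug-in `λ̂ = n/|A|`; under CSR it gives `E K̂(s) ≈ ((n−1)/n)·πs²`, a bias of
0.2% at n = 500 — immaterial at the tolerances used anywhere in the package.

The circumference proportion is computed exactly: the circle's intersection
angles with every polygon edge (a quadratic per segment) split it into arcs,
and each arc is classified inside/outside by an even-odd point-in-polygon
test of its midpoint. Tangencies contribute no crossing and leave the
classification unchanged, which is correct because they do not alter the arc
decomposition's interior/exterior pattern. The routine is JIT-compiled
(numba) so that pair matrices over thousands of points are tractable. The
tests cross-check it two independent ways: an exact half-plane
angular-interval construction on convex windows (agreement to 1e-9) and a
discretized-circle test via shapely on a non-convex L-shaped window.

Degenerate geometry: if no part of a circle's circumference is observable
inside the window (possible only for extreme radius/window combinations),
the pair's weight is set to 0 rather than infinity; coincident points
(duplicate addresses after privacy jitter) count as neighbors at every
`s > 0` with weight 1. Points exactly on the window boundary are inside.
Distance grids must be strictly increasing and positive; the default grid is
64 equal steps up to 8000 m, matching the distance range over which the
difference statistic is normally read.

## Difference of K functions

`D(s) = K̂_cases(s) − K̂_controls(s)`, each K on its own sub-pattern over the
shared window. The null hypothesis is random labeling: conditional on the
pooled locations, the case labels are an exchangeable sample. Envelopes are
built by permuting labels (optionally within matching strata) `n_sim` times,
recomputing `D`, and taking pointwise min/max (default) or 2.5%/97.5%
quantiles. The observed curve never enters the envelope, so for the minmax
rule the pointwise two-sided exceedance probability at any pre-fixed `s` is
`2/(n_sim+1)` under the null — exactly 0.02 at the default-free test setting
`n_sim = 99`, and 0.002 at the default `n_sim = 999`. Ties between the
observed and simulated `D` (possible because pair counts are integers) break
toward non-exceedance, making the rule mildly conservative; the calibration
test measures 0.012 against the nominal 0.02 at `n_sim = 99`.

Envelopes are pointwise, not simultaneous: reading the curve across many
distances inflates the family-wise exceedance rate, which is why the
per-distance verdicts (`cases_aggregated` / `controls_aggregated` /
`null_consistent`) are descriptive rather than a single global test. The
integrated (global) difference-of-K test statistic is a possible extension
and is deliberately not implemented.

Permutation is plain random labeling by default. Stratified permutation
(within region × birth-year × sex) is provided for sensitivity analysis of
matched designs, where the matching variables could correlate with location;
it is off by default because the plain version is the standard presentation
of the test and the default generator assigns strata independently of
location.

## Bernoulli scan statistic

Windows are closed discs centered at case locations; for each center the
radius runs through the sorted distinct distances to every at-risk
individual within the maximum radius (singleton window included), so each
distinct inside-set is scored exactly once per center. Two ranking kernels
are provided:

* `paper` (default): `n_in·log(n_in/N_in) + n_out·log(n_out/M_out)` with the
  candidate indicator `n_in/N_in > n_out/M_out` (evaluated as a cross
  product, so no division by zero; `0·log 0 = 0`);
* `bernoulli`: the full Kulldorff Bernoulli log-likelihood ratio, which adds
  the non-case factors and subtracts the null log-likelihood.

The two kernels can rank windows differently (the two-factor kernel omits
the non-case terms), but they agree on which windows are candidates, and all
reported count arithmetic — populations, cases, expected cases — is
identical under both. Ties in the kernel break toward smaller radius, then
lower center index, making reports deterministic.

The Monte Carlo null reassigns case labels uniformly over all at-risk
locations holding the case count fixed, and recomputes the maximum with
windows centered at the *replicate's* cases, so observed and null statistics
are identically defined. `p = (1 + #{T_rep ≥ T_obs}) / (R + 1)`, hence
`p ≥ 1/(R+1)` and p-values are valid (super-uniform) under exchangeability;
the calibration test over 200 null datasets measures rejection 0.025 at
α = 0.05 with R = 999. Secondary clusters are reported greedily in
descending score, skipping any window sharing a member with a higher-ranked
reported cluster; each is compared against the same null-maximum
distribution (the standard, slightly conservative convention for secondary
p-values). No population-fraction cap is applied beyond the distance cap.
Defaults: maximum radius 5000 m, 9999 replications, α = 0.05.

The maximum-radius default is 5 km with 8 km retained as a configuration
choice, reflecting the two conventions in circulation for this analysis;
both are exposed via `max_radius`.

## Synthetic data generator

The generator emulates the *structure* of matched registry data, not any
real geography:

* **Population intensity**: a Gaussian mixture truncated to the window
  (rejection sampling), the simplest controllable inhomogeneous intensity
  that mimics regions dominated by a few cities of very different size. The
  built-in `northeast_like_scenario` uses a 300 × 300 km window, four
  components with weights 0.55/0.20/0.15/0.10 and spreads 7–20 km, and
  638 cases — sized like the largest regional stratum of the registries it
  emulates (638 cases, 3828 controls) so default runtimes are
  representative.
* **Labels**: under the null, cases are a uniform draw without replacement
  from the location pool; an injected cluster multiplies a location's
  selection weight by `relative_risk` inside a disc. Note that after matched
  controls are attached, the case/at-risk ratio observed inside the disc is
  diluted below the raw relative risk (controls are drawn from everywhere),
  which is exactly how a matched design behaves.
* **Matching**: strata (region, birth year, sex) are assigned independently
  of location; each case receives `matching_ratio` (default 6) same-stratum
  controls drawn without replacement; the leftover pool is discarded. The
  default pool is sized at twice the final dataset plus a margin
  proportional to `matching_ratio / P(rarest stratum)`, emulating a birth
  registry that is effectively unlimited relative to the case series;
  exhaustion of a stratum raises an error naming the stratum rather than
  silently relaxing the matching.
* **Privacy jitter**: the last `d` integer digits of each coordinate are
  replaced by an independent uniform draw (`|x′ − x| < 10^d`); default
  `d = 1`, the meter digit, the most conservative reading of
  trailing-digit randomization. Jittered points that would leave the window
  are redrawn (then left unmoved), preserving pattern invariants. At
  kilometer analysis scales a meter-level jitter changes K̂ by well under 1%.

Because strata are independent of location, the default generator contains
no spatial confounding by matching variables: passing calibration tests here
shows the machinery is correct under exchangeability, not that real
populations lack stratum-location structure. A region-center coupling can be
emulated by supplying per-region scenarios; the stratified permutation
option exists to probe exactly this.

## Problem sizes used in the shipped checks

The statistical checks run at reduced but statistically meaningful sizes,
chosen so the whole suite completes in well under a minute of compute per
check: CSR closed-form agreement uses 200 patterns of 500 points; oracle
equivalence uses 50 instances with n ≤ 50; scan calibration uses 200 null
datasets of 140 at-risk individuals with 999 replications; envelope
calibration uses 500 null datasets of 60 points with 99 replicates; cluster
recovery uses 100 datasets of ~600 at-risk individuals.

## Known limitations

* Planar coordinates only; no lon/lat support, reprojection or spherical
  distances — project upstream.
* Homogeneous-K machinery only; the inhomogeneous-K estimator and
  anisotropic corrections are out of scope (the case-control design handles
  population inhomogeneity by comparison, not by modeling it).
* Circular scan windows only; no elliptic/irregular windows, space-time
  scan, Poisson scan model or covariate adjustment.
* The spatial recovery of a weak injected signal is limited by information,
  not implementation: e.g. with ~600 uniformly spread at-risk individuals
  over 400 km², a 500 m disc contains ~1 individual on average, so no scan
  can localize such a cluster reliably regardless of the relative risk
  inside it. Localization becomes reliable once the disc holds a handful of
  expected at-risk individuals (see the worked example, where the primary
  cluster lands within 1.7 km of a 3 km injected disc in a dense area).
* Envelope verdicts are pointwise; treat multi-distance exceedance patterns
  descriptively.
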