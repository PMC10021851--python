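# Methods

## Estimation model

The estimand is the district-level maternal mortality ratio (maternal deaths
per 100,000 live births over a multi-year analysis window). Facility-system
counts are treated as complete for live births but multiplicatively
under-reported for deaths at the state level; the correction is a per-state
ratio calibration:

    Cf_s = reference state MMR / facility-system state MMR,

with the facility-system state rate always computed from pooled counts
(total deaths over total births), never as an unweighted mean of district
rates. Where the reference MMR is missing, the ratio of infant mortality
rates substitutes for it (`imr_proxy` provenance is recorded); when the
reference MMR is present it always wins. Adjusted district MMR is the raw
district rate times its state's Cf; state estimates are convex combinations
of adjusted district estimates with weights equal to district shares of the
state's female population aged 15–49.

Assumptions this encodes: under-reporting is uniform within a state and
affects deaths and the proxy's infant deaths by the same factor; the
reference is unbiased; birth denominators are not calibrated (only the
ratio is corrected). Zero-birth districts have an undefined rate — they are
flagged, excluded from classification and aggregation (remaining weights
renormalised within the state), and listed in drop reports rather than
being treated as zero-mortality. A state whose facility MMR is zero against
a positive reference has an infinite ratio: this raises a
degenerate-calibration error by default; a flag permits switching such a
state to the IMR-proxy path. Rates are carried at full floating precision
and rounded only for display.

SDG-3.1 classification uses half-open bins [0, 70), [70, 140), [140, 210),
[210, ∞), so each finite non-negative rate falls in exactly one bin and the
bin counts always partition the defined-MMR districts.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every recovery claim is made.

* **Geography.** Districts on a rectangular lattice (default 32×20 = 640),
  assigned to states in contiguous row-major blocks (default 32 states × 20
  districts). Queen contiguity (shared edge or corner) defines adjacency.
* **True surface.** log true MMR = state base effect + covariate
  contributions + spatial noise field. State bases are log-uniform on
  [60, 300] deaths per 100,000, bracketing the published Indian state range
  (40–284). The noise field solves the simultaneous-autoregressive fixed
  point (I − ρW*)f = η with ρ = 0.6 and η ~ N(0, 0.15²) — the exact limit
  of iterated neighbour smoothing, solved sparsely rather than iterated.
* **Covariates.** Fifteen district covariates (antenatal/postnatal care,
  institutional delivery, contraception, BMI, anaemia, ages at
  marriage/first birth, children ever born, schooling, sex ratio at birth,
  household size, SC/ST share, urban share, poor-household share) drawn as
  clipped normals with means/SDs patterned on published descriptive
  statistics for Indian districts. Effects on log-MMR apply to the z-score
  of the *stored* (clipped) value, so the covariate→outcome link is exactly
  linear and noiseless-recovery tests are exact. Default effects (per SD):
  ANC4+ −0.10, PNC −0.10, children ever born +0.20, schooling −0.15, poor
  households +0.10 — modest, domain-plausible signs.
* **Counts.** Births per district uniform on [60k, 180k] (a three-year
  window; ~97k is the national mean per district), female population 15–49
  at 8× births, true maternal deaths Binomial(births, MMR/10⁵), observed
  deaths thinned Binomial(·, r_s) with state reporting fractions uniform on
  [0.5, 1.0]. Infant deaths are generated from a true-IMR surface centred
  at 30 per 1,000 whose log co-moves with log MMR at slope 0.5, so the two
  mortality measures correlate across units as observed nationally.
  Optional flags add under-reporting of births and noise on the reference.
* **Reference.** Reference MMR/IMR equal the true (birth-weighted) state
  rates; a configured fraction of states (default 0.25, ⌊fraction·n⌋
  states by seeded draw) has the reference MMR withheld to force the
  IMR-proxy path.

What the generator does **not** emulate: real administrative geography,
within-state heterogeneity of reporting, reference sampling error (off by
default), period mismatch between sources, cause-of-death misclassification,
or covariate spatial autocorrelation (covariates are i.i.d. across
districts). Passing recovery tests therefore demonstrates correctness of
the estimator under its own assumptions, not robustness to their violation
in real data.

A calibration-recovery note: with exact references, the only error in
adjusted district MMR is binomial, with E|relative error| ≈
0.8·√(10⁵/(births·MMR·r)). Recovery checks are run at births large enough
(≥ 6M per district in the acceptance run) for this floor to sit inside the
2% tolerance, alongside a check that the error shrinks as births grow.

## Health Infrastructure Index

Each per-1,000-population indicator is min-max normalised,
(x − min)/(max − min) clamped to [0, 1]; goalposts default to the observed
cross-district min/max (fixed goalposts can be supplied, since published
composite scales for this quantity are not always [0, 1]-bounded).
Aggregation is the arithmetic mean of dimension indices (geometric mean
available). The urban adjustment is the convex combination
(1 − u)·HII + u·1.0 with u the urban population share — the urban component
is imputed at the upper goalpost to credit unenumerated (largely private)
urban infrastructure. This is a documented convention, not an estimate; it
makes the adjusted index monotone in both arguments and never below the raw
index.

## Spatial statistics

Weights are queen contiguity (from an edge list or from polygons sharing at
least a boundary point), binary and row-standardised; all statistics use
the row-standardised form. Units are kept in sorted-id order; islands
(degree 0) are excluded from statistics with a warning and carry NaN local
results. Global Moran's I = (n/S0)·(z′W*z)/(z′z) with mean-centred z;
E[I] = −1/(n−1). Local I_i = (z_i/m2)·(W*z)_i with m2 = z′z/n, whose mean
equals the global statistic under row standardisation (asserted to 1e-10 in
tests; the global statistic is asserted against a brute-force O(n²) double
sum to 1e-12). Quadrants HH/LL/HL/LH come from the signs of z_i and its
lag (ties on zero go to the low side). The bivariate statistic replaces the
lag of x with the lag of a second variable y, holding x_i's role.

Permutation inference is GeoDa-style: 999 permutations by default, pseudo
p = (extreme + 1)/(permutations + 1), one-sided toward the observed
direction, ties counted as extreme; LISA uses conditional permutation
(hold unit i's value, resample the rest without replacement into its
neighbour set). One seeded generator drives all draws in unit order, so
results are reproducible given (seed, permutations).

**Test size.** Because the pseudo-p tail is chosen after observing the
statistic's sign, `pseudo_p < α` occurs with probability ≈ 2α under a
no-autocorrelation null. The significance flag therefore defaults to the
equal-tail correction `pseudo_p < α/2`, which gives the flag test size α
(empirically ~4.6% at α = 0.05 on i.i.d. fields); passing
`selection_correction=False` restores the raw convention used by most
cluster-map software, at roughly double the nominal false-positive rate.
No multiple-testing correction across units is applied by default,
mirroring standard LISA maps.

## Regression

Outcome: log adjusted district MMR. Zero-MMR districts have no logarithm;
the default drops and reports them (an `offset` policy is available).
Covariates are log- or identity-transformed per model specification; the
default suite logs a covariate when it is strictly positive in the data.
Estimation is OLS with HC1 sandwich standard errors (HC0–HC3 selectable,
flavour recorded); listwise deletion with per-row reasons; rank deficiency
is an error naming the fact rather than a silent drop. The collinearity
screen computes pairwise Pearson correlations on complete cases and fails
any model containing a pair with |r| > 0.60 unless overridden; the pipeline
prunes the later member of each flagged pair. The "area dummy" option is
implemented as state fixed effects — one dummy per district is impossible
with one observation per district, so the state level is the coarsest
faithful interpretation, and it is labelled as such in outputs.

## Pipeline and reproducibility

`mmrcal run` executes simulate (when no inputs are given) → estimate → hii
(when indicator inputs are supplied) → spatial → regress → report, writing
CSV artifacts plus `run_metadata.json` (seed, config echo, package version,
stage row counts, drop reports). One master seed drives everything; the
spatial stage derives its permutation seed as seed + 1 so stages can be
rerun independently yet reproducibly. Reruns with the same config are
byte-identical. Every excluded unit appears in exactly one drop report with
a reason.

## Numerical choices and limitations

* Within-state population weights sum to 1 (tolerance 1e-9); row sums of
  W* to 1e-12.
* The Moran statistic is not hard-bounded to [−1, 1]; no such invariant is
  enforced.
* Classification bins are half-open on the left edge (70.0 → the 70–139
  bin; 210.0 → the top bin).
* Point estimates only: no uncertainty intervals for calibrated MMR, no
  time trends, no spatial-lag/error regression. The ecological design
  carries ecological-bias caveats that no amount of calibration removes.
* Acceptance-scale problem sizes (8×10 calibration system, 20×20 LISA
  lattice with 50 replicates, 200 regression replicates at n = 640) were
  chosen so each check isolates one error source at a cost of a few
  minutes; all are seeded and deterministic.
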