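# Methods

## Scope and data model

The package analyzes serial growth–dilution evolution experiments tracked
by OD600.  Two data shapes are first-class: a *kinetic curve* (one well's
OD600 over a single 48 h cycle, nominally every 5 min, irregular spacing
accepted) and a *transfer trajectory* (one population's end-of-cycle
OD600 over T transfers, 1-based and contiguous, with the transfer at
which stress began recorded on the object).  Every series carries exactly
one layout annotation (culture type, treatment, dose, replicate); tables
with unmapped columns are rejected rather than silently subset.

## Within-cycle statistics

Curves are smoothed with a trailing 8-point moving average before any
statistic is computed; the window shrinks at the left edge so the curve
keeps its length and the first smoothed reading equals the first raw
reading (hence OD_i is well defined).  Yield is `log2(OD_f/OD_i)` in
doublings.  The growth rate is `ln(1.5)/t_thr` per hour, where `t_thr`
is the first time the smoothed curve reaches `1.5 × OD_i`; the crossing
is linearly interpolated between the bracketing samples to remove the
5-minute quantization bias.  Natural log is the deliberate choice of
base: it makes the estimator return the true Malthusian rate exactly in
the noiseless exponential limit (verified to 1e-3 over rates
0.02–0.5 h⁻¹), whereas base 10 would rescale all rates by 2.303.  A curve
that never reaches threshold has an *undefined* rate; undefined values
are excluded from location statistics but counted in a reported
`n_undefined`, so group medians are never dragged toward zero.

## Across-transfer rescue metrics

Transfer trajectories are smoothed with a centered window-3 moving
average (shrinking at the edges).  The rescue transfer is the first
transfer after stress onset with a positive first difference of the
smoothed series, scanning left to right — equivalently, the
declining-to-increasing trend change, with the declining-trend
precondition waived at the first evaluable step so a population that
never declines is still classifiable.  Zero differences count as
non-increasing.  The maximum recovery rate is the largest positive
post-stress first difference of the smoothed series.  Both are undefined
(reported as missing) when no positive step exists.

Survival and final size deliberately use the **raw** trajectory:
survival is `median(last 3 raw ODs) > extinction threshold` (strict;
default threshold 0.02, just above blank-level noise, robust to
single-transfer blips), and the normalized final size is the raw tail
median divided by the median final-transfer OD of same-treatment
prototroph reference populations.  Using raw values keeps thresholding
and normalization free of the edge-shrunken smoothing windows; the split
is pinned by tests.

The sign-change detector is intentionally magnitude-free, so on a
trajectory whose OD sits at the measurement noise floor it will fire on
noise.  The pipeline's rescued/extinct call is therefore the survival
classifier, while the rescue transfer is still reported for every
population (as experimental practice does when plotting recovery onset
for all replicates).

## Treatment comparisons

Mann–Whitney U uses the exact null distribution when the combined sample
size is ≤ 12 and tie-free, otherwise the tie-corrected normal
approximation with continuity correction; the route taken is recorded in
the output so results are auditable.  The variance comparison defaults
to the median-centered Brown–Forsythe variant of Levene's test, which is
robust for skewed OD-derived metrics; mean centering is a flag.  The 2×2
survival association reports Pearson chi-squared (df = 1) both without
and with Yates continuity correction, because with ~9 expected counts in
the smaller cells the two variants differ noticeably and the appropriate
choice is a judgement call.  The implementations are scipy's; the test
suite pins them against independent oracles (full enumeration of
labelings for the exact Mann–Whitney p, a hand ANOVA on deviation
tables, and the chi-squared value computed by hand from expected
counts).

## The consortium simulator

The generator is a minimal mechanistic model chosen to produce the
qualitative phenomena of the experimental system — obligate coexistence,
stress-induced collapse, single-partner rescue via reversion to
autonomy, U-shaped trajectories — not a fitted model of any particular
dataset.

**Within a cycle** the state (densities of ΔI, ΔM, ΔI-revertants,
ΔM-revertants, prototroph; free methionine and isoleucine pools; shared
resource) is integrated with a fixed Euler step of 0.05 h over 48 h.
Each auxotroph grows at
`r_aux × Monod(partner amino acid; K_aa) × Monod(resource; K_R)`,
consumes the partner-supplied amino acid 1:1 with its biomass gain
(capped by the pool, which is what makes the dependence obligate), and
releases its partner's required amino acid proportionally to its own
realized growth (release_met = 0.5, release_ile = 3.0 per unit growth)
plus a small growth-independent basal leakage (0.01 per OD per hour)
that lets a fresh coculture bootstrap.  Revertants and the prototroph
grow on the resource alone; revertants pay a 5% autonomy cost.
Per-step biomass demand is scaled down proportionally if it would exceed
the remaining resource, so total biomass gain per cycle is bounded by
the 0.9 OD-equivalent capacity.  Negative state is an error, never
clamped silently.

**Mutation.** New revertant lineages arrive as Poisson draws with mean
`mutation_rate × divisions` of the parental auxotroph in that step
(divisions = biomass gain × cells per OD), seeded at one-cell density
(1/6.4e8 OD).  By default only ΔI can revert, matching the universal
outcome of the experimental system; two-sided reversion is a flag.
Pre-stress mutation (standing variation) is on by default and can be
disabled for clean establishment-time tests.

**Between cycles** each strain's transferred cell count is binomial with
p = 0.05 over its absolute cell count (6.4e8 cells per OD in the 800 µl
working volume), which is the whole demographic stochasticity of the
model; strains below one cell are set to zero.  The transferred aliquot
is spent medium, so amino-acid pools carry over at the dilution fraction
(deterministically — molecule numbers are huge); the resource resets to
capacity.  This carryover is not a convenience: without it an obligate
coculture growing at realistic rates cannot re-bootstrap from empty
pools after a 1:20 dilution and washes out.

**Rates.** r_max is 0.14 h⁻¹ for prototroph-like cells and 0.12 h⁻¹ for
the auxotrophs — the regime of *E. coli* in minimal glucose medium at
30 °C, and the slowest rates that sustain a 1:20 / 48 h transfer regime
with saturation each cycle.  The release asymmetry puts methionine in
the binding role, and the benign-condition ΔI:ΔM equilibrium ratio lands
at ≈ 2.5:1 (asserted within ±20% by the tests).

**Stress presets** scale growth and add death separately for auxotrophs
and prototroph-like cells — the consortium's heightened stress
sensitivity relative to the prototroph is the mechanism that makes
reversion to autonomy a rescue route.  Yield factors set the stressed
plateau.  The shipped presets encode the two stressor phenotypes as
qualitative orderings: *salinity-like* (aux growth ×0.25, death
0.03 h⁻¹; revertant barely slowed, plateau factor 0.38) collapses
gradually, recovers late but fast and high; *pnp-like* (aux growth
×0.05, death 0.08 h⁻¹; revertant ×0.95, plateau factor 0.17) collapses
abruptly, recovers earlier but slower and lower.  With the default
mutation rate of 1e-8 per division, rescue is stochastic at roughly
75–90% of replicates per arm, driven by whether standing revertant
lineages survive the stress-transition bottlenecks.

**Measurement model.** Recorded end-of-cycle OD is total biomass plus
Gaussian noise (sd 0.003, truncated at zero).  What the generator does
*not* emulate: plate effects and drift, blank offsets, lag-phase
physiology, cross-resistance differences among revertant genotypes, and
any genomic detail of the reversion — so passing closure tests shows the
analysis recovers this model's ground truth under realistic noise and
demographic stochasticity, not that it is robust to every artifact of
real plate data.

## Numerical and design choices

- Transfer indices are 1-based (the experiment's "fourth transfer" is
  cycle 4); time within a cycle is 0-based minutes.
- Moving-average edge handling: trailing/shrinking for kinetic curves
  (preserves the first-reading semantics of OD_i), centered/shrinking
  for transfer series.
- Exact Mann–Whitney limit: combined n ≤ 12, tie-free; beyond that the
  normal approximation's error is far below decision-relevant scales.
- Simulator integration step 0.05 h; halving the step changes end-state
  biomass in the fifth decimal, and a revertant-only cycle matches an
  RK45 reference integration to 2%.
- Reproducibility: each replicate consumes an independent RNG stream
  spawned from (seed, culture, replicate-index), so runs are
  bit-identical under a fixed seed and insensitive to replicate count.
- Problem sizes in tests and the acceptance script (48 replicates ×
  20 cycles per arm; 10,000 null simulations; exhaustive oracle sweeps
  to length 10) match the experimental design they emulate while keeping
  a full run in seconds on one core.

## Known limitations

- The rescue-transfer detector has no magnitude threshold by design; on
  extinct, noise-floor trajectories its output is reported but not
  meaningful (use the survival flag to gate it).
- The simulator's stress presets are calibrated to qualitative orderings
  only; absolute recovery rates and final sizes depend on yield-factor
  choices that real data would have to constrain.
- Amino-acid pools are modeled in OD-equivalent consumption units with
  1:1 stoichiometry; real isoleucine/methionine yields per biomass are
  folded into the release coefficients.
- The Levene test and chi-squared variants assume independent
  populations; well-position or plate effects are not modeled.
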