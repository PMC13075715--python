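# Methods

This note records the modelling choices behind `wheatdem`: what each stage
computes, the defaults and why, what the synthetic data emulates and does
not, and the numerical decisions that matter for reproducibility.

## Breakage model

The kernel-scale model is the Tavares particle-replacement family:
a truncated log-normal breakage probability in mass-specific energy, a
power-law size scaling of the median fracture energy with a residual
floor, multiplicative damage accumulation under sub-critical impacts, and
the t10 exponential law for fragment fineness. Units follow milling
practice throughout: energies in J/kg, kernel sizes in mm, moduli in Pa,
angles in degrees (converted to radians only at trigonometric
boundaries).

Interpretation choices where the source conventions are ambiguous:

* the log-normal argument uses `(ln E* − ln E50)/(√2 σ)`, i.e. `σ` is the
  standard deviation of ln-energy; this is the standard form and makes
  `P(E50) = 1/2` exact;
* the size law is read as the *product*
  `E∞ (1 + Kp/Ks) [1 + (d0/d)^φ]`. For wheat against cast iron
  `Kp/Ks ≈ 1.9·10⁻³`, so the product and quotient readings differ by
  under 0.4% — immaterial here, but the choice is fixed;
* a truncation ratio of 100% is interpreted as an untruncated
  distribution (`Emax = ∞`); finite truncation is available through
  `MaterialParams.emax_ratio`;
* the damage equation is solved by successive substitution from `D = 0`
  (absolute tolerance 1e-10, at most 200 iterations, iterates clamped to
  [0, 1]). The iteration map is monotone increasing and bounded, so it
  converges to the least fixed point; the test suite checks it against a
  bisection root-finder to 1e-6 over a γ × energy-ratio grid;
* fragments below the minimum breakable size (0.30 mm) are retained at
  that size rather than deleted, so progeny mass is always conserved;
  collisions below the minimum collision energy (1e-4 J/kg) cause neither
  damage nor breakage; only normal-direction collision energy contributes
  (shear-energy fraction 0);
* progeny generation is a deliberately simple mass-conserving two-bin
  scheme (a fine bin of t10% of the parent mass at one-tenth the parent
  size, the remainder in one coarse fragment). The full progeny
  size-distribution machinery of commercial DEM codes is out of scope.

## Contact-parameter reduction

Static friction is the tangent of the slip angle, count-weighted because
the rig records how many kernels slip per angle (the weighting makes the
result identical to pooling one record per kernel, and permutation /
count-splitting invariance is tested). Rolling friction follows the
energy balance `ϑ = l sinθ / (l cosθ + s)` for a kernel released on a
30°, 20 mm slope. Restitution comes from rebound kinematics off a 45°
plate, `e₁ = L1/(2√(Hh))` (the cos 45° factors cancel); records implying
`e₁ > 1` are physically impossible and are excluded with a warning.
Summaries report per-group sample mean and SD (n−1) and an **unweighted
mean of group means** as the overall value, rounded to three decimals —
this is the convention that reproduces the reference summaries exactly;
per-kernel pooling is available as an option.

## Repose response surface

The three wheat-wheat contact coefficients are calibrated by matching a
simulated angle of repose to the measured 29.765°. The three-factor
Box-Behnken design (12 edge midpoints + 5 center replicates = 17 runs) is
generated directly; the full quadratic surface is fitted by OLS in
natural units. The ANOVA reports partial (Type-III) sums of squares
computed on the *coded* (−1..+1) design — the convention of
response-surface software, under which the linear-term SS are free of
correlation with the quadratic columns; fitted values and the
residual/lack-of-fit/pure-error decomposition are coding-invariant. Pure
error comes from exact factor-replicate groups; lack of fit is tested
against it. No multiple-testing adjustment is applied (none is customary
in this design).

Surface inversion minimises |predicted α − target| by a dense grid
(default 200 points per factor, evaluated in memory-bounded slices)
followed by Nelder-Mead refinement clipped to the factor box. Because a
quadratic's level set is a surface, any target strictly inside the
attainable range has a manifold of solutions: the optimizer flags this
and deterministically returns the candidate nearest the box center.
Unattainable targets return the boundary best with a warning.

The published quadratic coefficients and exact ANOVA table are *not*
reproduction targets: the printed equation predicts ≈ 23.7° at the design
center against an observed 31.82° (digits lost in typesetting), and the
printed pure-error SS differs ~1% from the value recomputed from the
printed center responses (rounding). The fit is therefore validated
against OLS internal properties, the recomputed center statistics
(31.82° ± 0.14°) and coefficient recovery on noiseless synthetic
surfaces.

## Fracture-energy calibration

Specific fracture energy is the trapezoidal integral of the
force-displacement curve up to the fracture point divided by kernel mass;
with displacement in mm, force in N and mass in g the quotient is already
in J/kg. The fracture point is detected as the running-maximum sample
preceding the first force drop of ≥ 30% of the local maximum within a
3-sample window; drops only qualify once that maximum exceeds 5% of the
curve's global peak, so sensor noise around zero force cannot trigger.
All three thresholds are exposed as arguments; the defaults were chosen
to be robust on the synthetic curve family.

Energies are ranked and assigned median-rank plotting positions
`P_i = (i − 0.5)/N`; the log-normal CDF is then fitted by nonlinear least
squares in `(ln E, P)` space (not maximum likelihood), matching the
plotted-curve convention with a reported R². Size classes are assigned by
nearest class equivalent diameter `De = [L(W+T)²/4]^(1/3)`; class weights
default to sample frequencies, with published weights accepted as an
override. The population E50 is the weight-averaged class median. The
size law `E50(d)` is fitted by multi-start nonlinear least squares
(20 log-spaced deterministic starts, best SSE wins, power term evaluated
in log space for robustness); a fitted φ near zero is flagged degenerate.
Note the three-parameter law is weakly identified from four class medians
spanning a ~1.5× energy range — the fitted *curve* is reproducible, the
individual constants are not, which is also why the published fitted
constants (E∞ = 73.40 J/kg, d0 = 5.34 mm, φ = 12.63) are mutually
inconsistent with the published class medians and are treated as
configuration inputs only. Likewise the published weighted E50
(2069.78 J/kg) is not reproducible from the published class values and
weights (direct computation gives 2080.41 J/kg); the package reports what
it computes.

## Damage-coefficient estimation

γ is the only free parameter of the damage law and is estimated from
repeated-impact outcome data: for each candidate on a grid (default
0.5–20, step 0.1) the drop-weight campaign is forward-simulated
(log-normal fracture-energy draws; per impact, break if `e·Ek ≥ Ef`, else
weaken) and the simulated cumulative breakage-probability curve is
compared with the empirical one by summed squared deviation. One fixed
seed is shared by all candidates (common random numbers), making the SSE
surface deterministic and smooth in γ; the grid minimum is refined by a
parabolic step through its neighbours. Kernels unbroken after `n_max`
impacts (default 100) are censored and contribute "still unbroken"
information up to `n_max`. The default simulation size is 10⁴ virtual
kernels; self-consistency recovery of γ = 5 within one grid step at that
size is part of the acceptance suite. At the reference energy
(268.8 J/kg, about 13% of the median fracture energy) damage per impact
is ≈ 0.8%, so typical kernels break after ~50–70 impacts, and the curve
position is strongly γ-sensitive (≈ 10% damage change per 0.1 in γ),
which is what makes the grid estimate sharp.

## Forward simulators and validation

The repeated-impact simulator consumes its seeded generator in kernel
order (documented so replays are bit-reproducible; the test suite replays
it kernel-by-kernel through the scalar damage update). The single-kernel
compression simulator is an explicit stand-in for a multi-particle DEM
run: Hertzian sphere-plate contact `F = k δ^{3/2}` with
`k = (4/3) K* √R` from the composite plane-strain stiffness, loaded
quasi-statically until the accumulated mass-specific energy (trapezoidal
on the sampled trace) reaches the kernel's fracture energy. The reported
fracture energy is that same trapezoidal integral, so trace and energy
agree exactly by construction. It reproduces the *workflow* (replicates,
ensemble mean/SD/CV, relative error against experimental indicators) but
not the absolute force level of a full DEM contact model with particle
shape — all published-value comparisons in the validation metrics are
computed from the published numbers themselves and are independent of
this stand-in.

## Synthetic data: what it shows and what it cannot

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes: Gaussian per-kernel contact
coefficients at the reference means and dispersions mapped back through
the inverse measurement equations; Hertzian compression curves cut at
log-normally drawn fracture energies with a three-sample post-fracture
collapse and optional additive force noise (0.5 N default, about 0.5% of
a typical peak); impact outcome series from the forward damage model; and
a quadratic repose surrogate (coefficients refit by OLS from the
reference run table) with Gaussian replicate noise at the reported
center-point SD of 0.14°. Sample sizes default to the physical campaigns
(5×20 friction kernels, 3×50 rebound kernels, 80 compression kernels,
17 design runs).

Passing the recovery tests therefore shows the *estimators invert the
assumed data-generating process correctly*; it cannot show that real
wheat follows that process. In particular the synthetic curves are
smooth Hertzian ramps without the yielding shoulder, anisotropy or
multi-peak post-fracture structure of real kernels, the repose surrogate
has no DEM physics in it, and the contact scatter is Gaussian by
construction. Zero-noise configurations make every stage an exact round
trip except where sampling variability is intrinsic (fracture energies
are drawn from a distribution even at zero measurement noise), which is
why the end-to-end zero-noise test runs 800 compression kernels and
accepts 5% on class statistics and ±0.5 on γ (calibration error from the
fracture stage propagates into the γ stage), versus ±0.1 for the isolated
γ recovery.

## Problem sizes and determinism

Default problem sizes were chosen to keep each stage in seconds to a
couple of minutes on one CPU: 10⁴ kernels per impact simulation, a
196-point γ grid, 200³ optimizer grid evaluated in slices, 800-kernel
compression campaigns in the analysis drivers. Every stochastic component
takes an explicit integer seed; the pipeline derives stage seeds by fixed
offsets from the config seed, records the config hash and seed in its
report, and produces byte-identical reports for identical configs (stage
timings go to the log, not the report).

## Known limitations

* The compression stand-in is rate-independent and spherical; it cannot
  validate force-displacement *shape* against bench curves.
* Censoring in the γ estimation is handled by curve truncation, not by a
  likelihood; with heavy censoring (> ~50%) the grid SSE flattens.
* The two-bin progeny scheme conserves mass but not surface area or size
  distribution beyond the t10 split.
* The ANOVA's Type-III convention matches single-df quadratic designs;
  it does not generalise to aliased or mixed-level designs (rank
  deficiency raises with the aliased terms named).
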