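# wheatdem

Calibration and validation of a **Tavares-type particle breakage model for
wheat kernels**, aimed at discrete-element (DEM) simulation of roller
milling. The package implements the full desk-scale calibration workflow a
DEM practitioner needs before running a mill simulation: reducing bench
measurements to contact coefficients, calibrating the inter-particle
contact parameters against the angle of repose by response-surface
methodology, fitting the log-normal fracture-energy distribution of single
kernels from compression tests, estimating the cumulative damage
coefficient from repeated drop-weight impacts, and validating the
assembled parameter set against compression fracture indicators.

## The model

A kernel stressed with mass-specific energy `E` (J/kg) breaks with
probability

    P(E) = 1/2 [1 + erf((ln E* − ln E50) / (√2 σ))],   E* = Emax·E/(Emax − E)

an (optionally upper-truncated) log-normal in `E` with median `E50` and
log-SD `σ`. The median scales with kernel size `d` as

    E50(d) = E∞ (1 + Kp/Ks) [1 + (d0/d)^φ]

where `K = Y/(1 − ν²)` are the plane-strain stiffnesses of kernel (p) and
tool (s): small kernels are disproportionately stronger, with residual
crushing energy `E∞` as the large-size floor. An impact below the fracture
threshold does not break the kernel but weakens it, `Ef′ = Ef (1 − D)`,
with the damage `D` solved from the implicit relation

    D = [ (2γ / (2γ − 5D + 5)) · e·Ek/Ef ]^(2γ/5)

by successive substitution from `D = 0`; `γ` is the cumulative damage
coefficient (larger `γ` = less damage per impact) and
`e = 1/(1 + Kp/Ks)` the fraction of collision energy absorbed by the
kernel. Fragment fineness after breakage follows the t10 law
`t10 = A [1 − exp(−b·e·Ek/E50)]`.

The multi-particle DEM runs themselves (repose pile, compression in a
commercial solver) are out of scope; they are replaced by pluggable
response evaluators and simple executable stand-ins so every calibration
stage runs and is testable on a desk.

## Worked example

Fit the quadratic repose surface to the bundled 17-run Box-Behnken table
and invert it for the wheat-wheat contact parameters:

```python
from wheatdem import datasets
from wheatdem.repose_rsm import (BBRun, fit_quadratic, center_replicate_stats,
                                 optimize_contact_params, relative_error)

runs = [BBRun(*r) for r in datasets.BBD_RUNS]
model = fit_quadratic(runs)
mean, sd = center_replicate_stats(datasets.BBD_CENTER_ALPHAS)
opt = optimize_contact_params(model, target_alpha=29.765)
print(round(model.r2, 5), round(mean, 2), round(sd, 2))
print([round(p, 3) for p in opt.params], round(opt.achieved_alpha, 3))
```

prints

```
0.99609 31.82 0.14
[0.325, 0.274, 0.034] 29.765
```

i.e. the surface explains 99.6% of the response variance, the five center
replicates average 31.82° with SD 0.14°, and a contact triple on the box
reproduces the experimental repose angle of 29.765° exactly (the solution
set is a level surface; the reported triple is the candidate nearest the
box center). The drop-weight impact energy for the reference test
(32 g ball, 0.03 m drop, 0.035 g kernel) evaluates to 268.8 J/kg:

```python
from wheatdem.tavares_core import impact_energy
from wheatdem import datasets
print(round(impact_energy(datasets.default_drop_weight()), 1))   # 268.8
```

The numbered drivers under `analysis/` run the five calibration stages in
order (`01_contact_parameters.py` … `05_validation.py`) and write their
tables under `results/`; `wheatdem run-all --outdir results/pipeline`
chains everything on synthetic data into a single calibration report.

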