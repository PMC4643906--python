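# Methods

`inhibkin` analyses steady-state inhibition of a Michaelis–Menten enzyme —
the motivating system is hydrolysis of radiolabelled anandamide by fatty
acid amide hydrolase (FAAH) in brain homogenate — from long-format
velocity tables and concentration–response curves. This note records the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Velocity models

All concentrations are micromolar; velocity units are arbitrary (Vmax
absorbs the scale, and every estimator is scale-equivariant).

**Linear mixed inhibition.** The observed velocity is

    v = Vmax_app / (1 + Km_app/[S])
    Vmax_app = Vmax / (1 + [I]/(α·Ki))
    Km_app   = Km · (1 + [I]/Ki) / (1 + [I]/(α·Ki))

with inhibition constant `Ki` and cooperativity factor `α`. `α → ∞`
recovers pure competitive inhibition, `v = Vmax/(1 + (Km/[S])(1 + [I]/Ki))`,
which is implemented as its own model (the mixed form delegates to it when
`mode="competitive"`). `α = 1` would be pure noncompetitive. `[S] = 0`
returns `v = 0` rather than an error so blank wells can be simulated.

**Dixon construction.** For these models `1/v` is exactly linear in `[I]`
at fixed `[S]`:

    1/v = (Km/S + 1/α)/(Vmax·Ki) · [I] + (1 + Km/S)/Vmax

so the lines for any two substrate concentrations are concurrent at
`[I] = −Ki`, `1/v = (1 − 1/α)/Vmax` (height `1/Vmax` in the competitive
limit). With `n` substrate levels there are `C(n, 2)` pairwise
intersections — 28 for the 8-level design used throughout. Taking the
*median* of the intersection x-coordinates (in the spirit of the direct
linear plot of Eisenthal & Cornish-Bowden) gives a Ki estimate with a
high breakdown point: a few wild intersections, which arise whenever two
lines are nearly parallel, barely move it, whereas they wreck a mean.
Line pairs whose relative slope difference is below `1e−6` are excluded
from the census (and reported as excluded) instead of contributing
numerically explosive crossings; the census conservation
`pairs + excluded = C(n,2)` is enforced.

**Two-inhibitor model.** Joint occupancy follows the multiple-inhibition
framework in which the denominator term is
`1 + I1/K1 + I2/K2 + I1·I2/(β·K1·K2)`: `β = ∞` means the inhibitors are
mutually exclusive (parallel Dixon lines of `1/v` vs `I1` across `I2`
levels), finite `β` permits simultaneous binding, making the slope in `I1`
grow with `I2` (the "V" shape).

**Concentration–response.** Potency uses the four-parameter logistic on
the log10 molar axis in the inhibition convention,

    response = bottom + (top − bottom) / (1 + 10^((x + pIC50)·n_H)),

monotone *decreasing* in concentration for positive Hill slope `n_H`, with
the midpoint at the IC50. `pIC50` is molar, so `IC50_µM = 10^(6 − pIC50)`.

## Fitting

All nonlinear fits use `scipy.optimize.least_squares`
(Levenberg–Marquardt) with positive parameters (Km, Vmax, Ki, α) estimated
on the log scale, which enforces physical bounds without constraints.
Standard errors come from the Gauss–Newton curvature at the optimum
(`(RSS/dof)·(JᵀJ)⁻¹`), back-transformed to the natural scale by the delta
method. Residuals are unweighted.

**Multi-start.** Kinetic fits seed a 3×3×3 grid of log-spaced Km, Ki and α
values anchored at the data (geometric mid-substrate, geometric
mid-inhibitor, α ∈ {0.5, 3, 30}), rank the grid points by raw RSS, and
polish the best three with Levenberg–Marquardt. This gives the same
coverage as polishing every grid point at a fraction of the cost; on exact
model data the estimates return the generating parameters to optimizer
tolerance. Potency fits multi-start over pIC50 (spanning the sampled
concentration range) × Hill slope ∈ {0.5, 1, 2}, with the top plateau
fixed at 100% of control and the bottom either pinned to 0 or floating.

**Model selection.** Candidates fit to the same data are compared by the
Gaussian-residual Akaike criterion `AIC = n·ln(RSS/n) + 2k`, where `k`
counts the free parameters plus one for the residual variance. Smallest
wins; exact ties resolve toward fewer parameters. A caveat worth knowing:
when the true model is competitive, the mixed model nests it at the α→∞
boundary, so AIC picks the spuriously richer model whenever the
likelihood-ratio gain exceeds 2 — about 8% of datasets *regardless of how
low the noise is* (the boundary mixture `0.5·χ²₀ + 0.5·χ²₁`). Competitive
→ mixed misselection therefore plateaus near 92–95% accuracy; it is a
property of AIC on nested models, not of the optimizer. AICc is available
(`aic_from_rss` takes the counts needed to add it) but plain AIC is the
default.

**Robust Dixon lines.** Straight lines of `1/v` vs `[I]` are fit by
iteratively reweighted least squares with the Tukey bisquare loss
(tuning constant 4.685, median-absolute-deviation scale), via statsmodels
RLM. With fewer than 4 points robust weights are meaningless and the fit
falls back to OLS; two points are interpolated exactly, and
near-perfectly-collinear data short-circuit to OLS before the MAD scale
can degenerate. The response is normalised by its median absolute value
before IRLS so results are exactly equivariant under rescaling of the
velocity units.

**Exclusivity test.** At fixed substrate, the family of `1/v`-vs-`I1`
lines (one per `I2` level) is fit twice: slopes free (2g parameters) and
one shared slope (g+1). Because velocity noise has roughly constant CV,
`sd(1/v) ∝ 1/v`, so both fits use `1/y²` weights — without them the
extra-sum-of-squares F test is badly anti-conservative at strong
inhibition. The verdict is `mutually_exclusive` when the shared-slope
model survives (F-test p ≥ 0.05 and ΔAIC ≤ 2), `cooperative` when the
free-slope model is clearly preferred (p < 0.05, ΔAIC ≥ 2) *and* the
slopes trend upward with `I2` (Kendall τ > 0), and `inconclusive`
otherwise. The thresholds are this package's choice; the underlying
parallel-vs-"V" criterion is the standard multiple-inhibition one.

## Albumin ligand depletion

Assay mixes carry fatty-acid-free bovine serum albumin (the substrate mix
keeps the substrate:albumin molar ratio near 1:4.5, i.e. ~2.25 µM albumin
at 0.5 µM substrate). A lipophilic inhibitor partitions onto it, so the
free concentration is the positive root of the 1:1 depletion quadratic

    free² + free·(capacity − total + kd) − kd·total = 0,

evaluated in the cancellation-safe form. One site class is assumed
(multiple sites fold into `capacity`); mass balance
`free + capacity·free/(kd + free) = total` holds to ≤1e−10 relative.
Refitting a 4PL against the *total* axis after depletion right-shifts the
apparent IC50 and steepens the apparent Hill slope — with capacity well
above the true IC50 and tight binding (kd ≪ capacity) the apparent n_H
rises past 3, reproducing qualitatively the anomalously steep curves seen
for strongly albumin-bound inhibitors such as carprofen. Substrate
depletion by the same albumin is deliberately not modelled: added
substrate concentration is treated as `[S]`, following assay convention.

## Synthetic data generator

The generator is the package's stand-in for homogenate radioassay data and
defines the conditions every Monte-Carlo statement refers to:

| parameter | default | rationale |
|---|---|---|
| substrate grid | 8 points, 0.5–4 µM, even | kinetic assay design |
| inhibitor grid | 0, 0.5, 1, 2 µM | brackets a sub-µM Ki; zero control |
| replicates | 3 | typical N = 3–4 per condition |
| noise | multiplicative Gaussian, CV 5% | SEMs roughly proportional to signal |
| additive floor | 0 (off) | available for low-velocity wells |
| generating Ki, α | 0.8 µM, 3.2 | sub-µM mixed inhibitor, single-figure α |

Noise is `v·(1+ε)`, `ε ~ N(0, CV)`, optionally plus `N(0, additive_sd)`,
truncated at zero (truncations are counted and warned about). Seeding uses
`numpy.random.default_rng(seed)`; a fixed config is bit-reproducible.
Concentration–response tables are normalised so zero-inhibitor rows
average exactly 100%. The dilution protocol returns noiseless expectations
for the three arms (undiluted, diluted, matched-free) under reversible or
irreversible assumptions.

What the generator does *not* emulate: radiochemistry (charcoal
extraction, quench, counting statistics), drift between replicate runs,
pipetting correlation within plates, or substrate depletion during the
incubation. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
real-assay pathology.

## Monte-Carlo problem sizes

Recovery and discrimination studies use 200 simulated tables per condition
(100 seeds for the corruption-robustness comparison), at the default
8×4×3 design. At these sizes the medians quoted by the acceptance script
are stable to ~1–2% between seeds, and the full script completes in well
under a minute on one CPU.

## Known limitations

- Dixon median-intersection Ki has no formal confidence interval here.
- α is estimated only by the nonlinear fit, never from Dixon intercepts.
- The albumin model is single-site; multi-class binding and substrate
  sequestration are out of scope.
- Competitive-vs-mixed AIC selection carries the irreducible ~8%
  boundary-overfit rate described above.
- No tight-binding (Morrison) or substrate-inhibition equations.
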