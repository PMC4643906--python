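# inhibkin

Enzyme-inhibition kinetics for steady-state radioassay data: who inhibits
what, how strongly, by which mechanism, and whether two inhibitors share a
binding site. The package was built around the analysis of reversible FAAH
(fatty acid amide hydrolase) inhibitors assayed by [³H]anandamide
hydrolysis in brain homogenate, but nothing in it is specific to that
enzyme.

It provides, as a library plus a thin `inhibkin` CLI:

- **Potency fitting** — four-parameter logistic concentration–response
  fits with the top fixed at 100% of control and the bottom pinned to zero
  or floating, selected by Akaike's criterion; reports pIC50/IC50
  (`IC50_µM = 10^(6−pIC50)`) and the Hill slope n_H.
- **Mechanism fitting** — global nonlinear least squares of a substrate ×
  inhibitor velocity table to the linear mixed-inhibition model
  (`v = Vmax_app/(1 + Km_app/[S])` with
  `Vmax_app = Vmax/(1+[I]/(αK_i))`,
  `Km_app = Km(1+[I]/K_i)/(1+[I]/(αK_i))`) and to its pure-competitive
  limit (α→∞), with AIC deciding between them; returns K_i ± SE, α ± SE.
- **Dixon analysis** — robust (Tukey bisquare) lines of 1/v vs [I] at each
  substrate level, all C(n,2) pairwise intersections, and the
  median-intersection K_i = −median(x), which shrugs off outlying
  crossings the way the direct linear plot's median estimator does.
- **Mutual exclusivity** — two-inhibitor Dixon families tested for
  parallel lines (mutually exclusive binding) versus a "V" opening toward
  the y-axis (cooperative binding), by a weighted shared-slope vs
  free-slope comparison (F test + ΔAIC).
- **Albumin ligand depletion** — the 1:1 sequestration quadratic giving
  free from added inhibitor concentration, explaining anomalously steep
  apparent Hill slopes (n_H ≈ 3) for strongly albumin-bound compounds.
- **Synthetic assays** — a seeded generator of velocity and
  concentration–response tables (8 substrate points spanning 0.5–4 µM,
  3 replicates, 5% CV multiplicative noise by default) so every estimator
  is testable without laboratory data.

## Worked example

Simulate a mixed-inhibition experiment (K_i = 0.8 µM, α = 3.2, Km = 1.5 µM,
5% CV, seed 7) and analyse it both ways:

```python
import inhibkin as ik

mm  = ik.MMParameters(Km=1.5, Vmax=1.0)
inh = ik.InhibitionParameters(Ki=0.8, alpha=3.2)
tab = ik.simulate_velocity_table(
    ik.SimulationConfig(seed=7, mm=mm, inhib=inh, noise_cv=0.05))

best = ik.fit_inhibition_kinetics(tab).best
print(best.model_label, best.inhib.Ki, best.se["Ki"], best.inhib.alpha)

fam = ik.build_dixon_family(tab)
est = ik.median_intersection_ki(ik.pairwise_intersections(fam))
print(est.ki, est.n_used)
```

This prints (values abbreviated):

```
mixed  Ki 0.744 ± 0.063 µM   alpha 4.12 ± 0.99
dixon  Ki 0.838 µM from 28 intersections
```

The AIC comparison selects the mixed model over the competitive one
(ΔAIC = 34 in this run), the nonlinear fit recovers the generating K_i and
α within their standard errors, and the 8 Dixon lines yield all 28
pairwise intersections whose median projects to a compatible K_i. The same
analyses are available from the shell:

```
inhibkin simulate --seed 7 --out table.csv
inhibkin fit-kinetics table.csv
inhibkin dixon table.csv
```

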