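# Methods

## The decision model

The model is a single-stage decision tree. The decision node is the choice
of treatment (one of the tabulated antipsychotics, or placebo); the chance
node resolves to improved or unimproved delirium with the treatment's
transition probability *p*. The QTc interval on treatment is the baseline
value plus the drug's mean QTc shift Δ (ms), and each leaf is valued by a
QTc-dependent utility, giving

EU(b) = p·U_imp(b + Δ) + (1 − p)·U_unimp(b + Δ).

Assumptions inherited from this structure: a single evaluation horizon
(no Markov dynamics, costs or discounting); the drug's full mean QTc shift
is applied at once; delirium response and QTc shift act independently
through *p* and Δ; placebo has probability p₀ and zero QTc shift and
competes in every ranking.

## Effect sizes and the odds-ratio transform

Treatment effects enter as a table of (p, plausible range) and (Δ, 95% CI)
per drug. Probabilities derive from meta-analytic odds ratios against the
placebo rate via p = A/(1+A), A = OR·p₀/(1−p₀); p₀ defaults to 0.5 (the
day-3 placebo improvement rate in the trial evidence the packaged table is
built on). The packaged table's plausible ranges are symmetric on the
log-OR scale to within 0.018 (printing precision) and asymmetric on the
probability scale, so the package parameterises probability uncertainty on
the log-OR scale throughout: mean = ln OR, sd = (ln OR_hi − ln OR_lo)/(2·1.959964).
The table loader enforces this symmetry within a 0.03 tolerance, along
with bound ordering, open-unit-interval probabilities, and unique names.

## Utility curves

Both health states use a decreasing sigmoid inflected at 500 ms, where
torsade-de-pointes risk takes off: concave (risk-averse) below the
inflection, convex (risk-seeking) above it. Defaults: improved Min 30,
Max 100; unimproved Min 0, Max 30; slope 0.05/ms; inflection 500 ms. With
matching shape parameters the improved curve dominates the unimproved one
pointwise, which makes expected utility increasing in *p*; the pair
validator enforces the configurations that guarantee this.

For risk-attitude sensitivity analysis, three variant families with fixed
second-derivative sign are provided: linear (zero), exponential convex
(positive) and exponential concave (negative). Their exact published
parameterisations are not recoverable, so the package anchors each variant
on a bounded QTc domain (default 380–620 ms) with the sigmoid's limit
utilities at the endpoints and clamps outside; the exponentials use
u(q) = u_min + (u_max − u_min)·(e^{k·s} − 1)/(e^k − 1) with s the
normalised reversed position and |k| = 3 (a visibly curved but monotone
bow). Note the geometry: a decreasing convex curve lies below the linear
chord, the concave one above it.

The default sweep crosses improved Min ∈ {10, 30, 50} with unimproved
Max ∈ {10, 30, 50} (combinations whose unimproved maximum falls below the
improved minimum are dropped — they would open a utility band no state can
reach) and slope ∈ {0.025, 0.05, 0.1}, 18 patterns, each evaluated under
all four families. The sweep reports per-baseline winners, the modal winner
across settings, and whether it matches the default-setting winner.

## Rankings and numerical conventions

Expected utilities are reported to two decimals; machine CSVs are
unrounded. Rankings compare utilities at the two-decimal reporting
precision, with ties resolved by input-table order (`precision=None`
compares exact floats). This matters once on the packaged table: at
baseline 420 ms amisulpride (84.05821) and quetiapine (84.05833) differ by
1.2×10⁻⁴ utility units — far below what three-decimal inputs can resolve —
so the ranking treats them as tied and table order puts amisulpride first,
matching the source analysis (whose unrounded inputs resolved the same
near-tie the same way). At every prolonged baseline the gap is large and
the precision choice is irrelevant. Presentation tables round half away
from zero to integers.

## Probabilistic sensitivity analysis

Per draw, each drug's log-OR and QTc shift are sampled independently
(within and across drugs; no correlation structure is assumed) from
normals matched to the 95% intervals; the log-OR draw maps back through
the odds-ratio transform, keeping sampled probabilities inside (0, 1). A
truncated-normal-on-p alternative sits behind
`PsaConfig(probability_scale="truncated_normal_p")` for robustness
comparison. One draw matrix is shared across baseline columns by default
(the baseline only shifts the utility argument), switchable. Defaults:
10,000 draws, a single seeded NumPy PCG64 generator, seed 20210625. Win
shares count the per-draw argmax among all options including placebo, ties
to the earlier option — a measure-zero event under continuous sampling.
Degenerate (zero-width) intervals reproduce point estimates exactly, so
the PSA collapses onto the deterministic analysis.

A tensor-product Gauss–Hermite quadrature (60 nodes per dimension) of the
same expectation serves as an independent oracle; Monte Carlo means agree
with it within 3 Monte Carlo standard errors on every packaged-table cell.

## Synthetic data

The generator emulates the packaged table's structure: latent truths drawn
uniformly on the sampling scales (log-OR mean/sd, QTc-shift mean/sd), then
emitted as point ± 1.959964·sd, so probability intervals are exactly
log-symmetric and every record validates by construction. Default ranges
(log-OR mean 0.4–1.5, sd 0.2–1.6; shift 0–15 ms, sd 0.6–3.3 ms) bracket
the packaged magnitudes. What it does not emulate: correlation between
efficacy and QTc effects, publication bias, non-normal meta-analytic
uncertainty, or heterogeneity between indications — so passing recovery
tests demonstrates pipeline correctness under the model's own assumptions,
not robustness to violations of them. The recovery experiment plants a
winner with a log-OR 1.0 above the field's upper range, zero QTc shift and
intervals shrunk fourfold, and requires both the deterministic argmax and
the largest PSA win share to name it at every baseline.

## Problem sizes

The deterministic analysis is closed-form and instantaneous. Reported PSA
summaries use 10,000 draws (Monte Carlo standard errors ≈ 0.04–0.16
utility units); test-suite PSAs use 200–10,000 draws and the recovery
property uses 2,000 draws over 20 seeds, sizes at which the checked
margins are many standard errors wide.

## Known limitations

- The effect table mixes evidence populations (delirium trials for
  response; schizophrenia trials for QTc shifts) — inherited from the
  sources, not correctable here.
- Single-stage tree: no dosing, duration, or time-varying p₀.
- Variant utility families are this package's parameterisation of the
  stated curvature constraints; conclusions that depend on their exact
  shape (rather than curvature sign) should be checked with custom
  patterns.
- The 420 ms winner is a genuine near-tie at published input precision;
  small changes to the inputs flip it, as the PSA's 36% vs 31% win split
  there makes visible.
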