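# Methods

## The measurement being modelled

A microfluidic NMR titration holds a fixed total protein concentration [P]
while the total ligand concentration [L] rises step by step: each step injects
a small volume v of a protein+ligand stock (solution b) into a chip circuit of
volume V that initially contains a protein-only stock (solution a), displacing
an equal volume of the fully mixed contents. Both stocks carry the same [P],
so only the ligand (and the TSP internal standard, which is deliberately
loaded at a ≥10× different concentration in the two stocks) changes between
steps. A ¹H 1D spectrum gives the TSP intensity I_TSP; a ¹H–¹⁵N HSQC gives
one assigned peak per backbone amide.

## Mixing model

The circuit is treated as a single well-mixed compartment: after injecting
volume v, every solute concentration updates as c ← (c(V−v) + c_b v)/V.
For constant v this has the closed form

    c_n = c_b · (1 − (1 − v/V)^n),

which the implementation matches to 1e−12 (tested up to n = 50). Plug-flow
displacement would mix slightly differently, but the analysis never uses the
nominal schedule — the TSP calibration measures the realized mixing ratio —
so the single-compartment choice only affects the synthetic data, not the
estimator. Injection volumes are drawn Normal(2.0, 0.25) μL truncated to
(0, V), matching a syringe-pump repeatability of ±0.25 μL (1 sd); sd = 0
gives exact volumes.

## Binding model

Two-state fast exchange: with α = [L]/[P] and β_D = K_D/[P], the bound
fraction is the physical root of β_D·f = (1−f)(α−f),

    f(α, β_D) = ((α + 1 + β_D) − sqrt((α + 1 + β_D)² − 4α)) / 2.

The code evaluates the conjugate form 2α/(s + sqrt(s² − 4α)), s = α+1+β_D,
which is free of cancellation for small f (stable to β_D = 1e−8 and below)
and extends smoothly to the slightly negative α the optimizer may probe while
the calibration line is free. The form is verified in the tests against an
independent bracketing root-finder for the mass-action equilibrium on a
200×200 (α, β_D) grid to 1e−10.

## CSP table

Per residue and step, Δδ = sqrt(Δδ_H² + (w_N·Δδ_N)²) with w_N = 0.14, the
standard amide weighting reflecting the ~7× larger ¹⁵N shift range; it is a
parameter (`n_weight`) because other weightings are in circulation. Δδ_max is
the value at the designated saturated step (the last step by default). The
saturation check — the largest |Δδ(last) − Δδ(second-last)| over residues —
is reported as a diagnostic rather than enforced, since deciding saturation
is an experimental-design question. Trajectory linearity (the fast-exchange
two-state signature) is scored as the maximum perpendicular deviation from
the total-least-squares line through the weighted (δ_H, w_N·δ_N) points.

Peak tracking matches labels exactly by default; a nearest-neighbour mode
(weighted distance, per-axis tolerances, ties within 1e−6 ppm flagged rather
than guessed) exists for lists with inconsistent labelling. Two peaks within
(0.02 ppm ¹H, 0.2 ppm ¹⁵N) of each other at any step mark both residues as
overlapped; overlapped residues stay in the table but are excluded from the
K_D fit by default, because an overlapped peak's apparent position (and hence
its fractional shift) is biased by its neighbour.

## Significance selection

σ_c is the corrected standard deviation of all Δδ_max values: the standard
deviation about zero (√(Σx²/n) — CSPs are non-negative with a null value
near zero), iteratively recomputed after removing values exceeding 3σ, until
a fixed point; residues with Δδ_max strictly above the final σ_c are
significant. Computing about the mean and other multipliers are exposed as
options. The fixed point is independent of the order in which over-threshold
values are removed (property-tested by exhaustive enumeration on small
lists). Note the selection logic is collective: when the perturbed residues
are numerous enough that 3σ never excludes them (as in the packaged fixture,
12/59 residues at ~0.27 ppm give σ_c ≈ 0.12 ppm), σ_c sits between the
background and the binding site and the selection is clean; when they are few
and extreme they are excluded from σ_c and still selected as > σ_c.

## Global fit

Only significant, non-overlapped residues enter. The residual for residue i
at step k is

    Δδ_ik/Δδ_max,i − f(α_k, β_D)/f(α_K, β_D),   α_k = slope·I_TSP,k + intercept,

with K the saturated step, minimized by Levenberg–Marquardt over
(log β_D, slope, intercept); fitting log β_D enforces positivity without
constraint machinery. Normalizing the model by its own saturated value is
deliberate and load-bearing: the data are normalized by the *observed* Δδ_max
= f(α_K, β_D)·Δδ_max,true, so a model normalized to 1 at saturation is only
correct if f(α_K) = 1 exactly. At realistic conditions (α_max = 5,
β_D ≈ 0.05, f(α_K) ≈ 0.985) the mismatch does not shrink K_D by the naive
1.5%: the free calibration lets the optimizer slide along the β_D–slope
valley chasing the plateau, and the unnormalized fit lands 57% low on
noiseless data. The normalized form recovers noiseless ground truth to
machine precision and reduces to the plain fractional-shift model in the
fully saturated limit. An optional shared-scale mode (a fourth free
multiplier) is available but off by default. Saturated-step residuals are
identically zero by construction and are dropped from the residual vector and
the degrees of freedom.

Initialization: slope/intercept from the line through (I_TSP at step 0, α=0)
and (I_TSP at the saturated step, nominal α_max); β_D from the best of a
9-point log-spaced grid of starts, 1e−3 to 10. Confidence intervals are
t-based from the Jacobian covariance (dof = points − parameters), with the
log-β_D variance mapped to β_D by the delta method and the K_D interval equal
to the β_D interval scaled by [P]; a case-resampling bootstrap over residues
is available (`ci_method="bootstrap"`).

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the estimator relies on —
displacement-mixing concentration series, two-state peak movement (hence
exactly collinear noiseless trajectories), a TSP intensity affine in the
mixing fraction, and independent Gaussian shift noise (defaults 0.002 ppm ¹H
/ 0.02 ppm ¹⁵N, the order of a <10 Hz apparent resolution at 14.1 T) plus
0.5% relative intensity noise. It does not simulate lineshapes, overlap-
induced peak pulling, intermediate/slow exchange, assignment errors, sample
degradation, or field drift; passing tests therefore demonstrate correctness
of the analysis under its own assumptions, not robustness to those effects.

The packaged fixture mimics a 59-amide SH3 domain: residue numbers 84–147
with five positions removed, twelve residues in three patches (96–100,
117–120, 135–137) given |Δδ_max,H| ∈ [0.20, 0.26] and |Δδ_max,N| ∈ [0.9, 1.1]
ppm with random signs (combined Δδ_max ≈ 0.24–0.30 ppm, typical of a
peptide–SH3 interface), all other residues exactly unperturbed. Free peak
positions are sampled uniformly over the amide region with a minimum
separation of twice the overlap tolerance, so the fixture is overlap-free by
construction. Defaults: [P] = 1000 μM (placing β_D = 0.048 in the fittable
regime), ligand stock at 5× molar excess (α_max = 5), 1 protein-only spectrum
plus 10 injections.

## Precision at these titration conditions

The displacement schedule with α_max = 5 moves from α = 0 to α ≈ 0.9 in one
injection, so the binding transition — the only region carrying information
about a small β_D — is sampled by essentially one point per residue, and the
three-parameter fit's covariance puts the standard error of K_D near 14% at
the default noise. Monte-Carlo over 100 seeds (analysis/05_recovery_study.py)
gives a near-unbiased estimator with median |relative error| ≈ 11% and 95% CI
coverage ≈ 0.88; the mild undercoverage traces to noise shared across
residuals (the step-0 reference position and the observed Δδ_max enter every
point of a residue; I_TSP noise enters every residue of a step), which the
unweighted covariance cannot represent. Sampling several steps inside
0 < α < 1 — a smaller injection volume or lower ligand excess — is the lever
that would tighten K_D; it is an experimental-design choice, not an estimator
option, so the package reports honest intervals instead.

## Numerical and policy choices

- σ computed with denominator n (about zero); cutoff strictly `>` σ_c.
- Ambiguous nearest-neighbour links (ties < 1e−6 ppm) flag the trajectory
  and drop it rather than guessing.
- PDB B-factors are written by fixed-column text substitution so the output
  is byte-identical to the input outside the temperature-factor field;
  Δδ_max is scaled ×100 (two decimals survive the %6.2f field), clamped to
  [0, 999.99], sentinel −1.00 for residues missing from the table; when a
  side-chain and backbone entry share a residue number the maximum is mapped
  (configurable).
- Patches require ≥ 2 consecutive significant residues (gap ≤ `max_gap`,
  default 1); isolated significant residues are reported as singletons, and
  side-chain signals are listed separately but attributed to their residue
  number.
- The Sparky dialect parses the assignment as everything left of the trailing
  2–3 numeric columns, so labels containing spaces round-trip; a label that
  is itself a bare number is indistinguishable from a data column and is not
  supported in that dialect (use CSV).
- Problem sizes in the test suite and drivers (11 steps, 59 residues, 50–100
  Monte-Carlo seeds) match the fixture's design; a single fit takes tens of
  milliseconds, the full recovery study a few seconds.
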