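# csptitr — chemical-shift-perturbation analysis of automated NMR titrations

`csptitr` quantifies protein–ligand binding from a series of ¹H–¹⁵N HSQC
spectra acquired at increasing ligand-to-protein ratio, the way an automated
microfluidic titration produces them: one assigned peak list per step plus the
1D intensity of a TSP internal standard that reports the mixing ratio of the
protein-only and protein+ligand stock solutions. It is aimed at structural
biologists who already have assigned peak lists and want the dissociation
constant, the set of significantly perturbed residues, and the binding-site
patches without manual curve fitting.

## Model

Under two-state fast exchange every amide resonance sits at the
population-weighted average of its free and bound positions, so the
isotope-weighted chemical shift perturbation

&nbsp;&nbsp;&nbsp;&nbsp;Δδ = √( Δδ_H² + (0.14·Δδ_N)² )

grows with the bound fraction. With the normalized ligand concentration
α = [L]/[P] and normalized dissociation constant β_D = K_D/[P], mass action
gives the bound fraction

&nbsp;&nbsp;&nbsp;&nbsp;f(α, β_D) = ( (α + 1 + β_D) − √((α + 1 + β_D)² − 4α) ) / 2 ,

and the fractional shift Δδ/Δδ_max of every significant residue equals f.
α itself is not pipetted but read off the internal standard,
α = slope·I_TSP + intercept. The global fit minimizes

&nbsp;&nbsp;&nbsp;&nbsp;Σ_{i,k} [ Δδ_ik/Δδ_max,i − f(α_k, β_D)/f(α_K, β_D) ]²

over (β_D, slope, intercept) by Levenberg–Marquardt, where K is the saturated
step; dividing the model by its own saturated value mirrors the normalization
of the data by the observed Δδ_max, which keeps the estimator unbiased even
when the last titration point is not fully saturated. Significant residues
are selected by the corrected standard deviation σ_c of all Δδ_max values
(iterative 3σ exclusion about zero), and consecutive significant residues are
grouped into binding-site patches.

A synthetic-data module generates titrations with exactly this structure:
displacement mixing of a 10 μL chip circuit by ~2 μL injections, an
11-experiment schedule, straight-line peak trajectories, and a TSP intensity
affine in the mixing fraction — including a packaged 59-amide SH3-domain
mimic whose ground truth (K_D = 48 μM at [P] = 1000 μM, 12 perturbed residues
in patches 96–100, 117–120, 135–137) is fully recorded.

## Worked example

The numbered drivers under `analysis/` run the whole study on the packaged
mimic (each writes its table under `results/`):

```
$ python analysis/01_simulate_titration.py
ground truth: K_D = 48.0 uM, beta_D = 0.048, alpha_max = 5.0
alpha per step: [0.0, 0.908, 1.829, 2.441, 3.078, 3.478, 3.801, 4.043, 4.222, 4.373, 4.523]

$ python analysis/02_build_csp_table.py
sigma_c = 0.1208 ppm (1 iterations, 0 excluded)
12 significant amides: ['Arg96', 'Arg99', 'Asn136', ...]

$ python analysis/03_fit_binding.py
K_D = 39.1 uM, 95% CI [29.4, 48.8] uM (truth 48.0 uM, inside)

$ python analysis/04_map_binding_site.py
3 binding-site patches: 96-100, 117-120, 135-137
```

σ_c = 0.121 ppm separates the 12 truly perturbed amides (Δδ_max ≈ 0.24–0.30
ppm) from the 47 unperturbed ones (Δδ_max at the ~0.005 ppm noise level); the
fitted K_D of this noisy realization is 39 μM with a 95% confidence interval
containing the generating 48 μM; and the significant residues group into
exactly the three ground-truth patches. `analysis/05_recovery_study.py`
repeats the fit over 100 seeds (median |relative K_D error| ≈ 11%, CI
coverage ≈ 0.88 at these titration conditions — see `docs/methods.md` for why
the schedule limits the attainable precision).

The same stages are available as a command-line tool
(`csptitr simulate / analyze / fit / map / run`) and as library functions
(`make_fixture_hfyn`, `build_csp_table`, `global_fit`, `find_patches`,
`write_structure_map`).

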