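# Methods

## Scope and modelling stance

`cometsim` simulates transient-transfection experiments in which synthetic
zinc-finger transcription factors (ZF-TFs), split-intein fusions,
chemically induced dimerizers, degrons and ligand-gated sensors are
combined into genetic programs and read out by flow cytometry ~42 h after
transfection. The model is deliberately concise: it represents proteins at
domain granularity, treats binding, splicing, activation and inhibition
with compact mass-action formalisms, and omits effects (resource burden,
chromatin context, per-protein stability differences beyond two explicit
hooks) whose inclusion would add parameters that endpoint dose-response
data cannot identify.

## The promoter transfer function

All DNA-binding species at a promoter — activators (AD + ZF in one chain
or one ligand-assembled complex), competitive inhibitors (ZF without AD)
and mixed inhibitors (DsRed/DsDed-ZF) — compete for binding sites with
independent-site statistics. The statistical weight of species *j* is
`w_j = beta_j * C_j / K(zf)`, and its fractional occupancy of a site pool
is `w_j / (1 + sum w)`. `beta` (`inhibitor_affinity_fold`, default 10) is
an affinity advantage of AD-free binders: proteins without bulky
transactivation machinery engage their sites more avidly, which is what
makes ZF inhibitors potent at doses comparable to their cognate activator
and is load-bearing for two observed behaviors (see *Ultrasensitivity
motifs*).

Transcription initiation, not binding, is cooperative. A single-pool
promoter transcribes at

    rate = b_p + m1 * (S * (1 - theta_D))^gamma_eff * theta_A
    gamma_eff = 1 + (gamma - 1) * (1 - theta_D)

where `S` is the site count, `theta_A` the summed activator occupancy and
`theta_D` the mixed-inhibitor occupancy *of the activator+mixed ensemble*
(plain competitive binders are excluded from `theta_D`'s denominator so
that adding a competitive inhibitor can never increase the rate by
relieving the cooperativity disruption). Mixed inhibitors thus act twice:
they occupy sites, and the sites they occupy are subtracted from the
cooperative ensemble while the effective exponent relaxes toward 1. The
rate is linear in `theta_A`, so an isolated activator's dose response is
exactly hyperbolic (Hill n = 1) at any `gamma` — the structural reason the
base case is not ultrasensitive — while maximal induction scales as
`S^gamma`, reproducing the strong inducibility of compact multisite
promoters.

Dual-specificity promoters: the overlapping layout (ZF1/2x6-C) is a single
six-site pool shared by both ZF classes; the alternating layout
((ZF2/ZF6)x3) is two disjoint three-site pools whose contributions combine
through a shared ensemble,

    rate = b_p + m1 * [ S1e^g*thA1 + S2e^g*thA2
                        + ((S1e+S2e)^g - S1e^g - S2e^g) * thA1 * thA2 ]

linear (Hill-1) in each activator separately but synergistic in the pair —
the basis of the hybrid-promoter AND topology. Constitutive promoters
(CMV, EF1a) carry fixed TF-independent rates from the part registry.

## Expression, splicing, dimerization, sensors

Per transcription unit: transcription at `k_tx * dose_copies * rate`,
first-order mRNA turnover (`delta_m`), translation (`k_tl`), first-order
protein turnover (`delta_p`, multiplied by `rho_pest` for PEST-tagged
proteins and by an optional per-protein `stability_multiplier`).

Trans-splicing is a single irreversible second-order step (`k_spl`): the
product ligates the intN donor's N-extein to the intC donor's C-extein;
the remaining exteins stay joined through the excised intein pair, which
is modelled as one stable species whose domains keep their functions (the
"AD-ZF-intC/intN" species is a bona fide activator). Non-intein domain
content is conserved exactly across every splice reaction. Capture/collapse
intermediates are not modelled — the chosen intein splices fast, and
endpoint data cannot identify the extra rates. Species closure is reached
by fixed-point iteration over splice/dimer products with a hard cap (64)
against combinatorial explosion.

Dimerization is reversible mass action (`k_on`, `k_off`) and strictly
ligand-gated; ligands are binary environmental conditions (the experiments
use fixed saturating doses — 100 nM rapamycin/rapalog, 100 µM abscisic
acid), not dynamic species. Ligand-gated sensors (intracellular
dimerizer-TFs and membrane receptors that release a TF by proteolysis) are
abstracted to two numbers: a zeroth-order release rate with ligand and a
leak fraction without. Receptor chain trafficking and protease kinetics
are out of scope.

## Cell-population model

Each simulated cell draws one uptake factor `u ~ exp(sigma * N(0,1))`
(log-normal, median 1, default `sigma = 0.5`) that multiplies every
plasmid dose — calcium-phosphate transfection delivers the plasmid mix
together, so co-uptake is fully correlated. Readout is the mean reporter
concentration over cells passing the uptake gate (default: no gating) at
`t_end = 42 h`, integrated by LSODA from an all-zero initial state with
`rtol = 1e-6`; a steady-state mode integrates far past all relaxation
times instead. The population mean is an endpoint average, not a
steady-state quantity: default dose responses therefore convolve the
transfer function with expression kinetics, exactly as the experimental
protocol does.

What the generator does *not* emulate: intrinsic (stochastic-kinetic)
noise, cell growth and division, autofluorescence spectra, instrument
compensation. Synthetic "observed" tables add multiplicative log-normal
replicate noise (default CV 0.1, three biological replicates) and an
optional additive background floor on top of the simulated population
means; passing tests on such data demonstrates self-consistency of the
pipeline, not predictive accuracy on a real cell line.

## Parameter conventions and defaults

Concentrations are arbitrary units; doses are ng of plasmid per well
(internally converted to gene copies at `2e8` copies/ng, a ~4 kb plasmid)
or gene copies directly. Defaults (shipped in `data/params.yaml`, all
overridable):

| parameter | default | meaning |
|---|---|---|
| `b_p` | 0.1 | promoter background (rate units/copy) |
| `m1` | 1.0 | amplitude per occupied-site-ensemble unit |
| `gamma` | 2.5 | initiation-cooperativity exponent |
| `K` | 2e4 | ZF binding constant (conc. units) |
| `inhibitor_affinity_fold` | 10 | site-weight advantage of AD-free binders |
| `k_tx` | 5e-9 | mRNA h⁻¹ copy⁻¹ rate-unit⁻¹ |
| `k_tl` | 1.0 | protein h⁻¹ mRNA⁻¹ |
| `delta_m` | 0.2 h⁻¹ | mRNA turnover (t½ ≈ 3.5 h) |
| `delta_p` | 0.05 h⁻¹ | protein turnover (t½ ≈ 14 h) |
| `rho_pest` | 5 | degron multiplier on `delta_p` |
| `k_spl` | 1e-4 | splicing association (conc⁻¹ h⁻¹) |
| `k_on`, `k_off` | 1e-3, 1.0 | dimerization (K_dim = 1e3) |
| `uptake_sigma` | 0.5 | log-SD of the per-cell uptake factor |

Turnover rates and the degron multiplier are standard mammalian-expression
magnitudes. The remaining scale parameters were calibrated once, jointly,
so that the shipped circuit library reproduces the quantitative behaviors
the system is known to show: direct ZFa activation fits Hill n ≈ 1 with
EC50 of a few ng, inhibitor-thresholded activation n ≈ 1.8, the
double-inversion cascade n ≈ 2.8, dimerizer-reconstituted activation
n ≈ 3.3 (with exactly this motif ordering), and all registered digital
gates reach ON/OFF corner fidelity ≥ 10 at their default doses. Under the
shipped defaults the simulated panel gives n = 0.93 / 1.63 / 2.41 / 3.40
for base / thresholded / cascade / reconstitution. The library also sets
`stability_multiplier = 4` on intC-ZF inhibitor fragments (appending the
intC domain destabilizes the inhibitory ZF), which is why their pre-splice
inhibition is a deliberately modest effect in the gate designs.

## Ultrasensitivity motifs (why the pieces matter)

* *Thresholding* (constitutive DsDed-ZF + dose-swept ZFa): at low
  activator dose the mixed inhibitor dominates the ensemble, suppressing
  both occupancy and cooperativity; rising activator simultaneously gains
  sites and restores `gamma_eff` — the product of the two releases is
  steeper than hyperbolic (n ≈ 1.6–1.8). This requires `theta_D` to be
  occupancy-coupled (competed away by the activator).
* *Double-inversion cascade*: the reconstituted upstream inhibitor forms
  bimolecularly (quadratic at low input) and acts through two inversions;
  with the PEST-tagged downstream inhibitor the composite response fits
  n ≈ 2.4–2.8.
* *Reconstitution* (RaZFa): with the brake (free FKBP-ZF) binding sites
  `beta`-fold more avidly than the assembled activator, converting brake
  into accelerator collapses the inhibitory denominator while the
  activating numerator grows — most of the response is concentrated near
  complete conversion (n ≈ 3.3). With `beta = 1` the conversion merely
  swaps occupied sites and the response stays hyperbolic; this motif is
  the strongest evidence for the affinity asymmetry.

## Numerical choices

Hill fits use bounded least squares with a fixed deterministic
initialization (y0 = min, a = range, EC50 = log-interpolated half-range
dose, n = 1; n bounded to [0.1, 10]); a constant response returns a
flagged degenerate fit. Q² is computed on per-set max-scaled values by
default (the heatmap convention); a raw mode exists because the scaling
convention for published goodness-of-prediction values is not always
stated. Parameter estimation optimizes log10-parameters with seeded
multi-start bounded least squares; the covariance Jacobian uses a
finite-difference step of 1e-3 in log10 space, large enough to clear the
ODE solver's discretization jitter (with the default step the reported
confidence intervals are sporadically garbage). Intervals are reported as
±1.96 SE in log10 space; their per-parameter frequentist coverage on
synthetic 3-replicate, 10%-CV data is ~92–94%. Parameters whose loss
surface is flat (absent stderr, or start-independent loss with
start-dependent estimates) are flagged unidentifiable rather than
silently returned. Bandpass thresholds are half-peak crossings under
log-dose linear interpolation; upper-edge sharpness is the maximum
downward log-log slope above the peak.

## Known limitations

* Kinetic and promoter scale parameters are calibrated to reproduce the
  reported summary characteristics of these parts (Hill coefficients,
  working gates), not fitted to replicate-level calibrated-cytometry
  tables; absolute reporter units are arbitrary.
* The exclusion-plus-`gamma`-relaxation form of mixed inhibition and the
  `beta` affinity asymmetry are the simplest forms found that satisfy the
  transfer-function contracts and the observed motif behaviors; they are
  defaults, not measured biophysics.
* A two-layer ZFa relay retains ≥ 50% of the one-layer fold induction as
  a steady-state property in the sub-saturating input regime (~63% at the
  tested design point); at the 42 h endpoint the two chained ~20 h protein
  lags cut retention to ~46%. Deep cascades read out at endpoint will look
  weaker than their steady-state structure.
* Ligands are binary and constant from t = 0; medium-change timing and
  ligand pharmacokinetics are idealized away.
* No resource competition, cell burden, growth dilution or intrinsic
  noise; population variability is extrinsic (uptake) only.
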