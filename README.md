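# cometsim

Model-guided design and simulation of mammalian genetic circuits built from
synthetic zinc-finger transcription factors (the COMET toolkit), split
inteins, chemically induced dimerizers, degrons and ligand-gated sensors.

`cometsim` is for synthetic biologists who want to propose a circuit
topology — a digital logic gate, an ultrasensitive switch, a bandpass
concentration filter, a sensor-driven AND — and see how it behaves across
component doses *before* cloning anything. Circuits are written as sets of
transcription units (promoter + fusion protein + plasmid dose); the package
compiles them into mass-action reaction networks (closing the species set
under trans-splicing and ligand-induced dimerization), integrates
heterogeneous cell populations to the flow-cytometry readout time point,
and scores the results with the field's standard metrics.

## The model in brief

**Promoter transfer function.** Every DNA-binding species competes for the
promoter's binding sites with noncooperative, independent-site statistics,
so the occupancy of species *j* is

```
theta_j = w_j / (1 + sum_k w_k),    w_j = beta_j * C_j / K
```

where `beta_j` is an affinity advantage carried by AD-free binders
(inhibitors). Cooperativity lives in transcription initiation: the maximal
rate scales supralinearly with the activator-occupied compact site ensemble,

```
rate = b_p + m_1 * (S * (1 - theta_D))^gamma_eff * theta_A
gamma_eff = 1 + (gamma - 1) * (1 - theta_D)
```

with `theta_D` the occupancy of mixed DsRed/DsDed-ZF inhibitors, which both
shrink and de-cooperativize the initiation ensemble. This keeps any single
activator's dose response hyperbolic (Hill coefficient n = 1) while
compact multisite promoters remain strongly inducible — and it reproduces
the three ultrasensitivity motifs: inhibitor thresholding, double-inversion
cascades, and dimerizer-reconstituted activators.

**Expression and posttranslational layer.** Per transcription unit:
transcription (dose-scaled transfer function), mRNA turnover, translation,
protein turnover (PEST degron multiplies the degradation rate). Every
complementary intN/intC pair splices irreversibly (second-order), ligating
the flanking exteins into a new product species and leaving the remaining
domains joined through the excised intein complex; every ligand-bridged
FRB/FKBP or PYL1/ABI1 pair associates reversibly.

**Cell population.** Each cell draws one log-normal uptake factor (median
1) applied to all co-delivered plasmids; readout is the gated population
mean of the reporter at 42 h (the experimental 40–48 h window).

**Metrics.** Ultrasensitivity via the modified Hill equation
`y = y0 + a*x^n / ((1/b)^n + x^n)` (EC50 = 1/b, ultrasensitive iff n > 1);
goodness of prediction `Q² = 1 − Σ(obs−sim)²/Σ(obs−mean(obs))²` on
max-scaled sets; gate corner fidelity (min ON / max OFF, with the ∞
convention when the denominator is ≤ 0); bandpass peak/threshold/sharpness
metrics; gene/connection/protein complexity counts.

## Worked example

Score the double-inversion cascade AND gate, in which the upstream
inhibitor DsDed-ZF10 is split into DsDed-intN and intC-ZF10 so that only
joint delivery silences the PEST-tagged downstream inhibitor and releases
the reporter:

```python
import numpy as np
import cometsim as cs

entry = cs.get_entry("CASCADE_AND_fig1J")
pop = cs.PopulationSettings(n_cells=64, uptake_sigma=0.5, seed=1)

maps = cs.landscape(entry.circuit, "DsDed-intN", "intC-ZF10",
                    [0, 30], [0, 30], pop=pop)
score = cs.gate_fidelity(maps["mKate2"], "0001")
print("corners:", {k: round(v, 1) for k, v in maps["mKate2"].corners().items()})
print("fidelity: %.1f" % score.fidelity)

dr = cs.dose_response(entry.circuit, entry.hill_input,
                      np.asarray(entry.hill_grid), pop=pop)
fit = cs.fit_hill(dr.doses, dr.outputs)
print("hill n=%.2f ec50=%.2f ng ultra=%s" % (fit.n, fit.ec50, fit.ultrasensitive))
```

prints

```
corners: {(0, 0): 1002.6, (0, 1): 4015.2, (1, 0): 1002.6, (1, 1): 102398.3}
fidelity: 25.5
hill n=2.42 ec50=9.12 ng ultra=True
```

Reporter output (arbitrary MEPTR-like units) is ~100× background only when
both splice fragments are delivered (corner fidelity 25.5, i.e. a clean
AND), and the activation along the joint dose axis is strongly
ultrasensitive (n = 2.4) — unlike direct ZFa activation, which fits n ≈ 1.

The same API drives the rest of the registered topology library
(`cometsim library list` shows all 22 entries: the eight single-output
gates, five two-reporter MIMO gates, the analog ultrasensitivity and
bandpass circuits, and four synonymous sensor-AND topologies), and the CLI
mirrors it: `simulate`, `fit-hill`, `qsquared`, `fit-params`, `synth`,
`ablate`, `library`.

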