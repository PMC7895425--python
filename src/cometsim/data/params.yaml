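# Default kinetic and promoter parameters (arbitrary-unit scheme documented
# in docs/methods.md).  Every value can be overridden from a user config.
version: 1

promoter_defaults:
  background_rate: 0.1      # b_p, rate units per gene copy
  unit_amplitude: 1.0       # m_1, rate units per occupied-site equivalent
  cooperativity: 2.5        # gamma, amplitude exponent over the site ensemble
  K: 2.0e4                  # ZF binding constant, concentration units
  inhibitor_affinity_fold: 10.0   # site-weight advantage of AD-free binders

# Per-promoter / per-ZF overrides, keyed by promoter name.
promoter_overrides: {}

kinetics:
  k_tx: 5.0e-9        # mRNA h^-1 per gene copy per promoter rate unit
  k_tl: 1.0           # protein h^-1 per mRNA
  delta_m: 0.2        # mRNA degradation, h^-1 (t1/2 ~ 3.5 h)
  delta_p: 0.05       # protein degradation, h^-1 (t1/2 ~ 14 h)
  rho_pest: 5.0       # degron multiplier on delta_p
  k_spl: 1.0e-4       # splicing association, conc^-1 h^-1 (irreversible)
  k_on: 1.0e-3        # dimerizer association, conc^-1 h^-1
  k_off: 1.0          # dimerizer dissociation, h^-1  (K_dim = k_off/k_on)
  sensor_release_rate: 4.0e3   # released TF, conc h^-1 at saturating ligand

dose:
  copies_per_ng: 2.0e8   # ~4 kb plasmid; canonical internal unit is gene copies
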