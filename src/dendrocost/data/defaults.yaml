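# Bundled model defaults: baseline rates, the 3x3x...x3 sampling levels of the
# seven-dimensional synthetic species grid, and named per-species presets.
#
# Values marked "provisional" are not printed in the main-text sources this
# package reproduces; they were chosen once from the experimental literature
# ranges discussed in docs/methods.md and are exposed here as configuration,
# not code.

baseline:
  tau: 0.01             # proteins per mRNA per s (dendritic translation rate)
  u_p: 0.03             # spine entry rate, 1/s (provisional)
  nu_p: 3.0e-4          # spine exit rate, 1/s (provisional; ~1 h residence)
  D_m0: 0.001           # resting-state mRNA diffusion constant, um^2/s (provisional)
  v: 1.0                # instantaneous run velocity, um/s
  beta: 0.5             # run-termination rate, 1/s (mean run ~2 s) (provisional)
  mrnas_per_granule: 1

geometry:
  rho: 1.0              # spines per um
  phi: 0.95             # required spine filling ratio
  grid_dx: 1.0          # um

# Three levels (low / medium / high) per sampled dimension; full factorial
# product = 3^7 = 2187 synthetic species. All provisional: chosen to span the
# experimentally reported ranges (see docs/methods.md).
grid_levels:
  mrna_halflife_h: [2.0, 8.0, 24.0]
  noncoding_ratio: [0.25, 1.0, 2.5]
  protein_halflife_d: [2.0, 8.0, 32.0]
  protein_aa: [150, 450, 1350]
  eta_p: [100, 2000, 32000]
  D_p: [0.002, 0.02, 0.2]
  alpha: [0.0125, 0.05, 0.25]

scenario:
  r_soma_grid: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
  lengths: [250.0, 500.0, 750.0, 1000.0]

presets:
  camkii:
    # Printed parameters: 478 aa, ~4900 nt transcript, 32336 copies/spine,
    # protein half-life ~8 d, mRNA half-life ~20 h, translation 0.01/s.
    N_aa: 478
    N_nt: 4900
    eta_p: 32336
    halflife_p_d: 8.0
    halflife_m_h: 20.0
    tau: 0.01
    D_p: 0.02            # provisional (large holoenzyme, cytosolic)
    alpha: 0.05          # provisional (motor-associated mRNA)
  shank3:
    # Provisional throughout: scaffold protein, somatically translated in the
    # photoactivation paradigm. Spine exchange kinetics are species-specific
    # (sub-hour fast-pool residence reported for Shank3), so the preset
    # overrides the baseline u_p/nu_p.
    N_aa: 1731
    N_nt: 7500
    eta_p: 300
    halflife_p_d: 4.0
    halflife_m_h: 10.0
    tau: 0.01
    D_p: 0.1
    alpha: 0.05
    u_p: 0.03
    nu_p: 1.0e-3

photoactivation:
  L: 250.0
  spine_positions: [25.0, 50.0, 75.0, 105.0]
  t_end_h: 8.0
  dt: 10.0
  saturation_level: 0.95
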