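# Demo cohort: two swimming phenotypes with distinct kernels and speeds.
# "wobbler"-like cells: weak friction, fast oscillation, high mean-squared
# velocity; "synchro"-like cells: strong friction, slow oscillation, low B.
populations:
  - name: wobbler
    n_cells: 5
    a: 5        # δ-peak amplitude (1/s)
    b: 2000     # oscillation amplitude (1/s²)
    tau: 0.5    # kernel decay time (s)
    omega: 120  # kernel frequency (1/s)
    B: 4000     # mean-squared velocity (μm²/s²)
    spread: 0.08
    sigma_loc: 0.02   # localization noise (μm), ~pixel scale
    n_steps: 30000
    dt: 0.002
    seed: 11
  - name: synchro
    n_cells: 5
    a: 20
    b: 8000
    tau: 0.3
    omega: 60
    B: 500
    spread: 0.08
    sigma_loc: 0.02
    n_steps: 30000
    dt: 0.002
    seed: 22
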