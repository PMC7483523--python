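# pscfcs

Subpopulation-selective fluorescence correlation spectroscopy for
single-molecule chaperone–client binding studies.

Solution mixtures probed at single-molecule concentrations usually hold
several coexisting species at once — a client protein free and bound, a
chaperone as monomer and trimer. Conventional FCS measures one average
diffusion time over all of them. This package implements the
*portion-selective* strategy: classify each fluorescence burst by its
apparent smFRET efficiency E = I_A/(I_D + I_A), keep only the trace
segments belonging to one subpopulation, replace everything else with
synthetic Poisson background at the measured rates, and autocorrelate
what remains. Because the burst selection itself biases the apparent
diffusion time, the peak threshold x is swept and the empirical law

    τ_app(x) = τ + a·x²

is extrapolated to x = 0, yielding an unbiased diffusion time τ for that
subpopulation alone. Diffusion times convert to molecular weights
through the Stokes–Einstein relation D = k_B T / 6πηR with τ = ω_xy²/4D;
under the equal-density sphere assumption M₁/M₂ = (τ₁/τ₂)³, so the
chaperone:client stoichiometry follows from the bound and apo client
diffusion times:

    r = ((τ_bound/τ_apo)³ − 1) · M_client / M_chaperone.

On top of the measurement pipeline sit the mass-action models of the
Skp–OmpC system: chaperone self-trimerization 3S ⇌ S₃ with
K = [S]³/[S₃] (half-trimerization C_1/2 = √(4K/3)), cooperative client
binding described by a Hill isotherm p = c^n/(K_D^n + c^n), and binding
of a second trimer, client·S₃ + S₃ ⇌ client·(S₃)₂ with constant K_D′,
coupled to the trimerization equilibrium through the free-trimer
concentration. A Brownian-dynamics photon-trace simulator provides
ground-truth data for every step.

Intended users: single-molecule biophysicists analysing two-channel
confocal photon traces (smFRET + FCS) and anyone fitting coupled
oligomerization/binding titrations.

## Layout

| module | contents |
|---|---|
| `pscfcs.trace` | two-channel binned traces, rebinning, burst detection, background estimation, Poisson replacement |
| `pscfcs.smfret` | burst efficiencies, histograms, Gaussian decomposition, window selection |
| `pscfcs.fcs` | multi-tau autocorrelator, 2D/2D1R model fits, threshold sweep and extrapolation |
| `pscfcs.hydro` | Stokes–Einstein conversions, cubic mass law, stoichiometry, diffusion-limited rates |
| `pscfcs.equilibria` | trimerization / Hill / second-trimer models, titration fitting, free energies |
| `pscfcs.simulate` | Brownian confocal photon-trace simulator, synthetic titration generator |
| `pscfcs.workflow`, `pscfcs.cli` | end-to-end runs and the `pscfcs` command |

## Worked example

`examples/01_simulate_and_select.py` simulates the six-molecule
validation scenario — four molecules emitting at FRET efficiency 0.11
and two at 0.33 diffusing through a confocal focus — and isolates the
minority species:

```
simulated 20 s, 20,833,333 bins of 0.96 us
431 bursts above 30 counts/ms; background 1.92/0.58 counts/ms per channel
histogram peak at E = 0.11 (sigma 0.06)
histogram peak at E = 0.33 (sigma 0.08)
window [0.3, 0.5]: 86 bursts, 100% from the E=0.33 molecules
```

The two-Gaussian decomposition recovers both branching ratios, and the
efficiency window isolates the two E = 0.33 molecules essentially
perfectly. `examples/02_unbiased_diffusion_time.py` then runs the
threshold sweep on a single 150 µs species:

```
conventional FCS: tau_app = 149.1 us (G0 = 9.13)
  threshold    3 counts/ms -> tau_app = 151.4 us
  ...
  threshold   11 counts/ms -> tau_app = 150.3 us
extrapolated unbiased tau = 147.7 us (true transit time 150 us)
```

The extrapolated diffusion time lands within ~2% of the ground truth.
`examples/03_stoichiometry_from_tau.py` converts published bound/apo
diffusion times into a stoichiometric ratio (r ≈ 2.6 chaperone monomers
per client) and `examples/04_equilibrium_fits.py` refits the three
coupled equilibria from noisy synthetic titrations, composing them into
the femtomolar effective trimer–client constant (≈ −20 kcal/mol).

A thin CLI mirrors the library:

```sh
pscfcs simulate --preset fig1 --seed 7 --duration 20 --out sim.h5
pscfcs run --trace sim.h5 --e-min 0.3 --e-max 0.5 --thresholds 3,5,7,9,11 --seed 1
pscfcs fit-hill --data titration.tsv
```

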