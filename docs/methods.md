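# Methods

## The measurement model

A confocal microscope collects photons from fluorescently labelled
molecules diffusing through a diffraction-limited focus. Photons are
detected in two spectral channels (donor, acceptor) and binned on a fine
time grid (0.96 µs by default); burst analysis and smFRET histogramming
work on a 1 ms rebinning of the same data. The apparent FRET efficiency
of a burst, E_app = I_A/(I_D + I_A), classifies it into a molecular
subpopulation (conformation or binding state).

Subpopulation-selective FCS keeps the fine-trace segments under the
bursts of a chosen efficiency window and replaces every other bin with a
Poisson draw at the measured per-channel background rates, so the
synthetic trace is statistically continuous with the retained signal.
Donor and acceptor are summed before autocorrelation, which cancels the
donor–acceptor anti-correlation produced by acceptor-state dynamics.
The autocorrelation G(t) = ⟨I(0)I(t)⟩/⟨I⟩² is fitted with the
two-dimensional diffusion model

    G(t) = 1 + G₀ / (1 + t/τ_app),        t ∈ (10 µs, 1 s),

optionally times (1 + A·exp(−t/t_R)) when fast photophysics is present
(2D1R). G₀ is the inverse mean occupancy of the focus.

Burst selection is biased: raising the peak threshold x preferentially
keeps long, bright (centre-crossing) transits, so τ_app grows with x.
The sweep fits τ_app = τ + a·x² and reports the intercept τ as the
unbiased diffusion time. The quadratic law is empirical; no mechanistic
claim is made for it, and it is used only near the onset of the bias
(see *Threshold grid* below).

## Estimators and numerical choices

**Correlator.** Multi-tau cascade, 16 points per stage, ×2 pairwise
rebinning per stage. Within each stage the estimator is the direct sum
Σᵢ I(i)I(i+k) / (N−k) normalized by the squared mean of that stage's
(rebinned) trace; the first stage therefore equals the brute-force
O(N²) estimator exactly, and coarser stages equal brute force on the
correspondingly rebinned trace. Tests assert both equivalences at
1e−10.

**Fits.** All nonlinear fits are unweighted least squares (lmfit
Levenberg–Marquardt). Dissociation constants are fitted in log₁₀ space
for scale invariance, with standard errors mapped back by the delta
method. The threshold extrapolation is linear least squares in the
basis (1, x²). Noiseless round-trips recover parameters to 1e−6
relative. Flat titrations (no signal) raise an unbounded-estimate error
instead of returning a boundary value.

**Burst definition.** A burst is a maximal run of consecutive 1-ms bins
whose summed donor+acceptor count is at or above the threshold. E_app
uses raw sums for detection; for histogramming and window selection the
expected background (rate × burst length) is subtracted per channel, so
a donor-only dye centres at E ≈ 0 and windows such as [−0.1, 0.1] are
meaningful. Efficiency windows are closed intervals. Selection windows
found on the 1-ms binning are mapped back to the fine binning by time
before Poisson replacement; adjacent windows merge.

**Mass-action solvers.** The trimerization balance [S] + 3[S]³/K = total
is strictly increasing in [S] and solved by bracketed root-finding
(Brent, [0, total], relative tolerance 1e−15); conservation holds to
1e−10 relative. C_1/2 = √(4K/3) in closed form. The second-trimer
fraction computes the free trimer concentration from this equilibrium
at each total — it does not approximate [S₃] ≈ total/3 — so the model
remains valid through the trimerization transition. Free energies use
ΔG = RT ln(K_D/1 M) at 296.15 K.

**Error propagation.** The cubic mass law propagates diffusion-time
uncertainty to first order, var(M)/M² = 9·(var(τ₁)/τ₁² + var(τ₂)/τ₂²);
a Monte-Carlo test keeps it honest to ≤5% at the percent-level noise
where the linearization applies.

## The simulator

Molecules perform free Brownian motion (Gaussian steps, variance 2DΔt
per axis) in a periodic box containing a Gaussian detection volume
W(r) = exp(−2(x²+y²)/ω_xy² − 2z²/ω_z²). Expected photons per bin are
brightness × W; the donor/acceptor split at branching probability
e_true is drawn as two independent Poisson streams (exactly equivalent
to a binomial split of a Poisson total), plus uniform Poisson
background per channel. Every run is bit-reproducible under its seed.
The simulator logs each molecule's expected photon count per 1-ms bin,
from which ground-truth transit windows and the dominant molecule under
any burst are derived — this is what lets tests attribute selected
bursts to species.

Defaults and why:

- **ω_xy = 0.25 µm**, giving τ = 150 µs at D ≈ 1.0e−10 m²/s — a free
  dye / small protein at room temperature.
- **ω_z = 2.5 µm (κ = 10), box 6 × 6 × 10 µm.** Two geometry artefacts
  bias a 2D-model fit of simulated 3D diffusion: the axial decay of the
  detection volume (−7% in τ at κ = 5, −2% at κ = 10, computed on
  noiseless model curves) and tail truncation by periodic recurrence in
  the lateral box (−6% at a 3 µm box, −3% at 6 µm, verified against an
  exact Fourier-mode computation of the periodic-box correlation). The
  chosen geometry keeps the combined systematic near −3%, small against
  the few-percent statistical scatter of minute-long traces. The axial
  box edge is ≥4 ω_z so the detection weight at the wrap plane is
  negligible.
- **Dynamics stride 4**: positions update every 3.8 µs (r.m.s. step
  ~30 nm, an eighth of the waist), below the 10 µs fit-window edge;
  stride 2 gives the same τ within seed noise at twice the cost.
- **Brightness 0.05 photons/fine bin (~52 kHz peak)** for diffusion
  studies; **0.15 (~156 kHz)** for the two-species histogram scenario,
  where bursts must carry ≳50 photons for the shot-noise width
  √(E(1−E)/N) of the efficiency peaks to stay well below their 0.22
  separation. **Background 2e−4 counts/channel/bin (~0.2 kHz)**, a
  clean-buffer confocal value; background sets the lowest usable peak
  threshold (below ~5σ of the background the selection fills with
  spurious one-bin "bursts" of conditioned noise).
- Periodic re-entry is the boundary policy; molecules are initialized
  uniformly.

What the simulator does *not* emulate: detector afterpulsing and dead
time, spectral crosstalk and direct acceptor excitation (available as
options but off), blinking/bleaching photophysics (a two-state toggle
exists solely to exercise the 2D1R model), triplet kinetics, and
out-of-focus background structure. Passing tests therefore validate the
estimator chain and the selection logic, not robustness to these
instrumental effects on real data.

## Threshold grid

The default sweep (3, 5, 7, 9, 11 counts/ms at ~52 kHz peak brightness)
sits just above the background noise floor, in the regime where the
bias is small and the quadratic law holds. A three-seed pilot on 60-s
single-species traces recovered τ with mean error 4.2% on this grid;
grids pushed deep into the steep-rise regime (up to 15–20 counts/ms)
extrapolated 5–7% low because the flat-then-rise shape is not a single
quadratic over that span. At high thresholds the selection also thins
below ~25 bursts and individual τ_app values destabilize. For
demonstrating the bias itself (monotone growth of τ_app), widely spaced
thresholds in the rising regime (e.g. 20–65 counts/ms at the brighter
two-species conditions) separate the effect from replicate noise.

## Problem sizes

Validation simulations use 20–60 s traces at 0.96 µs bins (2e7–6e7
bins) with 6–24 molecules; titration fits use 8–12 concentrations with
3–6 replicates at the noise levels stated in the test docstrings. These
sizes keep every statistical check several standard errors away from
its tolerance while the whole suite runs in minutes.

## Known limitations

- The 2D diffusion model is adopted as the standard reading of this
  kind of data; its residual −2 to −3% τ bias under the simulated 3D
  geometry is documented above and absorbed by the stated tolerances.
- The quadratic extrapolation is empirical; outside the onset regime it
  is not a good description (see *Threshold grid*).
- E_app is apparent: no γ-factor, crosstalk or direct-excitation
  correction, and no distance conversion.
- Hydrodynamics assumes spherical, equal-density species; shape and
  crowding corrections are out of scope.
- The labelled tracer in the trimerization titration is treated as
  chemically identical to unlabelled monomer (observable
  n(total) = 1 + 2f(total)).
- The titration models are built directly from mass action and
  conservation for the reactions 3S ⇌ S₃, client·S₃ ⇌ client + 3S
  (Hill form) and client·(S₃)₂ ⇌ client·S₃ + S₃, with normalized
  observables fixed to [0, 1]; optional free scale/offset parameters
  exist but are off by default, so any baseline structure in real data
  must be handled explicitly by the caller.
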