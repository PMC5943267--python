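# Methods

## Measurement model

A dual-polarization TCSPC acquisition records, for every detected photon,
its macro-time (arrival since the start of the run, in macro-clock ticks),
its micro-time (delay since the last excitation pulse, in TAC bins) and
which polarization detector fired.  All analyses in this package are
reductions of those three columns:

* **Macro-time statistics** give the count rate and, through the
  cross-correlation of the parallel and perpendicular channels, the number
  fluctuations of molecules in the two-photon observation volume.
  Cross-correlating two physical detectors (rather than autocorrelating
  one) cancels detector afterpulsing, which is uncorrelated between
  detectors.
* **Micro-time statistics** give the fluorescence decay per channel, from
  which lifetime, time-resolved anisotropy and steady-state anisotropy
  follow.

The instrument emulated here runs at an 80 MHz sync rate (12.5 ns period),
with hybrid detectors contributing a few hundred dark counts per second,
and a polarizing beamsplitter whose unequal channel efficiencies are
corrected by a scalar g-factor: wherever the equations use the
perpendicular intensity, the measured counts enter multiplied by g.

### Anisotropy

With dark-subtracted per-channel decays I∥(t), I⊥(t):

    r(t) = (I∥ − g·I⊥) / (I∥ + 2·g·I⊥)
    R    = (ΣI∥ − g·ΣI⊥) / (ΣI∥ + 2·g·ΣI⊥)

R equals the intensity-weighted average of r(t) (an algebraic identity the
suite verifies).  The hindered-rotor model r(t) = r∞ + (r0 − r∞)e^(−t/θ) is
fit by weighted least squares with per-bin Poisson error propagation.  An
optional wrap-around correction multiplies the decaying amplitude by
(1 − e^(−P/τ)) / (1 − e^(−P/τ − P/θ)) — the exact attenuation produced by
photons excited by earlier pulses folding into the observation window of
period P when the intensity decay is a single exponential with lifetime τ.

Two printed-form slips in the source material for this instrument class are
corrected here as the standard definitions: the steady-state denominator is
ΣI∥ **+** 2gΣI⊥ (a minus sign appears in one printed form), and the flicker
exponential decays (e^(−τ/τ_T); the printed positive exponent diverges).

### Lifetime

Tail fits (no IRF deconvolution) of the total decay I(t) = I∥ + 2gI⊥ to one
or two exponentials, starting 0.5 ns after the smoothed decay peak by
default.  For an exponential decay, pulse wrap-around rescales every
component by a constant and therefore does not bias tail-fitted lifetimes.
Weights are Poisson, iterated once with model-based variances scaled by the
measured var(I)/I ratio (the variance of I∥ + 2gI⊥ is p + 4g²q, not I);
the single reweighting iteration removes the classic small-count bias of
observed-count weighting.  Amplitudes are referred back to t = 0 so the
amplitude-weighted ⟨τ⟩ = Σaᵢτᵢ/Σaᵢ uses true decay amplitudes.

### FCS

The correlator is multi-tau: 16 linear lags per octave, bin width doubling
per octave, symmetric (Schätzel) normalization with means taken over the
overlapping window.  The stream is cut into 8 equal segments; the curve is
the segment mean and the per-point standard error the segment scatter.
Fits are weighted by those standard errors after smoothing them on the log
scale (a 5-point running mean): with only 8 segments the raw SE estimates
are noisy and correlated with the point fluctuations, which would otherwise
bias a weighted fit.  Positive parameters are fit in log space; the dark
fraction through a bounded logistic (T ≤ 0.85 — beyond that the flicker
factor degenerates into a re-parameterization of the whole decay); the
flicker fit is multi-started on a deterministic 6-point (T, τ_T) grid
because its χ² surface has a degenerate valley.  Model selection between
the plain and flicker models uses a reduced-χ² ratio threshold calibrated
to the number of fit points, 1 + χ²₂(1−α)/dof with α = 10⁻³, i.e. a
likelihood-ratio-style cut.

The default longest lag is 20 ms: diffusion times in this workflow are
70–600 µs, so the decay is complete well before that, and far-tail points
are the most sensitive to slow drifts (and, for simulated input, to
finite-reservoir artifacts — see below).  `fit_fcs(window_tau_d=k)`
optionally truncates the fit to k·τ_D after a full-range prefit; the
calibration rehearsal uses k = 6.

⟨N⟩ read off the correlation amplitude is corrected for the uncorrelated
dark-count background by (total/(total − background))², and the dark rate
is subtracted from ⟨k⟩ before brightness η = ⟨k⟩/⟨N⟩.

### Calibration and units

τ_D = ω²/8D ties the fitted correlation time of a diffusion standard
(fluorescein, D = 436 µm²/s at room temperature and high pH) to the radial
waist ω; the axial ratio ω/z comes from a global fit of a dilution series
in which only ⟨N⟩ may vary; V = π^{3/2}ω²z/8 converts ⟨N⟩ to molar
concentration.  ω/z is barely identifiable from a single curve — its
influence enters as (ω/z)²·τ/τ_D, of order 10⁻³ over the fitted window at
ω/z ≈ 0.05 — so it is held fixed during sample fits and only floated in the
calibration global fit, where its uncertainty remains large (as it is for
the physical instrument).  Public interfaces use nm, µs, µm²/s, fl and nM;
conversions live in one module.

### Dose-response

Fits operate on log₁₀ of molar concentration.  pCa here means
−log₁₀([Ca²⁺]/M).  The four-parameter model is
y = bottom + (top − bottom)/(1 + 10^((logKd − x)·h)); the biphasic variant
shares bottom/top between two transitions mixed by a fraction parameter.
Multi-start over a fixed log-Kd grid (6 points across the data range, and a
small Kd×gap grid for the biphasic model) makes fits deterministic; Kd
ordering in the biphasic model is enforced by parameterizing the second
transition as the first plus a positive log-spaced gap.

## The photon-stream simulator

The generator stands in for the microscope.  Molecules perform Brownian
motion (diffusion coefficient D) in a periodic box around a 3D-Gaussian
two-photon detection profile W = exp(−4x²/ω² − 4y²/ω² − 4z′²/z²); emission
is an inhomogeneous Poisson process at rate η_peak·W·B(t), with B(t) a
two-state bright/dark telegraph (stationary dark fraction T, relaxation
time τ_T — the standard identification k_off/(k_on+k_off) = T,
1/(k_on+k_off) = τ_T).  Each photon draws its fluorescence delay from the
(multi-)exponential decay, folded into the sync period and quantized to TAC
bins, and reaches the parallel detector with probability (1+2r)/3, the
perpendicular detector with probability (1−r)/(3g) — the remaining (1−r)/3
is the polarization component along the collection axis and is lost, which
reproduces the anisotropy and total-decay relations exactly by
construction.  r is evaluated at the unfolded delay.

**Sampling is exact.**  Rather than stepping time on a grid, candidate
photon times are generated as a homogeneous Poisson process at the peak
rate per molecule; the Brownian position is sampled exactly at those times
(Gaussian increments of variance 2DΔt per axis) and candidates are thinned
by W.  The flicker telegraph is evaluated exactly at the surviving
candidate times through its two-state transition kernel (kept with
probability e^(−Δ/τ_T), else redrawn stationary), which the Markov property
licenses.  There is no time-discretization error at any parameter setting.
The hot loop consumes pre-drawn numpy randoms inside a fused numba pass, so
streams are bit-reproducible per seed.

**Brightness convention.**  η in the configuration is the brightness that
⟨k⟩/⟨N⟩ analysis recovers: because ∫W dV = π^{3/2}ω²z/8 exactly, setting
the internal peak rate to η divided by the mean polarization detection
efficiency makes the detected rate ⟨N⟩·η·(1−T) + 2·dark exactly.  With
flicker, measured brightness is the bright-state value times (1−T), as on
the real instrument.  Lifetime component amplitudes in the configuration
are *decay* amplitudes (what tail fitting reports); photon fractions are
aᵢτᵢ/Σaⱼτⱼ internally.

**Reservoir geometry and its limits.**  The box is anisotropic — lateral
half-size 4ω, axial 1.25z by default — with periodic boundaries, holding
round(⟨N⟩·V_box/V_eff) molecules.  Two artifacts bound the trustworthy lag
range of simulated correlation curves: beyond roughly 7·τ_D (at the default
lateral margin) the closed reservoir equilibrates measurably faster than
free-space diffusion (correlation deficit), and near the lateral recurrence
time L²/4D periodic images add a small excess.  Both scale with the square
of the lateral margin; neither affects micro-time observables (lifetime,
anisotropy), which is why micro-time-only tests may use a smaller, cheaper
reservoir.  Axial truncation at 1.25z loses ~0.04% of ∫W — negligible
against fit precision.

**What the simulator does not emulate**: detector dead time and
afterpulsing, TCSPC pile-up, an instrument response function (photons
appear at their true delays; real data convolve a ~100 ps IRF, which is
why the analysis tail-fits), photobleaching, optical saturation, explicit
dipole rotational dynamics (polarization is assigned from r(t) directly),
and acceptor photon channels (hetero-FRET enters only through the donor's
lifetime components and anisotropy parameters).  Passing recovery tests
therefore demonstrate the correctness of the estimators under the model's
own assumptions, not robustness to those instrument non-idealities.

## Statistical design of the validation suite

FCS precision is set by photons per molecule per volume crossing
(η·τ_D ≈ 0.3 for a Venus-like homogenate), so fluctuation observables from
a 60 s simulated acquisition carry ~20–45% single-run scatter — matching
the published per-well variability once scaled from the instrument's
600 s per well.  Recovery tests therefore average five seeds of 60 s and
test each observable against its truth at 3 standard errors, where the SE
for the micro-time observables includes a photon-noise floor (a 4-dof
sample SD can fall below the provable shot-noise limit).  Flicker-model
selection is validated at the SNR equivalent of the published 200 s
acquisitions by simulating brighter-but-shorter streams (90 s at ~60 kcps;
FCS per-point SNR scales as rate·√duration), with a slow conformational
dark state (τ_T = 300 µs, T = 0.5).  Problem sizes throughout (seconds of
simulated acquisition, ⟨N⟩, replicate counts) are chosen as the smallest
that leave the tested effect statistically unambiguous.

## Known limitations

* ⟨N⟩ estimated from a noisy correlation amplitude is a convex transform
  (γ/Ĝ), so very noisy single runs overestimate ⟨N⟩ slightly (Jensen bias,
  ~σ² relative); averaging replicates, as the plate workflow does, is the
  remedy.
* The ω/z global fit is weakly identified at ω/z ≈ 0.05 and realistic
  noise; its standard error honestly reflects that.
* The biphasic dose-response model shares Hill plateaus between phases; it
  cannot represent transitions with opposite signs.
* Simulated correlation curves are quantitatively trustworthy only within
  the reservoir-artifact-free lag window described above.
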