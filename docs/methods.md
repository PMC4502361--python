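# Methods

`angain` simulates loudness perception from the auditory periphery upward
and uses the simulation to compare candidate "central gain" mechanisms for
hyperacusis against audiometric data.  The core assumption throughout is
that perceived loudness is proportional to the summed firing rate of the
whole auditory-nerve (AN) population, and that two tones evoking the same
summed activity are equally loud.  Everything else — the cochlear stages,
the fiber population, the sone calibration, the equal-loudness-contour
(ELC) search, and the gain fits — serves that assumption.

## Signal chain

```
pressure waveform (Pa)
  -> outer/middle-ear filter (3 parallel Butterworth bandpasses)
  -> DRNL cochlear filterbank (N channels, ERB-spaced CFs 40 Hz - 13 kHz)
  -> transduction: half-wave rectified BM velocity x CF-dependent scale
  -> LIF fiber population (3 spontaneous-rate classes per channel)
  -> gain stage (healthy-control gain, optional hyperacusis gain)
  -> summed rate -> sones / ELCs
```

### Stimuli

Tones and white noise are normalised to an exact RMS target
(`20e-6 * 10^(L/20)` Pa), so level arithmetic is exact.  Raised-cosine
on/off ramps (10 ms default) avoid spectral splatter; because responses
are summarised as mean rates over the whole stimulus, ramps of this length
are negligible (<0.1 dB of RMS for stimuli of 0.25 s and longer, and the
normalisation removes even that).

### Outer/middle ear

Three parallel Butterworth bandpass branches: 1900–4200 Hz at −2 dB,
4500–6300 Hz at −3 dB, 8000–12000 Hz at −19 dB.  The branch order is 4 by
default.  This choice is measurement-driven: the branches are summed
coherently, and with order-2 branches the cross-branch leakage interferes
destructively enough that white-noise band gains come out at
−3.4/−4.9/−24.7 dB instead of the nominal −2/−3/−19 dB; with order-4
branches the measured band gains are within 0.4 dB of nominal.  The filter
is linear and time-invariant; the pressure-to-stapes-velocity conversion
is deferred to the filterbank's `stapes_scale` so that the filter itself
has unity passband gain (which is what a before/after spectral
measurement sees).

A consequence of the three-passband design is that the filter strongly
attenuates frequencies outside 1.9–12 kHz (about −40 dB at 1 kHz, −90 dB
at 250 Hz).  This makes the model's *absolute* thresholds in dB SPL
unrealistic at low frequencies; it does not matter for any quantity
expressed in model dB HL, because a per-frequency input attenuation moves
every contour at that frequency equally (see "Level grids" below for the
one place where it does intrude).

### DRNL filterbank

Each channel is a dual resonance non-linear filter: a linear pathway
(gain, two first-order gammatone filters, four second-order Butterworth
low-passes) in parallel with a non-linear pathway (three gammatones, the
broken-stick non-linearity `y = sign(i) * min(a|i|, b|i|^c)`, three more
gammatones, three low-passes).  Per-channel coefficients come from the
published human parameter-set regressions `log10(param) = p0 + m*log10(cf)`
stored in `src/angain/data/drnl_human.yaml` (versioned; alternates can be
swapped in).  The linear-path gain uses the sign-corrected slope
parameter, `log10(gain) = 4.20405 - g0*log10(cf)` with `g0 = +0.48`.
CFs are spaced evenly on the ERB-number scale
`E(f) = 21.4*log10(4.37 f/1000 + 1)`.

Gammatone stages are realised as two-pole resonators (poles at
`exp(-2*pi*bw/fs) * exp(+-2i*pi*fc/fs)`) normalised to unity gain at the
centre frequency; an order-n gammatone is n cascaded stages sharing the
same pole bandwidth.  The exact digital realisation is not prescribed by
the coefficient set, so correctness is verified through behaviour: the
on-CF input/output function is linear (1 dB/dB) below the broken-stick
knee and the compressive pathway settles to `c` dB/dB above it.  Near the
pathway crossover the *summed* output shows interference plateaus (the
two pathways are not phase-aligned); `process_channel(..., pathway=...)`
exposes the isolated pathways for diagnostics.

With the default `stapes_scale = 1.5e-2` (m/s per Pa) the 1-kHz channel's
compression knee sits near 35 dB SPL after the outer/middle-ear filter,
so the 30–90 dB range used for loudness calibration is dominated by
compressive growth, as it should be.

### Auditory-nerve population

Each channel drives three leaky integrate-and-fire fibers, one per
spontaneous-rate (SR) class: low-threshold/high-SR (35 sp/s), medium
(8 sp/s), high-threshold/low-SR (2 sp/s).  Membrane dynamics (voltage
dimensionless):

    tau dV/dt = -V + I(t) + sigma * sqrt(tau) * eta(t)

with `tau = 10 ms`, reset 0, spiking thresholds 1.0/1.6/2.5 for the three
classes (ordered opposite to SR), and an absolute refractory period
`t_ref = 1 ms`.  The per-class noise level `sigma` is calibrated
deterministically (Brent root finding on the stationary first-passage
rate) so the zero-drive firing rate equals the class SR target.  `t_ref`
gives a hard rate ceiling of 1000 sp/s; at the drives the model actually
reaches, rates stay in the physiological few-hundred-sp/s range and
saturation is soft, which keeps summed activity growing smoothly at high
levels across the whole frequency range.

The drive current is `I = k(cf) * max(0, v_bm)` — an IHC-like half-wave
rectification of basilar-membrane velocity.  The transduction scale has a
CF-dependent profile, `k(cf) = k0 * (cf/1 kHz)^-2`.  Rationale: the DRNL
regressions make the broken-stick gain `a(cf)` grow as `cf^0.82`, so a
flat transduction would leave high-CF channels tens of dB more sensitive
than low-CF ones; the full physiological model this population abstracts
normalises that in its hair-cell/synapse stages.  The exponent was chosen
together with the LIF constants so that the model's threshold profile and
rate-level dynamic ranges across CF are physiologically plausible and the
fitted loudness exponent lands in the reported range.  The absolute scale
`k0` is anchored so that the low-threshold class's best 1-kHz channel sits
10 sp/s above its spontaneous rate at −2.5 dB SPL, i.e. the model hearing
threshold at 1 kHz is near 0 dB SPL.

Two evaluation modes share these parameters:

* **rate mode** (deterministic): each fiber's rate is the stationary
  first-passage (Siegert) rate at the channel's mean rectified drive,
  `1/(t_ref + tau*sqrt(pi) * int erfcx(-u) du)`.  The mean-drive
  approximation is good when the carrier period is short against `tau`
  (CFs of a few hundred Hz and above).  All contour searches and fits run
  in this mode.
* **spiking mode** (stochastic): Euler–Maruyama integration with the
  classical `|zeta(1/2)|/sqrt(2 pi) * sigma * sqrt(dt/tau)` effective-
  threshold correction for discrete boundary crossings; without it,
  simulated rates sit 3–9% below the stationary rate at 44.1 kHz.  With
  it, class-mean rates agree with rate mode to within ~2% at constant
  drive, and the two modes' rate-level functions agree within 10%.

The supra-threshold gain variants gate on each fiber's *stored mean*
spontaneous rate (the calibrated class target), not a per-simulation
estimate.

### Loudness in sones

    Ldn = ((S - Ssp) / (S_ref - Ssp))^x

with `S` the summed rate, `Ssp` the summed spontaneous rate and `S_ref`
the summed rate for 1 kHz at 40 dB SPL, which therefore scores exactly
1 sone.  Responses whose sum falls below the baseline (possible by chance
in spiking mode) clamp to 0 sones.  The exponent is fitted at calibration
time by least squares in the log domain (closed form, anchored at the
40-dB reference) against sone targets for 1-kHz tones at 30–90 dB SPL in
10-dB steps.  The targets use the sone-scale law `2^((L-40)/10)` — a
desk-scale stand-in for the loudness standard's tabulated values, exact
at moderate levels by the definition of the sone.  On the desk preset the
fit gives `x = 1.61`; the value is a model measurement, not a constant.

### Equal-loudness contours

Two tones are equally loud when they evoke the same summed activity.
Contours are referenced to 1-kHz tones from −10 to 130 dB SPL in 10-dB
steps plus −5, −2 and 2 dB SPL (18 contours) and evaluated at 0.125,
0.25, 0.5, 1, 2, 3, 4, 6 and 8 kHz.  Summed activity is tabulated on a
level grid per frequency — coarse 10-dB steps, refined to 2-dB steps
around the model hearing threshold (where raw activity crosses the 1-kHz
2-dB reference) — and interpolated linearly in activity vs level; the
crossing level is then read off the interpolation.  "Model dB HL" is
obtained by subtracting the 2-phon contour at every frequency.

The grid spans −60 to 160 dB SPL.  This is wider than any physical
stimulus on purpose: the outer/middle-ear passband structure places model
thresholds at 2–8 kHz well below −20 dB SPL and the healthy 100-phon
contour at 250 Hz above 130 dB SPL, and clamping those crossings corrupts
the model-HL normalisation that every comparison relies on.  Points whose
crossing lies outside the grid are flagged (`below-range`/`above-range`)
rather than dropped, mirroring clinical equipment ceilings.

In rate mode the whole construction is deterministic; in spiking mode
each (frequency, level) stimulus uses a seed derived from the pair, so
contours are reproducible.

### Gain stage

The healthy-control gain is quadratic in CF, `g_hc(cf) = a + b(cf - c)^2`,
applied multiplicatively to every fiber's rate (baseline included).  The
quadratic's argument is CF in Hz by default (an ERB-number variant is
available); values dipping below a floor of 1e-3 are clipped with a
warning.  ELC matching is invariant to an overall rescaling of `g_hc`
(reference and target activities scale together), so the fit pins the
gauge `g_hc(1 kHz) = 1` and optimises curvature and vertex only, with the
offset derived.

Hyperacusis gains are the 2x2x2 variants {linear | power-law} x
{sub- | supra-threshold} x {frequency-independent | quadratic}:

    linear      g = g_l(cf)
    power-law   g = (R / Rmax)^z * g_max(cf),  z = 1.1 fixed, g <= g_max
    sub         R' = g * g_hc * R
    supra       R' = (max(0, R - Rsp) * g + Rsp) * g_hc

`Rmax` is the per-class refractory ceiling (1/t_ref); since it enters
only as a normalisation, a different choice rescales the fitted `g_max`
without changing behaviour.

### Fitting

Hand-fitting is replaced by deterministic bounded optimisation.  The
objective is piecewise-linear in the tabulated grids (hence
derivative-free search): multi-start Nelder–Mead over (curvature, vertex)
for quadratics, a log-spaced grid plus simplex refinement for scalar
gains.  The healthy fit selects, per candidate gain, the reference phon
level whose contour passes nearest the control LDLs (stored as
`phon_ldl`, typically 100), converts contours to model HL with that
gain's own 2-phon contour, and minimises the weighted RMS distance at the
control LDL frequencies.  Hyperacusis fits freeze the healthy model
entirely (its gain, loudness calibration, 2-phon contour and the
reference activity at `phon_ldl`) and seek the level, per frequency, at
which *gained* activity reaches the healthy LDL reference activity.

Fit weights default to 1 with 125 Hz and 8 kHz down-weighted to 0.25:
the audiometer output limits at those frequencies (90 and 100 dB HL,
vs 110–120 dB HL elsewhere) skew measured group-mean LDLs, so they should
not steer the fit; contour points outside the search grid are charged a
flat 30-dB penalty.

`compare_variants` fits all eight variants and reports, per variant, the
LDL fit residual, the no-stimulus baseline activity change (elevation =
tinnitus proxy; the sub-threshold power-law instead *collapses* the
baseline because `(Rsp/Rmax)^z` is tiny), and the 2-to-30-phon growth
span at 1 kHz (28 dB in the healthy model by the phon anchoring; its
compression is the near-threshold step artifact).  The combined artifact
score adds the three axes in dB:
`residual + |baseline change| + max(0, 28 - span)`.

### Synthetic cohorts

The package emulates the audiometric group means rather than any real
dataset: control thresholds at 0 dB HL with LDLs flat at 100 dB HL
(measured at 0.5–4 kHz, as for the control group), and patient LDLs
shifted −20 dB across the clinical frequency set 0.125–8 kHz.  Optional
per-subject jitter is re-centred so the sample mean equals the target
mean exactly at every frequency.  What this does *not* emulate: real
control LDL spread across frequency, non-flat patient LDL shapes,
threshold microstructure, or any individual-level variability — so
passing fits show that the machinery discriminates gain mechanisms under
the idealised group-mean pattern, not that it reproduces any particular
cohort.

### Presets and problem sizes

* `full` — 500 channels, 10-s stimuli, spiking fibers: the
  reproduction-scale configuration.
* `desk` — 64 channels, 1-s stimuli, rate mode: the scale used by the
  test suite and the acceptance script; chosen so a full
  calibrate–fit–compare cycle runs in minutes on one core.
* `micro` — 24 channels, 0.25-s stimuli at 32 kHz: smoke tests.

All physiology constants are identical across presets; only the scale
changes.

## Known limitations

* **Frequency-uniformity of gain-induced shifts.**  A frequency-
  independent gain shifts each frequency's contour by (activity boost) /
  (local log-slope of the activity curve), and the log-slope at the LDL
  crossing varies across frequency in this implementation (≈0.11 dB/dB at
  250 Hz to ≈0.18 dB/dB at 4 kHz).  The fitted frequency-independent
  variants therefore track a uniformly shifted LDL curve only to within
  about ±5–7 dB (overshifting low frequencies, undershifting 4 kHz), not
  the few-dB agreement the original hand-fit implementation reports.
  This residual structure proved robust to every physiology dial exposed
  here (saturation rate, threshold spread, channel count, transduction
  profile, sensitivity anchor, grid density).
* **Near-threshold growth is log-linear.**  The Siegert rate rises
  smoothly from the spontaneous baseline, so the fitted *linear*
  supra-threshold gain (which needs only g ≈ 2–3 here for a 20-dB LDL
  shift) barely compresses the 2-to-30-phon span; the pronounced
  near-threshold step this mechanism is known for appears in this
  implementation mainly through the *power-law* supra-threshold variants,
  whose rate-dependent boost is convex in level.
* Low-frequency (≤250 Hz) contours rely on crossings beyond the physical
  stimulus range because of the outer/middle-ear passband structure;
  they are computed but flagged.
* ELCs are qualitatively shaped like standard contours only; no
  quantitative match to the ISO contours is attempted.
* Binaural integration, adaptation, phase locking, hidden hearing loss
  and individual-patient fitting are out of scope.
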