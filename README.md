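# angain

**An auditory-periphery loudness model with a central gain stage, for
investigating candidate hyperacusis mechanisms.**

Hyperacusis is an auditory disorder in which sounds of ordinary loudness
are perceived as uncomfortably or painfully loud; patients' loudness
discomfort levels (LDLs) sit roughly 20 dB below those of normal-hearing
listeners, fairly uniformly across the audiometric range.  A leading
hypothesis is an abnormal increase of neuronal response *gain* in the
central auditory system.  `angain` is a computational test bench for that
hypothesis, aimed at auditory modellers and hearing researchers: it
simulates the auditory periphery up to the auditory nerve (AN), predicts
loudness from summed AN activity, and fits competing "hyperacusis gain"
mechanisms to audiometric data so they can be compared on equal terms.

## The model

Sound pressure is passed through an outer/middle-ear filter (three
parallel Butterworth bandpasses: 1.9–4.2 kHz at −2 dB, 4.5–6.3 kHz at
−3 dB, 8–12 kHz at −19 dB), then through a dual resonance non-linear
(DRNL) cochlear filterbank — per channel, a linear pathway in parallel
with a compressive pathway built around the broken-stick non-linearity

    y(t) = sign(i(t)) · min(a·|i(t)|, b·|i(t)|^c)

with human per-CF coefficients on an ERB-spaced grid (40 Hz–13 kHz).
Each channel drives three leaky integrate-and-fire fibers with
spontaneous rates of 35, 8 and 2 sp/s (thresholds ordered oppositely).
Loudness in sones is computed from summed AN activity,

    Ldn(f, L) = ( (Σcf R_AN(f,L,cf) − R_ANsp) /
                  (Σcf R_AN(1 kHz, 40 dB, cf) − R_ANsp) )^x

so a 1-kHz tone at 40 dB SPL scores exactly 1 sone; the exponent `x` is
fitted at calibration time against the sone scale (the desk-scale model
yields `x = 1.61`).  Equal-loudness contours follow from the assumption
that equal summed activity means equal loudness.

On top sits a gain stage: a quadratic healthy-control gain
`g_hc(cf) = a + b(cf − c)²` fitted to control LDLs, plus one of eight
hyperacusis gain variants — {linear | power-law (g ∝ (R/Rmax)^1.1)} ×
{sub- | supra-threshold} × {frequency-independent | quadratic} — fitted
to patient LDLs with the healthy model frozen.  Supra-threshold variants
amplify only the evoked response, `(max(0, R − Rsp)·g + Rsp)·g_hc`,
which is the crux of the hyperacusis-vs-tinnitus distinction the model
probes.  See `docs/methods.md` for assumptions, parameter rationale and
known limitations.

## Worked example

```python
from angain import AuditoryModel, preset, loudness_sones

model = AuditoryModel(preset("micro"))   # 24 channels, 0.25-s tones
model.calibrate(seed=1)

print("sone exponent x =", round(model.loudness_.x, 3))
for level in (40, 50, 60, 70):
    s = loudness_sones(model.response(1000.0, level), model.loudness_)
    print(f"1 kHz at {level} dB SPL -> {s:.2f} sones")
```

prints

```
sone exponent x = 1.675
1 kHz at 40 dB SPL -> 1.00 sones
1 kHz at 50 dB SPL -> 2.27 sones
1 kHz at 60 dB SPL -> 4.31 sones
1 kHz at 70 dB SPL -> 7.97 sones
```

The 40-dB tone is 1 sone by construction; each 10-dB step roughly
doubles loudness, as the sone scale demands (the smoke-test `micro`
preset overshoots slightly; the `desk` preset doubles within 15%).

The same pipeline from the shell:

```bash
angain calibrate --preset desk --seed 1 --out runs/cal
angain make-fixtures --out runs/fx
angain elc --calibration runs/cal --out runs/elcs.csv
angain fit-gain --calibration runs/cal \
    --control runs/fx/control.csv --patient runs/fx/patient.csv \
    --out runs/variants.csv --healthy-out runs/healthy_gain.yaml
```

`fit-gain` prints one line per variant (LDL fit residual, no-stimulus
baseline change, near-threshold growth span) and ranks the eight
mechanisms by a combined artifact score; on the synthetic −20 dB patient
cohort the supra-threshold variants keep spontaneous activity untouched
while the sub-threshold linear variants acquire a phantom-sound
(tinnitus-like) baseline and the sub-threshold power-law variants
collapse it.

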