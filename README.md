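# snailrelay

ODE models and analyses of how cells read TGF-β **duration** through the
SMAD → GLI1 relay that controls SNAIL1.

TGF-β activates SNAIL1 — the transcription factor gating apoptosis and
the epithelial–mesenchymal transition — through two convergent arms: the
canonical pathway, in which nuclear pSMAD2/3–SMAD4 complexes
transactivate SNAIL1 and their own inhibitor (I-SMAD closes a negative
feedback, making the pSMAD response a transient that peaks near 12 h),
and a slow arm in which pSMAD-induced GLI1, amplified by a GLI1
transcriptional positive feedback and gated by a GSK3 phosphorylation
switch (active A, extra-active ER/Golgi-localized AA, inactive D with
A + AA + D conserved), sustains SNAIL1 at late times.  Under sustained
TGF-β, SNAIL1 shows two waves; short pulses trigger only the first.  The
network is thus a temporal checkpoint, and coarse-graining pSMAD, GLI1
and SNAIL1 levels at 12 h and 48 h yields a temporally ordered state
space (TOSS) that encodes stimulus duration.

The package provides, as an analysis project over a library:

* `snailrelay.models` / `simulate` — the nested ODE variants
  (`SMAD_ONLY` ⊂ `SMAD_GLI` ⊂ `FULL`), stimulus profiles, timed
  inhibitors (SMAD-phosphorylation, GLI1-activity, GSK3-activity),
  basal-fixed-point fold-change normalization.
* `snailrelay.targets` / `search` / `calibrate` — fold-change constraints
  as data (JSON), a weighted relative-residual cost, multi-start
  Metropolis search in log-parameter space, and the staged calibration of
  the full model, including the SMAD-only falsification (the canonical
  model fits the pSMAD transient but cannot produce two SNAIL1 waves).
* `snailrelay.motif` — the generic positive-feedback loop with an
  inactive-reservoir boost: response times, boost acceleration
  Δt_R((X)₀), noise-filtering boundaries.
* `snailrelay.duration` — pulse-duration scans, two-wave classification,
  duration-threshold bisection, TOSS encoding, and the four
  threshold-modulation predictions.
* `snailrelay.synth` — lognormal single-cell populations, triplicate
  qPCR-like fold changes, and parameter-recovery fixtures.

Numbered drivers in `analysis/` narrate the main results and write tables
under `results/`; a `snailrelay` CLI (`simulate`, `fit`, `falsify`,
`scan`, `motif`, `synth`, `calibrate`) wraps the same library.

## The model in brief

Hill-type activation (coefficient 2; the GLI1 self-activation coefficient
is fitted in 1–4), linear degradation, mass-action GSK3 interconversion.
SNAIL1 transcription is additive in its two inputs:

    d[SNAIL1_mRNA]/dt = b_S + a_SR·H(pSMAD) + a_SG·H(GLI1_nuc) − d_Sm·[SNAIL1_mRNA]

GSK3^AA acts only on the SUFU-complex release flux (its ER/Golgi role,
driven by a band-pass-filtered stimulus signal that peaks near 6–8 h);
active GSK3 accelerates degradation of SNAIL1 protein and the GLI1
pools.  A slowly decaying persistent-signaling pool charged by ligand
exposure lets washed-out pulses leave a duration-graded pSMAD residue
while a receptor-kinase inhibitor silences signaling outright.  Time is
in hours; concentrations are fold changes over the basal fixed point;
stimulus amplitude 1 ≡ the standard 4 ng/ml TGF-β1 dose.  See
`docs/methods.md` for the full account.

## Worked example

```python
from snailrelay import build_model, simulate, StimulusProfile, InhibitorSpec
from snailrelay.calibrate import calibrated_params
from snailrelay.duration import classify_waves, encode_toss

model = build_model("FULL")
params = calibrated_params()

cont = simulate(model, params, StimulusProfile())      # 4 ng/ml, 72 h
print(cont.argmax_time("pSMAD_nuc"))                   # 11.6  (h; transient peak)
print(round(cont.raw("GSK3_D", 12.0), 3))              # 0.649 (65% of GSK3 in the D form)
print(classify_waves(cont).label)                      # two_wave

p2 = simulate(model, params, StimulusProfile.pulse(2.0))
p8 = simulate(model, params, StimulusProfile.pulse(8.0))
print(classify_waves(p2).label, classify_waves(p8).label)  # one_wave two_wave
print(encode_toss(p8))                                 # (H, M; L, H) / SNAIL1 (H, H)

# timed inhibition: GANT61-like GLI1 block from 48 h
late = simulate(model, params, StimulusProfile(), [InhibitorSpec("GLI1_ACT", 48.0)])
pct = 100 * late.value("SNAIL1_mRNA", 72) / cont.value("SNAIL1_mRNA", 72)
print(round(pct))                                      # 14 (% of control at 72 h)
```

The same results, with tables, come from the analysis drivers:

```sh
python analysis/01_simulate_canonical.py   # canonical trajectory + headline numbers
python analysis/02_calibrate.py 1          # staged Monte Carlo calibration (seed 1)
python analysis/03_falsify_smad_only.py    # SMAD-only falsification
python analysis/04_inhibitor_panel.py      # timed-inhibition percentages
python analysis/05_motif_boost.py          # boosted-feedback response times
python analysis/06_duration_scan.py        # duration threshold, TOSS, modulations
```

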