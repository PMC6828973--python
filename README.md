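# flexrelax

Analysis of the **flexion relaxation phenomenon (FRP)** — the myoelectric
silence of the superficial lumbar paraspinal muscles during deep trunk
flexion — from **high-density surface EMG (HDEMG)** electrode grids.

The FRP is a classic clinical sign: pain-free people "switch off" their
erector spinae as they approach full trunk flexion, while many people with
low back pain (LBP) do not, or do so late. Classical bipolar EMG measures
this at a single site; an HDEMG grid (13 × 5 electrodes, 8 mm spacing, one
corner absent, 64 electrodes per side) measures it over the whole lumbar
region, so both the *timing* and the *spatial distribution* of the
relaxation can be quantified. `flexrelax` is for researchers in
neurophysiology and rehabilitation who want that analysis as a tested,
scriptable pipeline rather than a one-off spreadsheet.

## What it computes

For a trapezoidal flexion task (quiet standing → 4 s flexion → 8 s full
flexion → 4 s extension) recorded as 64 monopolar channels at 2048 Hz plus a
trunk electrogoniometer trace:

1. **Preprocessing** — zero-phase 20–350 Hz band-pass, along-column
   (cranio-caudal) differencing into 59 bipolar channels, automated channel
   QC (SNR, low-frequency artefact, dead-contact screens); flagged channels
   are kept and marked, never dropped.
2. **Kinematics** — velocity-threshold segmentation of the angle trace into
   baseline / flexion / full-flexion (MVF) / extension, and the mapping of
   angle to % of maximal trunk flexion.
3. **FRP onset detection** — per channel, the EMG offset is the first
   flexion-phase sample where the rectified, 50 Hz low-passed envelope falls
   below `T = μ_b + 3σ_b` (quiet-standing baseline mean + 3 SD) and stays
   below it for ≥ 0.25 s. The FRP is *present* for a subject/side when >50%
   of usable channels show an offset; onsets are expressed as % of trunk
   flexion and assembled into a 12 × 5 spatial onset map.
4. **Amplitude profiling** — per-channel RMS in adjacent 1 s epochs
   (4 flexion + 8 MVF), grid-averaged and normalized to the peak 1 s
   extension-phase RMS.
5. **Inference** — mixed-effects smoothing-spline ANOVA (SS-ANOVA):
   a cubic smoothing spline over time for the amplitude curve and a
   thin-plate spline over the grid plane for the onset map, with group (and
   side) as sum-coded nominal factors, a ridge-penalized subject intercept,
   GCV-selected smoothing, and Bayesian posterior covariance. Group
   differences are contrast curves with pointwise and mean 95% credible
   intervals; a contrast is significant when the mean difference's interval
   excludes zero.

Because raw cohorts of this kind are rarely shareable, the package ships a
**synthetic cohort generator** (`flexrelax.synthetic`) that emulates the
acquisition — band-limited EMG carriers with spatially correlated sources,
group-specific relaxation behaviour (controls relax mid-flexion, one LBP
subgroup relaxes late, one never relaxes), cranio-caudal onset gradients,
goniometer kinematics — and records the ground truth, so the entire pipeline
is testable by parameter recovery.

## Worked example

```python
import flexrelax as fr
from flexrelax.pipeline import PipelineConfig, analyze_cohort

cfg = fr.SyntheticConfig(n_per_group=(4, 3, 2), sampling_rate=1024.0,
                         n_repetitions=2, seed=7)
cohort = fr.generate_cohort(cfg, materialize=False)
result = analyze_cohort(cohort, PipelineConfig(synthetic=cfg))

subjects = result.classification.groupby("subject").agg(
    group=("group", "first"), frp=("frp_present", "first"),
    onset=("mean_onset_pct", "mean"))
print(subjects.round(1))
c = result.onset_contrast
print(f"onset delay: {c.mean_difference:.1f}% "
      f"(95% CI {c.mean_ci[0]:.1f} to {c.mean_ci[1]:.1f})")
```

prints

```
              group    frp  onset
subject
ctrl01      control   True   63.7
ctrl02      control   True   66.0
ctrl03      control   True   60.2
ctrl04      control   True   49.8
frp01       lbp_frp   True   74.6
frp02       lbp_frp   True   72.6
frp03       lbp_frp   True   68.4
nofrp01  lbp_no_frp  False    NaN
nofrp02  lbp_no_frp  False    NaN

onset delay: 12.0% (95% CI 3.8 to 20.1)
```

Every control and the `lbp_frp` subjects are classified as exhibiting the
FRP (the `lbp_no_frp` subjects are not, so they have no onset), and the
SS-ANOVA contrast recovers the onset delay injected by the generator
(13 points at the population level; 12.0 realized in this small cohort)
with a credible interval that covers it.

The same pipeline is available from the shell:

```bash
flexrelax simulate --config cohort.yaml     # write trial CSVs + truth tables
flexrelax analyze  --config cohort.yaml     # tables, figures, manifest
flexrelax report   --config cohort.yaml     # plain-text summary
```

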