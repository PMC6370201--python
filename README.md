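# dyadsync

Identification of movement synchrony in dyadic interactions from
motion-energy time series, with a fully synthetic validation study.

## The problem

When two people interact — a patient and a therapist in a video-recorded
session, say — their body movements occasionally become coupled: one
person's movement is followed, after a short delay, by a related movement
of the other.  Motion energy analysis (MEA) reduces each person's video to
a *motion energy time series* (METS): the number of pixels inside that
person's region of interest whose intensity changed between consecutive
frames.  Detecting *movement synchronization intervals* (MSIs) in a pair
of METS is usually done with **windowed cross-lagged correlation (WCLC)**
or **windowed cross-lagged regression (WCLR)**: a window of length *W*
(the bandwidth) slides along person A's series and, for every time lag ℓ
on a grid up to ±75 frames, the local association with person B's window
is computed —

- WCLC: the squared Pearson correlation
  r²(t, ℓ) = corr(a[t:t+W], b[t+ℓ:t+ℓ+W])², tested with the t statistic
  r·√((W−2)/(1−r²));
- WCLR: the R² gained by adding A's window to an autoregressive baseline
  b[i] ~ 1 + b[i−1] (an AR(1) control against spurious correlation in
  cyclic series), tested with the F statistic for the added predictor.

The result is an m×n **R² landscape** over (time, lag).  A peak-picking
pass chains contiguous significant ridge maxima into discrete intervals
with a characteristic lag, and an interval-level **R² cutoff** removes
spurious low-association intervals.

The catch: results depend heavily on the analysis configuration —
method (WCLC/WCLR), transform (raw, ROI-size standardization, log(x+1),
Anscombe 2√(x+3/8)), smoothing (none / slight spline p=.900 / heavy spline
p=.005), bandwidth (75–750 frames) and R² cutoff (0–0.3).  This package
implements the full detection stack *and* the factorial validation study
that scores all 2×4×3×5×5 = 600 configurations: per configuration, Cohen's
kappa between detected and reference intervals on sequences containing
synchrony, and the proportion of over-identified frames (pr_out) on
sequences containing none, classified into an ordinal identification rate
(good / acceptable / poor).

Because the original therapy videos are not distributable, the package
ships a synthetic-data generator that emulates their statistics: bursty,
zero-inflated pulse trains at 25 fps, ~118 s long, with reference
intervals of mean 145 frames (SD 57.93, range 26–282), produced in three
complexity conditions — naturally *embedded*, *isolated* (everything
outside the interval zeroed) and *artificial* (person B replaced by an
exact 50-frame-lagged echo of A, or by zeros for no-sync pairs).

## Worked example

```python
from dyadsync import (AnalysisConfig, GeneratorParams, SmoothingSpec,
                      TransformSpec, generate_base_pair, identify_msi,
                      make_artificial, make_isolated)

params = GeneratorParams()
embedded, ref = generate_base_pair(params, sync=True, seed=7)
artificial = make_artificial(make_isolated(embedded), lag=50)

config = AnalysisConfig(method="WCLC", transform=TransformSpec("log1p"),
                        smoothing=SmoothingSpec("none"),
                        bandwidth=125, r2_cutoff=0.25)
for iv in identify_msi(artificial, config, master_seed=1):
    print(f"MSI [{iv.start}, {iv.end}) lag={iv.lag:+.0f} mean R2={iv.mean_r2:.2f}")
print(f"reference interval [{ref.start}, {ref.end})")
```

prints

```
MSI [1609, 1742) lag=+50 mean R2=0.96
reference interval [1589, 1751)
```

— the pipeline recovers the constructed 50-frame echo lag exactly and the
detected span misses the reference interval by a handful of frames on
either side (the window only becomes significant once it captures enough
of the pulse).

The analysis drivers reproduce the study end to end:

```bash
python analysis/01_simulate_dataset.py     # 60-dyad dataset + summary
python analysis/02_echo_lag_recovery.py    # lag recovery across 10 pairs
python analysis/03_run_config_grid.py      # reduced 32-config grid (--full for 600)
python analysis/04_parameter_statistics.py # cross tables, ordinal regression, KW tests
```

On the default reduced grid, 8 of 32 configurations reach a good
identification rate in the artificial condition (all WCLC at bandwidth
125; min kappa 0.67–0.80, max pr_out < 1%), bandwidth dominates the cross
tables (Cramér's V = 0.58), and the echo lag is recovered for 10/10 pairs.

## Layout

- `src/dyadsync/` — the library: `motion_energy` (MEA from frame stacks),
  `preprocessing` (transforms, smoothing splines, noise injection),
  `detection` (WCLC/WCLR landscapes, peak-picking, cutoff filter),
  `synthetic_data` (generator and the three conditions), `evaluation`
  (kappa, pr_out, IR classification, sequential gating), `study` (600-config
  grid, cross tables, ordinal regression, Kruskal–Wallis), `io` (plain-text
  METS/manifest/interval/result tables).
- `analysis/` — numbered narrative drivers writing small tables to `results/`.
- `docs/methods.md` — model, parameters, generator design and limitations.
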