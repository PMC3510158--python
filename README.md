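# lenfreq

Statistical comparison of fish length-frequency distributions between two
sampling methods — for example, fishery-independent line fishing versus
baited remote underwater stereo-video (stereo-BRUVS). Different gears select
different sizes of fish, so before length data from a new survey method can
feed a stock assessment, one has to ask: do the two methods sample the same
length distribution, and if not, does the difference lie in the *location*
of the distribution, its *shape*, or both?

`lenfreq` is for fisheries scientists and quantitative ecologists who have
per-fish length records (fork length, mm) labelled by species and sampling
method and want a defensible, fully nonparametric answer.

## Methods at a glance

Given two samples x₁ (n₁ fish) and x₂ (n₂ fish):

* **Kernel density estimates.** Each sample is smoothed with a Gaussian KDE
  f̂(y) = (nh)⁻¹ Σᵢ φ((y − xᵢ)/h). Bandwidths come from the Sheather–Jones
  two-stage direct plug-in rule (the `dpik`-style recursion), which is
  data-driven and makes no distributional assumptions. Summary modes are the
  KDE argmax on a 1-mm grid.
* **Permutation test of density equality.** Both KDEs are rebuilt at the
  common bandwidth h = √(h₁h₂) (geometric mean, so neither sample size
  dominates the smoothing) and compared by the integrated squared difference
  T = ∫(f̂₁ − f̂₂)² dy. The null distribution of T comes from repeatedly
  reallocating the pooled lengths into random groups of sizes n₁ and n₂
  (without replacement) at the *same* h and grid; p = (1 + #{T* ≥ T}) / (1 + N).
  A grey reference band, built on the variance-stabilising √density scale,
  shows where the two estimates depart from the null of no difference.
* **Tie-tolerant bootstrap KS test.** The classical two-sample
  Kolmogorov–Smirnov statistic D = sup|ECDF₁ − ECDF₂| with a Monte-Carlo
  p-value obtained by resampling the pooled data *with* replacement — valid
  for mm-rounded lengths full of ties, where the asymptotic null
  distribution is not.
* **Location + shape vs shape only.** Each test is run twice: on raw lengths
  (sensitive to location and shape) and after standardising each sample by
  its own median and SD, y = (x − median)/SD (sensitive to shape only:
  skewness, modality).
* **Synthetic scenarios.** A seeded truncated-Gaussian-mixture generator
  emulates realistic gear-comparison data (unimodal distributions with a
  mode near a minimum legal length, and a bimodal case with a second mode of
  large fish near 600 mm), so the whole pipeline is testable without any
  field data.

## Worked example

Simulate a snapper-like comparison — a unimodal line-fishing sample (n=431)
against a bimodal stereo-video sample (n=557) — then summarise and test it:

```sh
lenfreq simulate --scenario pauratus_like --seed 7 --out lengths.csv
lenfreq summarize --input lengths.csv
```

```
      species       method  mean    sd  mode_kde  count        min        max  bandwidth
pauratus_like         Line 387.9  91.5     374.0    431 144.102322 682.726112      28.55
pauratus_like stereo-BRUVS 450.9 116.4     387.0    557 204.946747 736.658004      22.29
```

Both gears put the main mode just below the 400-mm legal limit (374 vs
387 mm), but the video sample's larger mean and SD betray its second mode of
large fish. Now the tests:

```sh
lenfreq -v compare --input lengths.csv --n-permutations 10000 --n-boots 10000 \
        --seed 7 --outdir report --plots --mll pauratus_like=400
```

```
INFO lenfreq: pauratus_like [location_and_shape]: n=(431, 557) h1=28.55 h2=22.29 h_common=25.23 KDE p=0.0001 KS p=0.0001 (seed 2083679832)
INFO lenfreq: pauratus_like [shape_only]: n=(431, 557) h1=0.31 h2=0.19 h_common=0.24 KDE p=0.0001 KS p=0.0018 (seed 2083679832)
```

All four p-values are small: the two gears differ in location *and* — even
after removing location and scale — in shape, exactly what a bimodal versus
unimodal pair should produce. `report/` contains the machine-readable
results (`tests.json`, `tests.csv`, `summary.csv`), the reference band per
comparison as CSV, and the figures: per-gear histogram + KDE + rug with the
legal-length line, and the overlaid KDE pair inside the grey null band.

For a null scenario (`--scenario null_pair`) the same pipeline returns
p-values spread over (0.05, 1], and for a pure shift (`shift_only`) the
location+shape tests reject while the shape-only tests do not.

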