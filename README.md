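# spatialtuning

Analysis toolkit for rodent spatial-coding electrophysiology: head-direction
(HD) cell tuning curves, place-cell firing-rate maps, formula-based cell
classification, rotational cross-correlation estimates of landmark stimulus
control, and the circular-statistics inference battery used to compare shift
distributions — plus a synthetic foraging/spiking simulator so the whole
chain can be validated end to end without any recordings.

## Who this is for

Labs analyzing tetrode recordings of HD cells (postsubiculum/MEC) and place
cells (CA1) in cue-manipulation designs: multi-compartment mazes that ask
whether directional tuning is anchored to a global reference or to local
compartment geometry, and cue-card/barrier rotation protocols that measure
how strongly a landmark controls spatial firing.

## The statistics at the core

* **Tuning curve / rate map.** Occupancy-normalized firing rate over 1°
  heading bins (circular-Gaussian smoothed, σ = 6°) or 2.5 cm position bins
  (Gaussian smoothed, σ = 5 cm, kernel renormalized over visited bins).
* **Mean vector length.** For a tuning curve with rates λ_b at directions
  θ_b: r = |Σ_b λ_b e^{iθ_b}| / Σ_b λ_b. HD criterion: r ≥ 0.2 and mean
  rate ≥ 0.3 Hz in both bracketing open-field sessions (plus ≥ 100
  spikes/session in the rotation experiment).
* **Spatial information (Skaggs).** SI = Σ_i p_i (λ_i/λ̄) log₂(λ_i/λ̄)
  bits/spike on unsmoothed rates. Place criterion: SI > 0.5, mean rate in
  [0.15, 6] Hz, spike width > 0.25 ms, after a > 3 cm/s speed filter.
* **Rotational cross-correlation.** The angular shift between two sessions
  (or two maze compartments) is the circular lag maximizing the Pearson
  correlation between tuning curves (1° steps) or between rate maps with one
  session's raw samples rotated about the arena center (5° steps).
* **Circular inference.** V-test (clustering around a predicted direction),
  Kuiper's uniformity test, Watson's U² von Mises goodness of fit
  (parametric bootstrap), Moore's paired test (Monte-Carlo null), ML
  estimation of the von Mises concentration κ, and the Mardia–Jupp
  two-sample concentration comparison.

## Worked example

Simulate a 10-minute octagon session with two HD cells, validate it, and
classify the units against a second (bracketing) session:

```bash
$ spatialtuning simulate --kind octagon --cells hd:2 --duration 600 --seed 3 --out demo/s1
wrote 2 units to demo/s1
$ spatialtuning validate-session demo/s1
OK: 30000 tracking samples at 50.0 Hz, 2 units (7948 spikes), duration 600.0 s
$ spatialtuning simulate --kind octagon --cells hd:2 --duration 600 --seed 4 --out demo/s2
wrote 2 units to demo/s2
$ spatialtuning classify --mode hd demo/s1 demo/s2
unit_id,r_1,r_2,rate_1,rate_2,decision
hd_00,0.7780556653902239,0.7730531902692476,6.625,6.78,True
hd_01,0.7739866348854271,0.7758782682942403,6.621666666666667,6.976666666666667,True
```

Both units clear the r ≥ 0.2 / ≥ 0.3 Hz criterion easily (the simulated
von Mises tuning with κ_t = 4 gives mean vectors r ≈ 0.78 here). The
rotational cross-correlation of a unit's tuning curve against itself
recovers a 0° shift at correlation 1:

```bash
$ spatialtuning rotation --pair demo/s1 demo/s1 --unit hd_00 --mode tuning
unit,shift_deg,max_corr,min_corr,n_overlap
hd_00,0.0,1.0000,-0.4659,360
```

A full in-silico experiment (simulate → classify → shift estimation →
inference) runs from a YAML config:

```bash
$ printf 'experiment: compartments\nn_cells: 12\nduration: 600.0\nseed: 5\n' > cfg.yml
$ spatialtuning run --config cfg.yml --out out/
```

which reports, among others, `mean_shift_parallel_deg: 0.444`,
`mean_shift_radial_deg: -0.472` and a V-test toward 0° with p < 10⁻⁶ — a
global-reference population: adjacent-compartment shifts cluster at 0° in
both maze configurations. With `reference_mode: local` the radial mean
shift moves to ≈ 60°, the signature of tuning re-anchoring to each
compartment.

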