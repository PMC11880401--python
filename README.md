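# crt-cluster

Movement-pattern analysis of the **five time chair rise test (5CRT)** from
force-plate recordings.

The 5CRT — stand up from a chair and sit back down five times as fast as
possible — is scored in geriatric assessment by a single stopwatch time
(0–4 SPPB points). A stopwatch hides *how* a person rises. This package
analyzes the vertical ground reaction force Fz recorded under the feet
(200 Hz force plate) during the test and groups chair-rise waveforms into
movement patterns, exposing differences (notably in the post-rise
stabilization phase) that duration alone cannot show. It is aimed at
researchers in biomechanics and functional assessment of older adults.

## What it computes

For each recording the pipeline:

1. **Segments** the trace: finds the rest-bounded active span and splits it
   into the five chair-rise cycles (all-or-nothing; incomplete tests are
   excluded with a diagnostic). The force-plate test duration `t_GRF` is the
   active-span length.
2. **Extracts phase forces** per cycle from the body-weight-normalized
   signal `F_z = F_z,GRF / (m·g)`: the seat-unloading minimum, the seat-off
   peak, the stabilization minimum and the standing value — the four
   landmarks of the classical sit-to-stand phase decomposition (flexion
   momentum, momentum transfer, extension, stabilization).
3. **Clusters** each participant's peak-normalized first chair rise with
   k-means under the **dynamic time warping** metric,

   `DTW(x, y) = min_π sqrt( Σ_{(i,j)∈π} (x_i − y_j)² )`,

   using **DTW Barycenter Averaging (DBA)** for the cluster centers
   (k = 2, 10 restarts, 100 iterations max). Cycles 2–5 are then assigned
   with the fitted model. Labels are canonicalized so *cluster 1* is always
   the low-stabilization-force pattern.
4. **Evaluates**: silhouette sweep over k = 2…10 and Davies-Bouldin index in
   DTW space; per-variable cluster comparisons (Shapiro-Wilk audit +
   two-sided Mann-Whitney U at α = 0.01); OLS regression of `t_GRF` on the
   stopwatch time; a cycle-to-cluster consistency table; SPPB scoring.

Because no public 5CRT force-plate dataset exists, the package ships a
first-class **synthetic cohort generator** (`crt_cluster.synthetic`) whose
defaults are calibrated to published cohort statistics: two archetypes with
stabilization forces 0.39 ± 0.16 vs 0.69 ± 0.13 body weights, stopwatch
durations 9.84 ± 1.41 s vs 12.59 ± 2.47 s, and the duration relation
`t_GRF = 0.89·t_stopwatch + 2.86`. Every generated recording carries a
ground-truth channel so recovery can be measured. See `docs/methods.md` for
the model and its limitations.

## Worked example

```bash
crt-cluster simulate --n1 20 --n2 28 --seed 3 --out demo
crt-cluster run --input demo --out report
```

prints

```
wrote 48 recordings to demo
analyzed 48 participants (240 cycles); cluster sizes: {0: 21, 1: 27}
```

and writes `labels.csv`, `phases.csv`, `summary.json`, `regression.json`,
`consistency.csv` and the barycenter CSVs into `report/`. From
`summary.json` and `regression.json` of that run:

| cluster | n | stopwatch (s) | stabilization force (a.u.) |
|---|---|---|---|
| 1 (low-stab) | 21 | 10.31 ± 1.65 | 0.41 ± 0.14 |
| 2 (high-stab) | 27 | 12.30 ± 2.40 | 0.74 ± 0.09 |

The stabilization force separates the clusters (Mann-Whitney
p = 9.7·10⁻⁹ < 0.01) while the seat-off peak does not (p = 0.05); the
duration regression recovers slope 0.886 and intercept 2.93 s — the
embedded relation. 88% of participants keep all five rises in their
first-rise cluster (`consistency.csv`). A single duration is scored with

```bash
crt-cluster score --duration 12.47   # -> 3  (SPPB points)
```

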