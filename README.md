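# seizurepca

Early seizure onset detection from EEG frequency-band energies via a
dominant-eigenvector (uncentered PCA) feature, with full threshold
metrology and a seeded synthetic ictal-EEG generator.

## The problem

Closed-loop neurostimulation for intractable epilepsy needs seizure onsets
detected within a few seconds and with few false alarms.  A simple,
hardware-friendly detector thresholds a scalar feature computed from the
EEG spectrum.  The question this package addresses: *which* spectral
feature?  Individual band energies (δ, θ, α, β, γ) each capture only part
of the ictal signature, and the spectral profile of the first seconds of a
seizure (beta-dominant build-up) differs from its later course
(theta-dominated rhythmic activity).  A weighted combination of band
energies trained specifically on the *initial* seizure segment should
therefore detect onsets earlier and more reliably than any single band or
than a combination trained on whole seizures.

## The method

For a single EEG channel x(n) sampled at f_s = 200 Hz, each 2 s window
(1 s hop) is passed through a first-difference filter and an unnormalized
DFT,

    X[k] = Σ_{n=0}^{N−1} [x(n+1) − x(n)] e^{−j2πkn/N},   N = 2·f_s = 400,

and the band energies X_b = Σ_{k∈b} |X[k]|² are collected over
δ 1–4, θ 4–8, α 8–13, β 13–25, γ 25–55 Hz (below 1 Hz discarded, 60 Hz
line frequency excluded), giving one energy vector X_n ∈ ℝ⁵ per window.
From training seizures the pooled second-moment matrix

    C = (1/N_w) Σ_n X_n X_nᵀ

is formed — either over windows from the initial 5 s after onset or over
whole seizures — and its dominant eigenpair C e = λ e defines the feature
axis (e_i and e_w respectively; both entrywise nonnegative by
Perron–Frobenius).  Detection thresholds the projection u_n = e · X_n.

Calibration per feature: the threshold at a 5% false-positive window rate
(E_FP = 0.05) and the largest threshold still detecting within 2 s
(E_Lat = 2) are averaged per training seizure, and the operating threshold
Th₁ is the median across training seizures.  Evaluation reports false
positives (FP, % of non-seizure windows above threshold), false negatives
(FN, seizures not detected within 5 s), detection latency, and the
*stable threshold range* [E_FP, E_Lat] whose per-seizure width ranks the
features' robustness.

## Worked example

The bundled generator produces the default study — 100 annotated seizures
(10–60 s, beta-dominant onsets, theta-dominant late phases, 60 s
peri-ictal margins) plus 1.5 h of non-seizure EEG with interictal spikes,
60 Hz bursts, and movement artifacts:

```bash
seizurepca run-experiment --seed 1 --out report/
```

```
angle(e_i, e_w) = 57.4°
   delta: FP  3.26%  FN   0.0%  Lat  1.96 s  mean rank 5.46  firsts 1
   theta: FP  0.19%  FN   0.0%  Lat  2.28 s  mean rank 5.76  firsts 0
   alpha: FP  1.93%  FN   0.0%  Lat  2.30 s  mean rank 4.11  firsts 2
    beta: FP  2.15%  FN   2.0%  Lat  2.16 s  mean rank 2.05  firsts 13
   gamma: FP  1.41%  FN   2.0%  Lat  2.55 s  mean rank 6.08  firsts 0
     u_i: FP  2.15%  FN   0.0%  Lat  2.16 s  mean rank 1.45  firsts 34
     u_w: FP  0.81%  FN   0.0%  Lat  2.20 s  mean rank 3.09  firsts 0
```

Reading this: the initial-segment PCA feature u_i detects all 50 held-out
test seizures (FN 0%) with ~2 s latency at a held-out false-positive rate
of 2.15%, and its stable threshold range is the widest of the seven
features for 34 of 50 test seizures (mean rank 1.45).  The two trained
eigenvectors disagree by 57°: e_i loads on beta
(e ≈ [0.06, 0.10, 0.36, 0.90, 0.21]), e_w on theta — thresholding along
the *onset* energy direction is what buys the early detection.  The
command also writes `performance_grid.csv` (7 features × 7 threshold
scales), `rank_summary.csv`, `first_rank_counts.csv`, the two model JSONs,
and `sample_size_sweep.csv` (eigenvector mean ± sd for training sets of
10/20/30/50 seizures).

Other commands: `seizurepca simulate` (write the synthetic dataset as EDF +
annotation CSVs), `extract` (band-energy series → CSV), `train` (fit a
model JSON from annotated clips), `detect` (threshold a recording with a
trained model).

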