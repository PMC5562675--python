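# Methods

## Signal model and feature definition

The detector operates on one EEG channel sampled at f_s = 200 Hz.  Each
analysis window holds N = 400 samples (2 s); windows advance by 1 s, so
consecutive windows overlap by half.  Window timing is 0-based and
half-open: a window "at" t covers [t, t + 2) s, and its energy is
attributed to the window *end* — causally, a window's content is only
known once it completes, so detection times and latencies are quoted at
window ends.

Within a window the signal is first-difference filtered,
y(n) = x(n+1) − x(n).  EEG magnitude falls roughly as 1/f, and the
difference filter (amplitude gain 2·sin(πf/f_s)) flattens that tilt so
higher-frequency ictal activity is not swamped by low-frequency power.
The N−1 differences are zero-padded back to N points, keeping the DFT bin
grid at k·f_s/N = 0.5 Hz so the band edges fall exactly on bins.  The DFT
is unnormalized and untapered (rectangular window), and band energies sum
|X[k]|² over one-sided bins only, without the one-sided factor of two —
only relative comparisons between bands and across time matter, so
constant factors are irrelevant.  Numerical bookkeeping is guarded by two
invariants tested in the suite: Parseval's identity
Σ_k |X[k]|² = N·Σ_n y(n)² to 1e-6 relative, and agreement of the FFT path
with a direct O(N²) DFT-summation oracle to 1e-9 relative.  Zero-padding
truncation costs O(1/N) ≈ 0.3% of the energy as out-of-band leakage; this
is accepted (and asserted) rather than hidden by tapering.

Bands: δ 1–4, θ 4–8, α 8–13, β 13–25, γ 25–55 Hz.  Bins below 1 Hz are
discarded (electrode drift/offset); the γ band stops at 55 Hz, inclusive,
so that 60 Hz line interference never enters any band.  Shared interior
edges belong to the upper band; the cover is disjoint.

## Eigenfeature training

The five band energies of window n form X_n ∈ ℝ⁵ (nonnegative).  Over all
qualifying windows of all training seizures the pooled, *uncentered*
second-moment matrix C = (1/N_w) Σ X_n X_nᵀ is accumulated, and its
dominant eigenpair C e = λ e is the trained feature.  Uncentered is
deliberate: the energy vectors sit far from the origin, and the object of
interest is the principal *energy direction* of ictal activity, not the
principal variance direction; an optional centering flag exists for
sensitivity studies only.  Two segment modes are trained:

* `initial_5s` — windows fully inside [onset, onset + 5 s] (4 windows per
  seizure at the defaults) → e_i;
* `whole` — windows fully inside [onset, offset] → e_w.

Partial windows straddling a segment edge are dropped.  Pooling is over
windows, not per-seizure averages of C, so longer seizures contribute
more windows to e_w; this matches the summation-over-training-seizures
formulation and is flagged as a convention rather than a finding.

Since C is entrywise nonnegative, Perron–Frobenius guarantees an
entrywise-nonnegative dominant eigenvector; the implementation orients
the eigh output so the largest-magnitude component is positive and
asserts min(e) ≥ −1e-10.  Exact eigenvalue ties (within 1e-10 relative)
are resolved deterministically toward the lowest index, with a warning.
The detection feature is the projection u_n = e · X_n; single-band
comparator features are the corresponding components of X_n (equivalently
projections onto one-hot axes).  Angles between feature axes are reported
sign-free, min(θ, 180° − θ).

## Threshold calibration and metrology

Detection: the first window at/after the search start whose u_n ≥
threshold fires; latency = max(0, window end − onset); a seizure not
detected within 5 s of onset is a false negative.  FP counts non-seizure
windows with u_n strictly above threshold (strict `>` for counting, `≥`
for detection fixes boundary behavior at exactly-threshold values).
Mean latency averages non-FN seizures only; FN seizures appear in FN%,
not in latency.

Per training seizure, two solvers bracket the useful threshold interval:

* E_FP = 0.05: the smallest *observed* feature value whose FP rate is
  ≤ 5%.  The search runs over the sorted observed values (an exact order
  statistic), never a continuous grid, so it is deterministic and
  brute-force verifiable.
* E_Lat = 2: the largest threshold still detecting within 2 s, i.e. the
  max of u_n over windows ending in (onset, onset + 2].

The candidate threshold is their arithmetic mean; the operating threshold
Th₁ is the median candidate over training seizures (mean of the central
two for even counts).  Performance is then swept at
{0.2, 0.5, 0.8, 1.0, 1.2, 1.5, 2.0} × Th₁.  FP is provably nonincreasing
and per-seizure latency/FN nondecreasing along the sweep, and the suite
asserts exactly that; note the *mean* latency over non-FN seizures may
legitimately dip when a slow seizure crosses the 5 s cutoff and leaves
the latency pool, so monotonicity is asserted per seizure.

The gap between the two solver outputs, clamped at zero, is the stable
threshold range: the noise margin within which the feature simultaneously
meets the FP and latency targets.  Ranges are ranked per test seizure
(rank 1 = widest, ties averaged; every member of a tie at the top counts
as a first rank) and summarized as mean ± sd and first-rank counts.
Widths are compared in raw feature units.  A scale-free alternative
(widths normalized by each feature's Th₁) was considered and rejected: it
systematically favors whichever band has the smallest background energy
after the difference filter (δ here), rewarding an artifact of the
background spectrum rather than detection robustness.  Raw widths carry
their own caveat — features living on larger energy scales are favored —
which is inherent to this ranking style and is stated rather than
patched.

Non-seizure data is split in half by windows: the first half feeds the
E_FP solver during calibration, and all reported FP rates come from the
held-out second half, so the FP target is never graded on the windows
that set it.

## Synthetic study conditions

The generator emulates chronic rodent epidural EEG at 200 Hz:

* **Background**: 1/f-shaped Gaussian noise (log–log PSD slope −1 over
  2–50 Hz, verified by periodogram regression), rms 25 µV, plus a 3 µV
  white sensor floor.
* **Seizures**: 100 events, durations uniform over whole seconds 10–60 s,
  each clipped with 60 s pre/post margins.  A seizure is a sum of five
  band-limited noise oscillations (4th-order Butterworth-filtered white
  noise per band) under smooth envelopes: a 1 s half-cosine build-up, an
  onset phase (5 s) with band-energy weights
  {β 1.0, α 0.6, δ 0.3, θ 0.3, γ 0.2}, a 2 s cross-fade, then a late
  phase with {θ 1.0, β 0.6, α 0.4, γ 0.35, δ 0.3} — beta-dominant onset,
  theta-dominant (beta still strong) late course.  Weights are specified
  on the *measured* energy scale: each band's waveform amplitude is
  divided by the difference-filter gain at band center, so the weights
  set the post-filter band-energy shares that the analysis pipeline
  actually sees.  Without this compensation the filter's ~40× power-gain
  advantage of γ over θ would make the late phase gamma-dominant no
  matter what the weights say.  Overall ictal scale: 150 µV nominal rms.
  Seizure-to-seizure variability is lognormal jitter on each band's log
  energy (sd 0.25) and on the overall log energy (sd 0.2).
* **Artifacts** (non-seizure record only): biphasic interictal spikes
  (8/min, 60 ms, 350 µV — prominent spikes are ubiquitous in chronically
  epileptic rodents and are the main false-positive hazard for
  beta-weighted features), Hann-tapered 60 Hz bursts (1/min, 1 s, 30 µV),
  and slow movement transients (1.5/min, 1.5 s, 300 µV, 0.5–3 Hz).
* **Non-seizure record**: 1.5 h, generated independently of all clips —
  the stand-in for interictal data taken at least 1 h from any seizure.

All randomness descends from a single root seed through spawned NumPy
seed sequences (one stream per clip, one for the non-seizure record, one
for seizure-level draws), making every sample, file, and report
bit-reproducible; the suite asserts byte-identical report CSVs across two
independent runs.

What the generator does *not* model: spatial structure across channels
(the pipeline is single-channel by design), postictal suppression,
evolving spike morphology, amplifier saturation dynamics, state-dependent
background (sleep/wake), or any biophysics of the pilocarpine model.
Passing tests therefore demonstrate that the pipeline recovers the
structure the generator plants — beta-dominant onsets separable from
background along a trained energy direction — not that it would achieve
the same FP/FN/latency on real recordings.

One structural consequence is worth stating plainly: because *every*
synthetic onset is beta-dominant by construction, the single beta-band
feature is nearly as strong as u_i here, and its raw stable range
outranks u_w's (which projects a beta-dominant onset onto a theta-heavy
axis).  In real data, onset spectra vary more across seizures, which is
precisely what favors trained multi-band combinations over any fixed
single band; the generator's uniformity understates that advantage for
u_w while leaving u_i's top rank, zero FN, and the e_i/e_w contrast
intact.

## Default experiment

100 seizures split 50/50 train/test uniformly at random (seeded); e_i and
e_w trained on the 50 training seizures; each of the seven features
calibrated to its own Th₁ (features live on different scales); evaluation
on the 50 test seizures and the held-out non-seizure half across the
seven threshold scales; stable-range ranks over test seizures; and a
training-set-size sweep refitting the eigenvectors on 20 random subsets
(without replacement) of 10/20/30/50 training seizures, reporting
component-wise mean ± sd — the sd shrinks with size, reaching exactly
zero at the full pool.  The full default run (simulation included)
completes in a few seconds; problem sizes were chosen to mirror the study
design (100 events, 1.5 h FP data) rather than for speed.

## I/O conventions

Recordings travel as plain 16-bit EDF (1 s data records; physical range
±1000 µV, a typical rodent epidural scale with headroom — out-of-range
samples saturate with a warning, as a real amplifier would) or as CSV
with a time/index column; annotations as `onset_s,offset_s,label` CSV
sidecars.  Annotation times are real-valued seconds converted to sample
indices by rounding down; onset marks are visual-precision, so sub-sample
precision is meaningless.  Recordings whose length is not a whole number
of seconds are zero-padded to the next full EDF record on write.
Multichannel recordings require an explicit channel choice at the CLI;
the analysis path is single-channel.
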