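"""Seeded synthetic annotated-EEG generator.

Emulates the statistical structure the subband-PCA detector assumes, so
every pipeline stage is testable without animal recordings:

* 200 Hz single-channel epidural-style EEG;
* 1/f background (log–log spectral slope ≈ −1 over 2–50 Hz) plus a small
  white sensor-noise floor;
* seizures ≥ 10 s whose initial ~5 s are beta-band dominant and whose late
  phase is dominated by theta (with beta still strong), each realized as a
  sum of band-limited noise oscillations with smooth phase envelopes;
* three non-seizure artifact classes at Poisson times: biphasic interictal
  spikes, 60 Hz line bursts, and slow high-amplitude movement transients;
* peri-ictal clips with 60 s margins and a dedicated long non-seizure
  record (default 1.5 h) kept well clear of any seizure.

Band weights are specified on the *measured* energy scale — the scale on
which the analysis pipeline reports band energies after its
first-difference filter.  The filter's power gain 4·sin²(πf/fs) rises
steeply with frequency, so the generator divides each band's waveform
amplitude by the gain at band center; the configured weights then set the
relative post-filter band-energy magnitudes directly.  Seizure-to-seizure
variability enters as lognormal jitter on each band's energy and on the
overall seizure energy.

All randomness flows from one root seed through spawned NumPy seed
sequences (one child stream per clip, one for the non-seizure record, one
for seizure-level draws), so every sample is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .data_io import (AnnotatedDataset, AnnotatedRecord, Recording,
                      SeizureAnnotation)
from .subband import DEFAULT_BANDS, BandDefinition

__all__ = [
    "SeizureProfile",
    "ArtifactSpec",
    "SimulationConfig",
    "difference_filter_gain",
    "simulate_background",
    "simulate_seizure",
    "inject_artifacts",
    "simulate_dataset",
]

#: Onset-phase band weights (measured-energy scale): beta-dominant build-up.
ONSET_WEIGHTS = {"delta": 0.3, "theta": 0.3, "alpha": 0.6, "beta": 1.0,
                 "gamma": 0.2}
#: Late-phase weights: theta maximal with beta still prominent.
LATE_WEIGHTS = {"delta": 0.3, "theta": 1.0, "alpha": 0.4, "beta": 0.6,
                "gamma": 0.35}


@dataclass
class SeizureProfile:
    """Band-energy dynamics of one simulated seizure."""

    duration_s: float = 30.0
    onset_phase_len_s: float = 5.0
    ramp_s: float = 1.0           # half-cosine build-up at onset
    blend_s: float = 2.0          # onset→late cross-fade
    onset_weights: dict[str, float] = field(
        default_factory=lambda: dict(ONSET_WEIGHTS))
    late_weights: dict[str, float] = field(
        default_factory=lambda: dict(LATE_WEIGHTS))

    def __post_init__(self) -> None:
        if self.duration_s < self.onset_phase_len_s:
            raise ValueError("seizure shorter than its onset phase")
        for w in (self.onset_weights, self.late_weights):
            if any(v < 0 for v in w.values()):
                raise ValueError("band weights must be nonnegative")


@dataclass
class ArtifactSpec:
    """Non-seizure artifact classes (rates per minute)."""

    spike_rate_per_min: float = 8.0
    spike_width_ms: float = 60.0
    spike_amplitude_uv: float = 350.0
    line_burst_rate_per_min: float = 1.0
    line_burst_duration_s: float = 1.0
    line_burst_amplitude_uv: float = 30.0
    line_freq_hz: float = 60.0
    movement_rate_per_min: float = 1.5
    movement_duration_s: float = 1.5
    movement_amplitude_uv: float = 300.0
    movement_freq_range_hz: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        for r in (self.spike_rate_per_min, self.line_burst_rate_per_min,
                  self.movement_rate_per_min):
            if r < 0:
                raise ValueError("artifact rates must be nonnegative")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    fs: float = 200.0
    n_seizures: int = 100
    nonseizure_duration_s: float = 5400.0   # 1.5 h of FP-test data
    pre_s: float = 60.0
    post_s: float = 60.0
    interictal_gap_s: float = 3600.0        # non-seizure data ≥ 1 h from seizures
    background_rms_uv: float = 25.0
    white_noise_sd_uv: float = 3.0
    seizure_rms_uv: float = 150.0
    duration_range_s: tuple[int, int] = (10, 60)
    band_jitter_sd: float = 0.25            # lognormal sd of per-band log energy
    amplitude_jitter_sd: float = 0.2        # lognormal sd of overall log energy
    profile: SeizureProfile = field(default_factory=SeizureProfile)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)

    def to_dict(self) -> dict:
        return asdict(self)


def difference_filter_gain(freq_hz: float | np.ndarray, fs: float) -> np.ndarray:
    """Amplitude gain |1 − e^{−j2πf/fs}| = 2·sin(πf/fs) of the first
    difference."""
    return 2.0 * np.sin(np.pi * np.asarray(freq_hz, dtype=float) / fs)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_background(duration_s: float, fs: float = 200.0,
                        rms_uv: float = 25.0, white_sd_uv: float = 3.0,
                        seed=0) -> Recording:
    """1/f-shaped background noise plus a white sensor floor.

    Shaping is spectral: white Gaussian noise is filtered in the frequency
    domain with amplitude ∝ f^{-1/2} (power ∝ 1/f) above 1 Hz, flat below,
    then rescaled to the requested rms.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * shape, n)
    pink *= rms_uv / max(pink.std(), np.finfo(float).tiny)
    x = pink + white_sd_uv * rng.standard_normal(n)
    return Recording(x[None, :], fs, ["EEG1"])


def _narrowband(n: int, fs: float, band: BandDefinition,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-rms band-limited Gaussian noise (4th-order Butterworth)."""
    sos = sps.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    # pad so filter transients do not bias the usable segment
    pad = int(4 * fs)
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    return x / max(x.std(), np.finfo(float).tiny)


def _phase_envelopes(n: int, fs: float, profile: SeizureProfile
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Onset/late amplitude envelopes in [0, 1] (smooth ramp + cross-fade)."""
    t = np.arange(n) / fs
    ramp = np.clip(t / max(profile.ramp_s, 1e-9), 0.0, 1.0)
    ramp = 0.5 * (1 - np.cos(np.pi * ramp))  # half-cosine rise
    xfade = np.clip((t - profile.onset_phase_len_s) / max(profile.blend_s, 1e-9),
                    0.0, 1.0)
    xfade = 0.5 * (1 - np.cos(np.pi * xfade))
    fade_out = np.clip((profile.duration_s - t) / 1.0, 0.0, 1.0)
    onset_env = ramp * (1.0 - xfade) * fade_out
    late_env = ramp * xfade * fade_out
    return onset_env, late_env


def simulate_seizure(profile: SeizureProfile, fs: float = 200.0, seed=0,
                     seizure_rms_uv: float = 150.0,
                     bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
                     ) -> tuple[np.ndarray, SeizureAnnotation]:
    """One seizure burst as a sum of enveloped band-limited oscillations.

    Returns the samples (µV) and an annotation spanning the burst.  Band
    amplitudes are gain-compensated so that the configured weights govern
    the band energies *as measured by the analysis pipeline* (after its
    difference filter); the overall scale is set so a nominal onset-phase
    waveform has rms ``seizure_rms_uv``.
    """
    rng = _rng(seed)
    n = int(round(profile.duration_s * fs))
    onset_env, late_env = _phase_envelopes(n, fs, profile)
    comp = {}
    amp_on, amp_late = {}, {}
    for b in bands:
        gain = float(difference_filter_gain(b.center_hz, fs))
        comp[b.name] = _narrowband(n, fs, b, rng)
        amp_on[b.name] = profile.onset_weights.get(b.name, 0.0) / gain
        amp_late[b.name] = profile.late_weights.get(b.name, 0.0) / gain
    nominal_rms = np.sqrt(sum(a * a for a in amp_on.values()))
    scale = seizure_rms_uv / max(nominal_rms, np.finfo(float).tiny)
    x = np.zeros(n)
    for b in bands:
        env = amp_on[b.name] * onset_env + amp_late[b.name] * late_env
        x += scale * env * comp[b.name]
    return x, SeizureAnnotation(0.0, profile.duration_s)


def _add_event(x: np.ndarray, waveform: np.ndarray, center_idx: int) -> None:
    half = waveform.size // 2
    lo = center_idx - half
    hi = lo + waveform.size
    wlo = max(0, -lo)
    whi = waveform.size - max(0, hi - x.size)
    if whi <= wlo:
        return
    x[max(0, lo):min(x.size, hi)] += waveform[wlo:whi]


def inject_artifacts(rec: Recording, spec: ArtifactSpec, seed=0) -> Recording:
    """Add spikes, line bursts, and movement transients at Poisson times.

    Returns a new Recording; the input is untouched.  All channels receive
    the same artifacts (a single generator source).
    """
    rng = _rng(seed)
    fs = rec.fs
    dur_min = rec.duration_s / 60.0
    data = rec.data.copy()

    def poisson_times(rate_per_min):
        k = rng.poisson(rate_per_min * dur_min)
        return np.sort(rng.uniform(0, rec.duration_s, size=k))

    # interictal spikes: biphasic derivative-of-Gaussian transients
    w = spec.spike_width_ms / 1000.0
    tt = np.arange(-int(w * fs) // 1, int(w * fs)) / fs
    sigma = w / 4.0
    spike = -tt * np.exp(-tt**2 / (2 * sigma**2))
    spike *= spec.spike_amplitude_uv / max(np.abs(spike).max(), 1e-12)
    for t in poisson_times(spec.spike_rate_per_min):
        polarity = rng.choice([-1.0, 1.0])
        for ch in data:
            _add_event(ch, polarity * spike, int(t * fs))

    # 60 Hz line bursts, Hann-tapered
    nb = int(spec.line_burst_duration_s * fs)
    tb = np.arange(nb) / fs
    for t in poisson_times(spec.line_burst_rate_per_min):
        phase = rng.uniform(0, 2 * np.pi)
        burst = (spec.line_burst_amplitude_uv * np.hanning(nb)
                 * np.sin(2 * np.pi * spec.line_freq_hz * tb + phase))
        for ch in data:
            _add_event(ch, burst, int(t * fs))

    # slow high-amplitude movement transients (0.5–3 Hz)
    nm = int(spec.movement_duration_s * fs)
    tm = np.arange(nm) / fs - spec.movement_duration_s / 2
    for t in poisson_times(spec.movement_rate_per_min):
        f = rng.uniform(*spec.movement_freq_range_hz)
        phase = rng.uniform(0, 2 * np.pi)
        env = np.exp(-tm**2 / (2 * (spec.movement_duration_s / 5) ** 2))
        wave = spec.movement_amplitude_uv * env * np.sin(2 * np.pi * f * tm + phase)
        for ch in data:
            _add_event(ch, wave, int(t * fs))

    return Recording(data, fs, list(rec.channel_labels), rec.start_time_s)


def simulate_dataset(cfg: SimulationConfig) -> AnnotatedDataset:
    """Full study dataset: peri-ictal clips plus a non-seizure record.

    Each of ``cfg.n_seizures`` clips is ``pre_s + duration + post_s`` long
    with the seizure annotated at clip-local ``[pre_s, pre_s + duration]``;
    durations are whole seconds drawn uniformly from ``duration_range_s``.
    The non-seizure record (background + artifacts, no annotations) is
    generated independently, standing in for interictal data taken at
    least ``interictal_gap_s`` away from any seizure.
    """
    if cfg.n_seizures < 1:
        raise ValueError("need at least one seizure")
    ss = np.random.SeedSequence(cfg.seed)
    meta_ss, nonseiz_ss, *clip_ss = ss.spawn(cfg.n_seizures + 2)
    meta = np.random.default_rng(meta_ss)

    lo, hi = cfg.duration_range_s
    durations = meta.integers(lo, hi + 1, size=cfg.n_seizures)
    band_names = [b.name for b in DEFAULT_BANDS]
    # lognormal jitter on log band energy → factor exp(N/2) on amplitude weight
    band_jit = np.exp(meta.normal(0.0, cfg.band_jitter_sd,
                                  size=(cfg.n_seizures, len(band_names))) / 2)
    amp_jit = np.exp(meta.normal(0.0, cfg.amplitude_jitter_sd,
                                 size=cfg.n_seizures) / 2)

    records: list[AnnotatedRecord] = []
    for i in range(cfg.n_seizures):
        child = clip_ss[i].spawn(2)
        dur = float(durations[i])
        clip_len = cfg.pre_s + dur + cfg.post_s
        bg = simulate_background(clip_len, cfg.fs, cfg.background_rms_uv,
                                 cfg.white_noise_sd_uv, np.random.default_rng(child[0]))
        prof = SeizureProfile(
            duration_s=dur,
            onset_phase_len_s=cfg.profile.onset_phase_len_s,
            ramp_s=cfg.profile.ramp_s,
            blend_s=cfg.profile.blend_s,
            onset_weights={b: cfg.profile.onset_weights.get(b, 0.0) * band_jit[i, j]
                           for j, b in enumerate(band_names)},
            late_weights={b: cfg.profile.late_weights.get(b, 0.0) * band_jit[i, j]
                          for j, b in enumerate(band_names)},
        )
        burst, _ = simulate_seizure(prof, cfg.fs,
                                    np.random.default_rng(child[1]),
                                    cfg.seizure_rms_uv * amp_jit[i])
        x = bg.channel(0).copy()
        i0 = int(round(cfg.pre_s * cfg.fs))
        x[i0:i0 + burst.size] += burst
        rec = Recording(x[None, :], cfg.fs, ["EEG1"])
        ann = SeizureAnnotation(cfg.pre_s, cfg.pre_s + dur, f"seizure_{i:03d}")
        records.append(AnnotatedRecord(rec, [ann]))

    child = nonseiz_ss.spawn(2)
    bg = simulate_background(cfg.nonseizure_duration_s, cfg.fs,
                             cfg.background_rms_uv, cfg.white_noise_sd_uv,
                             np.random.default_rng(child[0]))
    nonseiz = inject_artifacts(bg, cfg.artifacts, np.random.default_rng(child[1]))
    records.append(AnnotatedRecord(nonseiz, []))
    return AnnotatedDataset(records)
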