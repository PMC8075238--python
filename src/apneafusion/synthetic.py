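"""Synthetic one-minute single-lead ECG segments, normal vs apnea-like.

The apneic archetype is the cyclic variation of heart rate (CVHR) that
accompanies obstructive events: bradycardia while the airway is blocked
followed by tachycardia when breathing resumes, with respiratory amplitude
modulation suppressed. Normal minutes keep a near-constant heart rate with
beat-to-beat jitter and visible respiratory modulation. Beats are stylized
piecewise-Gaussian P-QRS-T templates; baseline wander and white noise are
added on top, and every generated component is stored so the emitted
samples decompose exactly into clean + wander + noise.

The morphology is deliberately schematic: the aim is spectral separability
of the two rhythm classes, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import APNEA, NORMAL, ECGRecord, Segment, write_record

#: (amplitude rel. R, center offset s, width s) for the P, Q, R, S, T waves
_WAVES = (
    (0.12, -0.17, 0.025),
    (-0.10, -0.02, 0.008),
    (1.00, 0.00, 0.012),
    (-0.15, 0.02, 0.008),
    (0.25, 0.25, 0.045),
)


@dataclass
class SynthConfig:
    """Generator parameters (rates in bpm, amplitudes in mV, times in s)."""

    fs: float = 100.0
    normal_hr: float = 60.0
    hr_jitter_sd: float = 2.0
    brady_hr: float = 45.0
    brady_duration: float = 30.0
    tachy_hr: float = 90.0
    qrs_amplitude: float = 1.0
    resp_mod_depth_normal: float = 0.15
    resp_mod_depth_apnea: float = 0.03
    resp_freq: float = 0.3
    wander_amplitude: float = 0.1
    wander_freq: float = 0.25
    noise_sd: float = 0.02
    adc_gain: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs", "normal_hr", "brady_hr", "tachy_hr", "qrs_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.brady_duration < 60:
            raise ValueError("brady_duration must lie in (0, 60) s")
        if self.noise_sd < 0 or self.wander_amplitude < 0:
            raise ValueError("noise_sd and wander_amplitude must be nonnegative")


@dataclass
class SynthSegment:
    """A generated segment plus its ground truth.

    ``segment.samples == clean + wander + noise`` exactly.
    """

    segment: Segment
    clean: np.ndarray
    wander: np.ndarray
    noise: np.ndarray
    beat_times: np.ndarray

    @property
    def label(self) -> str:
        return self.segment.label


def _beat_times(label: str, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = float(rng.uniform(0.05, 0.4))
    while t < 60.0:
        if label == NORMAL:
            hr = config.normal_hr
        else:
            hr = config.brady_hr if t < config.brady_duration else config.tachy_hr
        hr = max(hr + rng.normal(0.0, config.hr_jitter_sd), 20.0)
        times.append(t)
        t += 60.0 / hr
    return np.array(times)


def gen_segment(
    label: str, config: SynthConfig | None = None, seed: int | None = None
) -> SynthSegment:
    """Generate one labeled minute of synthetic ECG.

    ``seed`` overrides ``config.seed`` (used for per-item seeding in
    datasets). Identical label/config/seed give identical samples.
    """
    config = config or SynthConfig()
    if label not in (NORMAL, APNEA):
        raise ValueError(f"label must be {NORMAL!r} or {APNEA!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(60 * config.fs))
    t = np.arange(n) / config.fs

    beats = _beat_times(label, config, rng)
    depth = config.resp_mod_depth_normal if label == NORMAL else config.resp_mod_depth_apnea
    resp_phase = rng.uniform(0, 2 * np.pi)
    clean = np.zeros(n)
    for tb in beats:
        amp = config.qrs_amplitude * (
            1.0 + depth * np.sin(2 * np.pi * config.resp_freq * tb + resp_phase)
        )
        for rel_amp, offset, width in _WAVES:
            center = tb + offset
            lo = max(int((center - 5 * width) * config.fs), 0)
            hi = min(int((center + 5 * width) * config.fs) + 1, n)
            if lo < hi:
                tt = t[lo:hi] - center
                clean[lo:hi] += amp * rel_amp * np.exp(-0.5 * (tt / width) ** 2)

    wander_phase = rng.uniform(0, 2 * np.pi)
    wander = config.wander_amplitude * np.sin(2 * np.pi * config.wander_freq * t + wander_phase)
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)

    # emulate the recorder's 16-bit digitization so that disk round-trips are
    # exact; the quantization residual is charged to the noise component to
    # keep the clean + wander + noise decomposition identity intact
    raw = clean + wander + noise
    quantized = np.round(raw * config.adc_gain) / config.adc_gain
    noise = noise + (quantized - raw)

    seg = Segment(
        samples=quantized,
        label=label,
        record_id="synthetic",
        minute_index=0,
        sampling_rate=config.fs,
    )
    return SynthSegment(segment=seg, clean=clean, wander=wander, noise=noise, beat_times=beats)


def gen_dataset(
    n_per_class: int, config: SynthConfig | None = None
) -> tuple[list[SynthSegment], list[dict]]:
    """Balanced labeled set with per-item seeds derived from the master seed.

    Returns the segments and a manifest (one dict per segment with the
    label and the child seed used); labels alternate N, A, N, A, ... so
    fixture records written from consecutive segments mix both classes.
    """
    config = config or SynthConfig()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_per_class)]
    segments: list[SynthSegment] = []
    manifest: list[dict] = []
    for i, label in enumerate([NORMAL, APNEA] * n_per_class):
        seg = gen_segment(label, config, seed=child_seeds[i])
        seg.segment.minute_index = i
        segments.append(seg)
        manifest.append({"index": i, "label": label, "seed": child_seeds[i]})
    return segments, manifest


def write_dataset(
    segments: list[SynthSegment],
    directory: str | Path,
    minutes_per_record: int = 10,
    record_prefix: str = "syn",
    gain: float = 200.0,
) -> list[Path]:
    """Write segments as WFDB-style fixture records readable by ``io.read_record``.

    Consecutive segments are concatenated into records of
    ``minutes_per_record`` minutes with matching per-minute annotations.
    """
    directory = Path(directory)
    paths = []
    for r, start in enumerate(range(0, len(segments), minutes_per_record)):
        chunk = segments[start : start + minutes_per_record]
        record = ECGRecord(
            record_id=f"{record_prefix}{r:03d}",
            sampling_rate=chunk[0].segment.sampling_rate,
            samples=np.concatenate([s.segment.samples for s in chunk]),
            minute_labels=[s.label for s in chunk],
        )
        paths.append(write_record(record, directory, gain=gain))
    return paths
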