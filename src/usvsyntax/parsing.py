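"""Spectrogram-based USV detection.

A deliberately simple, noise-robust parser: the short-time power spectrum
is computed, the per-bin noise floor is taken as the median frame power
over the whole file (robust because vocalizations are temporally sparse),
and frames whose in-band power exceeds the floor by a dB threshold are
merged into candidate syllables.  Events closer than ``merge_gap`` are
merged and events shorter than ``min_duration`` are dropped.  Boundaries
are reported at hop resolution.

Per-syllable pitch features come from the per-frame peak frequency inside
the band: the mean of the track is the syllable's mean frequency, and a
pitch jump is counted wherever the track moves by more than
``jump_threshold`` between consecutive frames (direction = sign of the
move).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .corpus import Syllable


@dataclass(frozen=True)
class ParserConfig:
    fs: int = 250_000
    fft_size: int = 256
    hop: int | None = None          # defaults to fft_size // 2
    band: tuple[float, float] = (25_000.0, 110_000.0)
    threshold_db: float = 10.0
    min_duration: float = 0.005
    merge_gap: float = 0.010
    jump_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.band[0] < self.band[1] <= self.fs / 2):
            raise ValueError(f"band {self.band} must lie within [0, fs/2]")
        if self.threshold_db <= 0 or self.min_duration <= 0:
            raise ValueError("threshold_db and min_duration must be positive")
        if self.min_duration <= self.hop_samples / self.fs:
            raise ValueError("min_duration must exceed one hop")

    @property
    def hop_samples(self) -> int:
        return self.hop if self.hop is not None else self.fft_size // 2


def _spectrogram(waveform: np.ndarray, config: ParserConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    freqs, times, spec = signal.spectrogram(
        waveform,
        fs=config.fs,
        window="hann",
        nperseg=config.fft_size,
        noverlap=config.fft_size - config.hop_samples,
        mode="psd",
    )
    return freqs, times, spec


def parse_wav(waveform: np.ndarray, config: ParserConfig = ParserConfig()) -> list[Syllable]:
    """Detect syllables in a mono waveform sampled at ``config.fs``.

    Returns time-ordered, non-overlapping syllables with mean frequency
    and pitch-jump features filled in.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or waveform.size < config.fft_size:
        raise ValueError("waveform must be a mono array longer than one FFT frame")
    if np.allclose(waveform, waveform.flat[0]):
        raise ValueError("waveform is constant (empty or clipped recording)")
    freqs, times, spec = _spectrogram(waveform, config)
    in_band = (freqs >= config.band[0]) & (freqs <= config.band[1])
    band_power = spec[in_band].sum(axis=0)
    floor = np.median(spec[in_band], axis=1).sum()
    active = band_power > floor * 10 ** (config.threshold_db / 10.0)

    hop_s = config.hop_samples / config.fs
    events: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            events.append((start, i))
            start = None
    if start is not None:
        events.append((start, len(active)))

    # merge events separated by less than merge_gap
    merged: list[tuple[int, int]] = []
    for ev in events:
        if merged and (times[ev[0]] - times[merged[-1][1] - 1]) < config.merge_gap:
            merged[-1] = (merged[-1][0], ev[1])
        else:
            merged.append(ev)

    syllables = []
    band_freqs = freqs[in_band]
    band_spec = spec[in_band]
    for i0, i1 in merged:
        t0 = times[i0] - hop_s / 2
        t1 = times[i1 - 1] + hop_s / 2
        if t1 - t0 < config.min_duration:
            continue
        mean_f, n_jumps, dirs = _pitch_track(band_spec[:, i0:i1], band_freqs, config)
        syllables.append(
            Syllable(
                start_time=max(t0, 0.0),
                end_time=t1,
                mean_frequency=mean_f,
                jump_count=n_jumps,
                jump_directions=dirs,
            )
        )
    return syllables


def _pitch_track(
    seg_spec: np.ndarray, band_freqs: np.ndarray, config: ParserConfig
) -> tuple[float, int, tuple[str, ...]]:
    peaks = band_freqs[np.argmax(seg_spec, axis=0)]
    steps = np.diff(peaks)
    jump_idx = np.nonzero(np.abs(steps) > config.jump_threshold)[0]
    dirs = tuple("up" if steps[i] > 0 else "down" for i in jump_idx)
    return float(peaks.mean()), len(jump_idx), dirs


def extract_pitch_features(
    segment: np.ndarray, config: ParserConfig = ParserConfig()
) -> tuple[float, int, tuple[str, ...]]:
    """Mean peak frequency and pitch jumps of one detected syllable.

    ``segment`` is the waveform slice of a single syllable; it must span
    at least two analysis frames.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < config.fft_size + config.hop_samples:
        raise ValueError("segment shorter than two analysis frames")
    freqs, _, spec = _spectrogram(segment, config)
    in_band = (freqs >= config.band[0]) & (freqs <= config.band[1])
    return _pitch_track(spec[in_band], freqs[in_band], config)


def read_wav(path: str | Path, expected_fs: int | None = None) -> tuple[int, np.ndarray]:
    """Load a mono PCM WAV as float; rejects a sampling-rate mismatch."""
    fs, data = wavfile.read(str(path))
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"sampling rate {fs} != expected {expected_fs}")
    if data.ndim != 1:
        raise ValueError("expected a mono recording")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return fs, np.asarray(data, dtype=float)


def write_wav(path: str | Path, waveform: np.ndarray, fs: int = 250_000) -> None:
    """Write a waveform as 16-bit PCM, scaled to 90% full range."""
    w = np.asarray(waveform, dtype=float)
    peak = np.abs(w).max()
    if peak > 0:
        w = w / peak * 0.9
    wavfile.write(str(path), fs, (w * 32767).astype(np.int16))
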