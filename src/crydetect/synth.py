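"""Synthetic audio, sessions and perturbations.

Stands in for recordings at every pipeline stage: stylized infant-cry
audio (harmonic expiratory phrases with a rising-falling F0 contour
around 450 Hz, jitter, and pauses), spectrally distinct non-cry domestic
sounds, labeled monitoring sessions on the 5-s epoch grid, and the
perturbed "re-recordings" (attenuation, low-pass filtering, added
background) used for feature screening and robustness analysis.

All generators are pure functions of (parameters, seed): the same seed
yields bitwise-identical audio. The cry model is a source model, not a
resynthesis of real cries — it has the right gross spectro-temporal
structure (harmonic stack, F0 range, ~1 s phrases) while remaining fully
controllable and license-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .audio_io import DEFAULT_SAMPLE_RATE, AudioSignal
from .sequences import EpochLabelSeries

NONCRY_KINDS = ("white_noise", "pink_noise", "tone", "babble", "knock")


@dataclass(frozen=True)
class CryModel:
    """Source model of infant-cry acoustics.

    f0_base/f0_excursion give the rising-falling pitch contour per
    expiratory phrase (contour spans f0_base .. f0_base + excursion and
    back); jitter is multiplicative cycle-to-cycle F0 noise.
    """

    f0_base: float = 450.0
    f0_excursion: float = 100.0
    phrase_seconds: float = 1.0
    pause_seconds: float = 0.4
    harmonics: int = 8
    jitter: float = 0.02
    amplitude: float = 0.6

    def __post_init__(self) -> None:
        if self.f0_base - self.f0_excursion <= 0:
            raise ValueError("f0 contour must stay positive")
        if self.phrase_seconds <= 0 or self.pause_seconds <= 0:
            raise ValueError("phrase and pause durations must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """Layout of a labeled monitoring session on the epoch grid."""

    total_epochs: int
    cry_bouts: tuple[tuple[int, int], ...] = ()  # (start epoch, length)
    background: str = "white_noise"
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_epochs <= 0:
            raise ValueError("session needs at least one epoch")
        occupied = np.zeros(self.total_epochs, dtype=bool)
        for start, length in self.cry_bouts:
            if start < 0 or length <= 0 or start + length > self.total_epochs:
                raise ValueError(f"cry bout ({start}, {length}) outside session")
            if occupied[start : start + length].any():
                raise ValueError("cry bouts overlap")
            occupied[start : start + length] = True

    @property
    def labels(self) -> np.ndarray:
        lab = np.zeros(self.total_epochs, dtype=np.int64)
        for start, length in self.cry_bouts:
            lab[start : start + length] = 1
        return lab


def _smooth_noise(n: int, rate: int, rng, cutoff_hz: float = 30.0) -> np.ndarray:
    """Unit-variance noise band-limited to slow modulations."""
    coarse_n = max(int(np.ceil(n * cutoff_hz / rate)) + 2, 4)
    coarse = rng.standard_normal(coarse_n)
    t = np.linspace(0.0, coarse_n - 1.0, n)
    x = np.interp(t, np.arange(coarse_n), coarse)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_cry(
    duration: float,
    model: CryModel = CryModel(),
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioSignal:
    """Generate stylized cry audio: voiced phrases separated by pauses."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * sample_rate))
    out = np.zeros(n_total)
    pos = 0
    while pos < n_total:
        phrase_len = int(round(model.phrase_seconds
                               * rng.uniform(0.85, 1.15) * sample_rate))
        phrase_len = min(phrase_len, n_total - pos)
        if phrase_len > sample_rate // 50:  # skip fragments below one F0 period
            tau = np.linspace(0.0, 1.0, phrase_len)
            f0 = model.f0_base + model.f0_excursion * np.sin(np.pi * tau)
            f0 = f0 * (1.0 + model.jitter
                       * _smooth_noise(phrase_len, sample_rate, rng))
            phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
            phrase = np.zeros(phrase_len)
            for k in range(1, model.harmonics + 1):
                phrase += np.sin(k * phase + rng.uniform(0, 2 * np.pi)) / k
            envelope = np.sin(np.pi * tau) ** 0.5  # rise-fall per phrase
            out[pos : pos + phrase_len] = phrase * envelope
        pos += phrase_len
        pos += int(round(model.pause_seconds * rng.uniform(0.85, 1.15) * sample_rate))
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= model.amplitude / peak
    return AudioSignal(samples=out, sample_rate=sample_rate)


def _pink_noise(n: int, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n=n)
    return x / np.max(np.abs(x))


def _babble(n: int, rate: int, rng) -> np.ndarray:
    """Speech-like alternation of weak voiced segments and noise."""
    out = np.zeros(n)
    pos = 0
    voiced = bool(rng.integers(0, 2))
    while pos < n:
        seg = int(rng.uniform(0.12, 0.25) * rate)
        seg = min(seg, n - pos)
        if voiced:
            f0 = rng.uniform(120.0, 250.0)
            t = np.arange(seg) / rate
            x = sum(np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)) / k
                    for k in range(1, 4))
            env = np.sin(np.pi * np.linspace(0, 1, seg))
            out[pos : pos + seg] = 0.5 * x * env
        else:
            out[pos : pos + seg] = 0.25 * rng.standard_normal(seg)
        voiced = not voiced
        pos += seg
    return out / max(np.max(np.abs(out)), 1e-9)


def _knock(n: int, rate: int, rng) -> np.ndarray:
    out = np.zeros(n)
    n_bursts = max(1, int(n / rate * rng.uniform(1.5, 3.0)))
    burst_len = int(0.03 * rate)
    decay = np.exp(-np.arange(burst_len) / (0.005 * rate))
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(1, n - burst_len)))
        out[start : start + burst_len] += decay * rng.standard_normal(burst_len)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def synth_noncry(
    kind: str,
    duration: float,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    freq: float | None = None,
) -> AudioSignal:
    """Generate one of the non-cry domestic sound kinds.

    ``freq`` fixes the tone frequency for kind "tone" (otherwise drawn
    uniformly from 100-1000 Hz).
    """
    if kind not in NONCRY_KINDS:
        raise ValueError(f"unknown non-cry kind {kind!r}; expected one of {NONCRY_KINDS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    if kind == "white_noise":
        x = 0.3 * rng.standard_normal(n)
        x = np.clip(x, -1.0, 1.0)
    elif kind == "pink_noise":
        x = 0.5 * _pink_noise(n, rng)
    elif kind == "tone":
        f = freq if freq is not None else rng.uniform(100.0, 1000.0)
        x = 0.4 * np.sin(2 * np.pi * f * np.arange(n) / sample_rate)
    elif kind == "babble":
        x = 0.5 * _babble(n, sample_rate, rng)
    else:  # knock
        x = 0.7 * _knock(n, sample_rate, rng)
    return AudioSignal(samples=x, sample_rate=sample_rate)


def synth_session(
    spec: SessionSpec,
    model: CryModel = CryModel(),
    epoch_seconds: float = 5.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> tuple[AudioSignal, EpochLabelSeries]:
    """Render a labeled session: continuous background with cry bouts mixed in.

    Cry bouts are mixed over the background at the spec's SNR; the label
    series marks exactly the bout epochs.
    """
    rng = np.random.default_rng(spec.seed)
    samples_per_epoch = int(round(epoch_seconds * sample_rate))
    n = spec.total_epochs * samples_per_epoch
    bg = synth_noncry(
        spec.background, spec.total_epochs * epoch_seconds,
        seed=int(rng.integers(0, 2**31)), sample_rate=sample_rate,
    ).samples.copy()
    bg_rms = np.sqrt(np.mean(bg**2))
    out = bg
    for start, length in spec.cry_bouts:
        cry = synth_cry(
            length * epoch_seconds, model=model,
            seed=int(rng.integers(0, 2**31)), sample_rate=sample_rate,
        ).samples
        cry_rms = np.sqrt(np.mean(cry**2))
        if cry_rms > 0 and bg_rms > 0:
            cry = cry * (bg_rms * 10.0 ** (spec.snr_db / 20.0) / cry_rms)
        a, b = start * samples_per_epoch, (start + length) * samples_per_epoch
        out[a:b] += cry
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return (
        AudioSignal(samples=out[:n], sample_rate=sample_rate),
        EpochLabelSeries(labels=spec.labels),
    )


def perturb(signal: AudioSignal, condition: dict, seed: int = 0) -> AudioSignal:
    """Emulate a degraded re-recording of the same audio.

    ``condition`` is one of
    ``{"attenuate_db": d}`` (amplitude scaled by 10^(-d/20)),
    ``{"lowpass_hz": f}`` (zero-phase Butterworth low-pass), or
    ``{"background": kind, "snr_db": s}`` (background mixed so that
    signal RMS is ``s`` dB above the added background).
    Duration and sample rate are preserved.
    """
    x = signal.samples
    if "attenuate_db" in condition:
        gain = 10.0 ** (-float(condition["attenuate_db"]) / 20.0)
        y = x * gain
    elif "lowpass_hz" in condition:
        cutoff = float(condition["lowpass_hz"])
        nyquist = signal.sample_rate / 2.0
        if not 0.0 < cutoff < nyquist:
            raise ValueError(f"lowpass cutoff {cutoff} Hz outside (0, {nyquist})")
        sos = butter(6, cutoff / nyquist, btype="low", output="sos")
        y = sosfiltfilt(sos, x)
    elif "background" in condition:
        snr_db = float(condition.get("snr_db", 10.0))
        bg = synth_noncry(
            condition["background"], signal.duration, seed=seed,
            sample_rate=signal.sample_rate,
        ).samples[: x.size]
        sig_rms = np.sqrt(np.mean(x**2))
        bg_rms = np.sqrt(np.mean(bg**2))
        if bg_rms > 0:
            bg = bg * (sig_rms * 10.0 ** (-snr_db / 20.0) / max(bg_rms, 1e-12))
        y = x + bg
    else:
        raise ValueError(
            f"unknown perturbation condition: {sorted(condition)} "
            "(expected attenuate_db, lowpass_hz, or background)"
        )
    peak = np.max(np.abs(y)) if y.size else 0.0
    if peak > 1.0:
        y = y / peak
    return AudioSignal(samples=y, sample_rate=signal.sample_rate)


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write 16-bit PCM WAV at the signal's rate (round-trips via load_wav)."""
    x = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, pcm)


def condition_label(condition: dict) -> str:
    if "attenuate_db" in condition:
        return f"attenuate_{condition['attenuate_db']:g}dB"
    if "lowpass_hz" in condition:
        return f"lowpass_{condition['lowpass_hz']:g}Hz"
    if "background" in condition:
        return f"bg_{condition['background']}_snr{condition.get('snr_db', 10.0):g}dB"
    return "unknown"
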