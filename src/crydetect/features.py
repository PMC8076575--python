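"""Frame-level acoustic descriptors and per-epoch statistical functionals.

Each 5-s epoch is framed (25 ms window, 10 ms hop, Hamming) and a set of
low-level descriptors (LLDs) is computed per frame:

* MFCC coefficients 1-12 (from a 26-band mel filterbank, 20-8000 Hz),
* the 26 log mel-band energies themselves,
* RMS energy and zero-crossing rate,
* fundamental frequency F0 (Hz; 0 when unvoiced) and voicing probability
  (peak of the normalized autocorrelation in the 75-600 Hz lag band).

Every LLD's frame series is then summarized by 13 statistical functionals
(mean, SD, min, max, range, percentiles 1/25/50/75/99, IQR, skewness,
kurtosis), giving a fixed 42 x 13 = 546-dimensional named feature vector
per epoch. The registry of names is the contract shared by screening,
training and prediction.

Conventions fixed for reproducibility: population (ddof=0) standard
deviation; type-7 (linear interpolation) percentiles; skewness/kurtosis of
a zero-variance series defined as 0; mel energies floored at 1e-10 before
the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, irfft, rfft

from .audio_io import AudioSignal, Epoch, segment_epochs

FRAME_SECONDS = 0.025
HOP_SECONDS = 0.010
N_MEL_BANDS = 26
N_MFCC = 12
MEL_FMIN = 20.0
MEL_FMAX = 8000.0
F0_MIN = 75.0
F0_MAX = 600.0
VOICING_THRESHOLD = 0.45
LOG_FLOOR = 1e-10

MFCC_NAMES = tuple(f"mfcc{i}" for i in range(1, N_MFCC + 1))
MELBAND_NAMES = tuple(f"melband{i}" for i in range(1, N_MEL_BANDS + 1))
LLD_NAMES = MFCC_NAMES + MELBAND_NAMES + ("rms_energy", "zcr", "f0", "voicing")

FUNCTIONAL_NAMES = (
    "mean",
    "std",
    "min",
    "max",
    "range",
    "p1",
    "p25",
    "p50",
    "p75",
    "p99",
    "iqr",
    "skewness",
    "kurtosis",
)

#: LLDs unaffected by a pure gain change (used by screening sanity checks).
GAIN_INVARIANT_LLDS = ("zcr", "f0", "voicing") + MFCC_NAMES


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered name contract: one feature per (LLD, functional) pair."""

    llds: tuple[str, ...] = LLD_NAMES
    functionals: tuple[str, ...] = FUNCTIONAL_NAMES

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"{lld}_{fn}" for lld in self.llds for fn in self.functionals)

    @property
    def dimension(self) -> int:
        return len(self.llds) * len(self.functionals)

    def to_dict(self) -> dict:
        return {"llds": list(self.llds), "functionals": list(self.functionals)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRegistry":
        return cls(llds=tuple(d["llds"]), functionals=tuple(d["functionals"]))


DEFAULT_REGISTRY = FeatureRegistry()


@dataclass
class FrameSeries:
    """Per-frame LLD values for one epoch; all series share one frame count."""

    series: dict[str, np.ndarray]
    frame_seconds: float = FRAME_SECONDS
    hop_seconds: float = HOP_SECONDS

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.series.values()}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent frame counts across LLDs: {lengths}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.series.values())).size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


@lru_cache(maxsize=8)
def mel_filterbank(
    n_fft: int, sample_rate: int, n_bands: int = N_MEL_BANDS,
    fmin: float = MEL_FMIN, fmax: float = MEL_FMAX,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_bands, n_fft // 2 + 1)."""
    mel_points = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_bands + 2)
    hz_points = np.asarray(_mel_to_hz(mel_points))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_bands, fft_freqs.size))
    for b in range(n_bands):
        lo, ctr, hi = hz_points[b], hz_points[b + 1], hz_points[b + 2]
        rising = (fft_freqs - lo) / (ctr - lo)
        falling = (hi - fft_freqs) / (hi - ctr)
        fb[b] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    if x.size < frame_len:
        raise ValueError("signal shorter than one analysis frame")
    return sliding_window_view(x, frame_len)[::hop]


def compute_llds(
    epoch: Epoch | AudioSignal,
    frame_seconds: float = FRAME_SECONDS,
    hop_seconds: float = HOP_SECONDS,
) -> FrameSeries:
    """Compute all frame-level LLDs for one epoch.

    Digital silence is handled gracefully: zero energy, zero voicing,
    F0 = 0, log mel energies at the floor.
    """
    x = np.asarray(epoch.samples, dtype=np.float64)
    rate = epoch.sample_rate
    frame_len = int(round(frame_seconds * rate))
    hop = int(round(hop_seconds * rate))
    frames = _frame(x, frame_len, hop)
    n_frames = frames.shape[0]

    # -- spectral LLDs -------------------------------------------------
    n_fft = 1 << (frame_len - 1).bit_length()
    window = np.hamming(frame_len)
    power = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_fft, rate)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, LOG_FLOOR))
    mfcc = dct(log_mel, type=2, norm="ortho", axis=1)[:, 1 : N_MFCC + 1]

    # -- time-domain LLDs ----------------------------------------------
    rms = np.sqrt(np.mean(frames**2, axis=1))
    # crossings per second; sign changes are invariant to positive gain
    signs = np.signbit(frames)
    zcr = np.sum(signs[:, 1:] != signs[:, :-1], axis=1) / frame_seconds

    # -- pitch / voicing via normalized autocorrelation ----------------
    centered = frames - frames.mean(axis=1, keepdims=True)
    n_acf = 1 << (2 * frame_len - 1).bit_length()
    spec = rfft(centered, n=n_acf, axis=1)
    acf = irfft(np.abs(spec) ** 2, n=n_acf, axis=1)[:, :frame_len]
    r0 = acf[:, 0]
    lag_min = int(np.floor(rate / F0_MAX))
    lag_max = min(int(np.ceil(rate / F0_MIN)), frame_len - 1)
    lags = np.arange(lag_min, lag_max + 1)
    # unbiased normalization so long-lag peaks are not penalized
    # frames with vanishing energy (incl. denormals) are treated as silence
    silent = r0 <= 1e-30
    norm = np.where(silent, 1.0, r0)[:, None] * (1.0 - lags / frame_len)[None, :]
    r_norm = acf[:, lag_min : lag_max + 1] / norm
    r_norm[silent, :] = 0.0
    vmax = r_norm.max(axis=1)
    voicing = np.clip(vmax, 0.0, 1.0)
    # the autocorrelation also peaks at period multiples; the fundamental is
    # the earliest LOCAL peak within 90% of the global peak, not the argmax
    interior = r_norm[:, 1:-1]
    local_peak = np.zeros_like(r_norm, dtype=bool)
    local_peak[:, 1:-1] = (interior >= r_norm[:, :-2]) & (interior >= r_norm[:, 2:])
    candidate = local_peak & (r_norm >= 0.9 * np.maximum(vmax, 1e-12)[:, None])
    has_candidate = candidate.any(axis=1)
    best = np.where(has_candidate, np.argmax(candidate, axis=1),
                    np.argmax(r_norm, axis=1))
    f0 = np.where(voicing >= VOICING_THRESHOLD, rate / lags[best], 0.0)

    series: dict[str, np.ndarray] = {}
    for i, name in enumerate(MFCC_NAMES):
        series[name] = mfcc[:, i]
    for i, name in enumerate(MELBAND_NAMES):
        series[name] = log_mel[:, i]
    series["rms_energy"] = rms
    series["zcr"] = zcr.astype(np.float64)
    series["f0"] = f0
    series["voicing"] = voicing
    return FrameSeries(series, frame_seconds=frame_seconds, hop_seconds=hop_seconds)


def _functionals_matrix(values: np.ndarray) -> np.ndarray:
    """13 functionals per row of a (n_lld, n_frames) matrix."""
    mean = values.mean(axis=1)
    std = values.std(axis=1)  # population SD
    vmin = values.min(axis=1)
    vmax = values.max(axis=1)
    pcts = np.percentile(values, [1, 25, 50, 75, 99], axis=1)  # type-7
    centered = values - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    m3 = np.mean(centered**3, axis=1)
    m4 = np.mean(centered**4, axis=1)
    safe_m2 = np.where(m2 > 0.0, m2, 1.0)
    skew = np.where(m2 > 0.0, m3 / safe_m2**1.5, 0.0)
    kurt = np.where(m2 > 0.0, m4 / safe_m2**2 - 3.0, 0.0)
    return np.column_stack(
        [mean, std, vmin, vmax, vmax - vmin,
         pcts[0], pcts[1], pcts[2], pcts[3], pcts[4], pcts[3] - pcts[1],
         skew, kurt]
    )


def apply_functionals(
    frames: FrameSeries, registry: FeatureRegistry = DEFAULT_REGISTRY
) -> pd.Series:
    """Summarize a FrameSeries into the registry-ordered feature vector."""
    if frames.n_frames == 0:
        raise ValueError("cannot summarize an empty frame series")
    values = np.vstack([frames[lld] for lld in registry.llds])
    table = _functionals_matrix(values)
    out = pd.Series(table.ravel(), index=list(registry.names), dtype=np.float64)
    if not np.all(np.isfinite(out.to_numpy())):
        bad = out.index[~np.isfinite(out.to_numpy())].tolist()
        raise AssertionError(f"non-finite features produced: {bad[:5]}")
    return out


def extract_epoch_features(
    epoch: Epoch, registry: FeatureRegistry = DEFAULT_REGISTRY
) -> pd.Series:
    return apply_functionals(compute_llds(epoch), registry)


def extract_features(
    signal: AudioSignal,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    epoch_seconds: float = 5.0,
) -> pd.DataFrame:
    """Segment a signal and extract the per-epoch feature matrix.

    Returns a DataFrame with ``epoch_index`` and ``start_time_s`` columns
    followed by the registry features, one row per epoch.
    """
    epochs = segment_epochs(signal, epoch_seconds)
    rows = [extract_epoch_features(ep, registry) for ep in epochs]
    matrix = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=list(registry.names)
    )
    matrix.insert(0, "start_time_s", [ep.start_time for ep in epochs])
    matrix.insert(0, "epoch_index", [ep.index for ep in epochs])
    return matrix


def feature_columns(matrix: pd.DataFrame, registry: FeatureRegistry) -> pd.DataFrame:
    """Restrict a feature table to the registry columns (drops metadata)."""
    return matrix[list(n for n in registry.names if n in matrix.columns)]
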