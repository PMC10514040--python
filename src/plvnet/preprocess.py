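"""Signal conditioning: downsampling, common average reference, zero-phase FIR
filtering, sub-band decomposition and epoching.

The chain mirrors standard EEG practice for phase-synchrony analysis: the
continuous record is downsampled to 256 Hz, re-referenced to the common
average, broadband filtered (0.5-40 Hz zero-phase FIR), decomposed into the
six conventional sub-bands, and cut into non-overlapping 4-s epochs. Filters
are applied to continuous segments *before* epoching so Hilbert/filter edge
artifacts stay outside the analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band edges {self.f_low}-{self.f_high} Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def width(self) -> float:
        return self.f_high - self.f_low


#: The six conventional EEG sub-bands used throughout the analysis.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}

#: Broadband pre-filter applied before sub-band decomposition.
BROADBAND = BandDefinition("broadband", 0.5, 40.0)


def downsample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Resample ``data`` (..., n_samples) from ``fs`` to ``target_fs``.

    Uses polyphase resampling (built-in anti-alias low-pass), exact for
    rational ratios such as 2048 -> 256.
    """
    if target_fs > fs:
        raise ValueError(f"target_fs {target_fs} exceeds input fs {fs}")
    if target_fs == fs:
        return np.asarray(data, dtype=float)
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=-1)


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels (axis 0).

    After re-referencing the channel mean is zero at every sample.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2 or data.shape[0] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def design_fir_bandpass(f_low: float, f_high: float, fs: float) -> np.ndarray:
    """Hamming-window FIR bandpass taps; order 3*fs/f_low rounded to even."""
    if not (0 < f_low < f_high < fs / 2):
        raise ValueError(
            f"band edges ({f_low}, {f_high}) Hz invalid for fs={fs} Hz (need 0 < lo < hi < fs/2)"
        )
    order = int(round(3 * fs / f_low))
    order += order % 2  # even order -> odd tap count, type-I linear phase
    return signal.firwin(order + 1, [f_low, f_high], pass_zero=False, fs=fs, window="hamming")


def bandpass_fir_zero_phase(
    data: np.ndarray, f_low: float, f_high: float, fs: float
) -> np.ndarray:
    """Zero-phase (forward-backward) FIR bandpass along the last axis."""
    taps = design_fir_bandpass(f_low, f_high, fs)
    n = np.asarray(data).shape[-1]
    # filtfilt needs padlen < n; fall back to a shorter filter for short inputs
    if len(taps) * 3 >= n:
        order = max(2 * (n // 8), 8)
        taps = signal.firwin(order + 1, [f_low, f_high], pass_zero=False, fs=fs, window="hamming")
    return signal.filtfilt(taps, [1.0], np.asarray(data, dtype=float), axis=-1)


def band_filter(data: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    return bandpass_fir_zero_phase(data, band.f_low, band.f_high, fs)


def extract_epochs(
    data: np.ndarray,
    fs: float,
    epoch_len: float,
    n_epochs: int,
    onsets: np.ndarray,
) -> np.ndarray:
    """Cut ``n_epochs`` windows of ``epoch_len`` seconds starting at sample
    indices ``onsets`` from continuous ``data`` (..., n_samples).

    Returns an array (..., n_samples_per_epoch, n_epochs). Epochs must be
    non-overlapping and fully contained in the record.
    """
    data = np.asarray(data, dtype=float)
    nsamp = int(round(epoch_len * fs))
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < n_epochs:
        raise ValueError(f"need {n_epochs} onsets, got {len(onsets)}")
    onsets = onsets[:n_epochs]
    order = np.argsort(onsets)
    sorted_onsets = onsets[order]
    if np.any(np.diff(sorted_onsets) < nsamp):
        raise ValueError("requested epochs overlap")
    end = sorted_onsets[-1] + nsamp
    if end > data.shape[-1]:
        raise ValueError(
            f"insufficient data: need {end} samples, have {data.shape[-1]} "
            f"(short by {end - data.shape[-1]})"
        )
    epochs = np.stack([data[..., o : o + nsamp] for o in onsets], axis=-1)
    return epochs


def presentation_onsets(
    fs: float,
    presentation_len: float,
    n_presentations: int,
    epoch_len: float,
    epochs_per_presentation: int,
    guard: float = 0.5,
) -> np.ndarray:
    """Epoch onsets for a block of repeated stimulus presentations.

    Each presentation contributes ``epochs_per_presentation`` consecutive
    non-overlapping epochs starting ``guard`` seconds after its onset (the
    guard keeps filter edge effects out of the first window).
    """
    need = guard + epochs_per_presentation * epoch_len
    if need > presentation_len:
        raise ValueError(
            f"{epochs_per_presentation} epochs of {epoch_len}s (+{guard}s guard) "
            f"do not fit in a {presentation_len}s presentation"
        )
    onsets = []
    for p in range(n_presentations):
        t0 = p * presentation_len + guard
        for e in range(epochs_per_presentation):
            onsets.append(int(round((t0 + e * epoch_len) * fs)))
    return np.asarray(onsets, dtype=int)
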