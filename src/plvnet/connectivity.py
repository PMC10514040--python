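"""Phase-locking-value connectivity with a phase-permutation surrogate null.

For a channel pair the PLV is the magnitude of the time-averaged unit phasor
of the instantaneous phase difference,

    PLV = | (1/N) sum_k exp(i * (phi_1(t_k) - phi_2(t_k))) |,

with instantaneous phases taken as the argument of the Hilbert analytic
signal of the narrowband (FIR-bandpassed) channel. PLV is computed per 4-s
epoch and arithmetically averaged across epochs. Edges are then pruned
against a surrogate null built by randomly permuting the time samples of the
second channel's phase sequence (one fresh permutation per surrogate per
epoch), recomputing the epoch-averaged PLV per permutation, and zeroing
edges whose empirical one-sided p-value is not below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import BandDefinition, band_filter
from .synth import Condition, EpochedRecording


@dataclass
class PLVMatrix:
    """Symmetric channel x channel epoch-averaged PLV in [0, 1], zero diagonal."""

    values: np.ndarray
    band: BandDefinition | None = None
    condition: Condition | None = None
    n_epochs_averaged: int = 0
    labels: tuple[str, ...] | None = None
    p_values: np.ndarray | None = None  # filled by surrogate_prune

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLV values must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) of a narrowband signal.

    Works on the last axis; the amplitude envelope is discarded. The input
    should already be band-limited (see :func:`plvnet.preprocess.band_filter`).
    """
    x = np.asarray(x, dtype=float)
    if np.all(np.abs(x) < 1e-300):
        raise ValueError("all-zero input has undefined phase")
    return np.angle(hilbert(x, axis=-1))


def fft_analytic_phase(x: np.ndarray) -> np.ndarray:
    """Frequency-domain analytic-signal phase; independent cross-check of
    :func:`hilbert_phase` (zeroes negative frequencies, doubles positive)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = np.fft.fft(x, axis=-1)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.angle(np.fft.ifft(X * h, axis=-1))


def compute_plv(phase1: np.ndarray, phase2: np.ndarray) -> float:
    """PLV of two equal-length phase sequences."""
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise ValueError("phase sequences must have equal length")
    return float(np.abs(np.mean(np.exp(1j * (phase1 - phase2)))))


def compute_plv_quadrature(phase1: np.ndarray, phase2: np.ndarray) -> float:
    """The sin/cos quadrature form of the same statistic,
    sqrt(mean(sin d)^2 + mean(cos d)^2); equal to :func:`compute_plv`."""
    d = np.asarray(phase1, dtype=float) - np.asarray(phase2, dtype=float)
    return float(np.hypot(np.mean(np.sin(d)), np.mean(np.cos(d))))


def _plv_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """Epoch-averaged PLV matrix from phases (n_ch, n_samples, n_epochs)."""
    n_ch, nsamp, n_ep = phases.shape
    U = np.exp(1j * phases)
    acc = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        Ue = U[:, :, e]
        acc += np.abs(Ue @ Ue.conj().T) / nsamp
    P = acc / n_ep
    np.fill_diagonal(P, 0.0)
    return np.clip(0.5 * (P + P.T), 0.0, 1.0)


def band_phases(rec: EpochedRecording, band: BandDefinition) -> np.ndarray:
    """Per-channel/epoch instantaneous phase of ``rec`` in ``band``.

    Filtering is applied along the sample axis of each epoch.
    """
    filtered = band_filter(np.moveaxis(rec.data, 2, 1), band, rec.fs)  # (ch, ep, samp)
    return np.moveaxis(hilbert_phase(filtered), 1, 2)


def epoch_averaged_plv(
    rec: EpochedRecording,
    band: BandDefinition,
    use_truth_phases: bool = False,
) -> PLVMatrix:
    """PLV per epoch, averaged over epochs, for every channel pair.

    With ``use_truth_phases`` (synthetic recordings only) the generator's
    ground-truth band phases are used instead of the filter+Hilbert estimate,
    which isolates the coupling model from filter effects.
    """
    if rec.n_epochs < 1:
        raise ValueError("need at least one epoch")
    if use_truth_phases:
        if not rec.truth_phases or band.name not in rec.truth_phases:
            raise ValueError(f"recording has no ground-truth phases for {band.name!r}")
        phases = rec.truth_phases[band.name]
    else:
        phases = band_phases(rec, band)
    return PLVMatrix(
        values=_plv_matrix_from_phases(phases),
        band=band,
        condition=rec.condition,
        n_epochs_averaged=rec.n_epochs,
        labels=rec.montage.labels,
    )


def surrogate_plv_matrices(
    phases: np.ndarray, M: int, rng: np.random.Generator
) -> np.ndarray:
    """M surrogate epoch-averaged PLV matrices from phases (ch, samp, ep).

    Surrogate m permutes the time samples of the *second* channel of every
    pair (a fresh permutation per surrogate per epoch, shared across pairs),
    leaving the first channel intact, and averages across epochs exactly as
    the observed statistic. Entry [i, j] uses channel j as the permuted one.
    """
    n_ch, nsamp, n_ep = phases.shape
    U = np.exp(1j * phases).astype(np.complex64)
    out = np.zeros((M, n_ch, n_ch), dtype=np.float32)
    for m in range(M):
        acc = np.zeros((n_ch, n_ch), dtype=np.float32)
        for e in range(n_ep):
            perm = rng.permutation(nsamp)
            Ue = U[:, :, e]
            acc += np.abs(Ue @ Ue[:, perm].conj().T).astype(np.float32) / nsamp
        out[m] = acc / n_ep
    return out


def surrogate_prune(
    plv: PLVMatrix,
    phases: np.ndarray,
    M: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> PLVMatrix:
    """Zero the edges of ``plv`` that do not beat the permutation null.

    For each pair the empirical one-sided p-value is
    (1 + #{PLV_surr >= PLV_obs}) / (M + 1); entries with p >= alpha are set
    to zero, the rest keep their observed value (never rescaled). ``phases``
    must be the same (ch, samp, ep) phase array the observed matrix was
    computed from.
    """
    if M < 20:
        raise ValueError("need at least 20 surrogates")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if 1.0 / (M + 1) >= alpha:
        raise ValueError(
            f"M={M} cannot resolve alpha={alpha}: minimum attainable p is 1/(M+1)"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    surr = surrogate_plv_matrices(phases, M, rng)  # (M, ch, ch)
    obs = plv.values
    # use the [i, j] orientation (channel j permuted) for the upper triangle
    exceed = (surr >= obs[None, :, :].astype(np.float32)).sum(axis=0)
    p = (1.0 + exceed) / (M + 1.0)
    iu = np.triu_indices_from(obs, k=1)
    p_sym = np.ones_like(obs)
    p_sym[iu] = p[iu]
    p_sym.T[iu] = p[iu]
    pruned = np.where(p_sym < alpha, obs, 0.0)
    np.fill_diagonal(pruned, 0.0)
    return PLVMatrix(
        values=pruned,
        band=plv.band,
        condition=plv.condition,
        n_epochs_averaged=plv.n_epochs_averaged,
        labels=plv.labels,
        p_values=p_sym,
    )


def connectivity_for_recording(
    rec: EpochedRecording,
    band: BandDefinition,
    M: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    prune: bool = True,
) -> PLVMatrix:
    """Filter -> Hilbert phase -> epoch-averaged PLV -> surrogate pruning."""
    phases = band_phases(rec, band)
    plv = PLVMatrix(
        values=_plv_matrix_from_phases(phases),
        band=band,
        condition=rec.condition,
        n_epochs_averaged=rec.n_epochs,
        labels=rec.montage.labels,
    )
    if not prune:
        return plv
    return surrogate_prune(plv, phases, M=M, alpha=alpha, seed=seed)
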