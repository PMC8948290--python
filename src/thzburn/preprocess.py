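"""Waveform denoising and spectral deconvolution.

Two data-driven steps turn raw per-pixel waveforms into reflectivity
spectra:

1. Wavelet shrinkage on the shift-invariant (maximal-overlap / stationary)
   wavelet transform, with one hard threshold per decomposition level
   estimated from two signal-free time windows (before and after the main
   pulse).  The final-level scaling (approximation) coefficients are never
   touched.
2. Wiener deconvolution of each pixel against the window-air reference,
   with the per-frequency SNR of the reference as the regularizer:

       R(f) = S_samp(f) conj(S_ref(f)) / (|S_ref(f)|^2 + 1/SNR(f))

The level thresholds use the max-|coefficient| rule over the two noise
windows, which guarantees every noise-window coefficient at a thresholded
level is zeroed; a k-sigma alternative is available via ``rule="ksigma"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from scipy import signal as sps

from .simulate import ScanCube, Waveform

DEFAULT_WAVELET = "sym4"
DEFAULT_LEVELS = 6
SNR_CEILING = 1.0e6
SNR_FLOOR = 1.0e-12


@dataclass(frozen=True)
class NoiseWindows:
    """Two signal-free intervals (ps): ``pre`` before the main pulse,
    ``post`` after it (and before the first Fabry-Perot echo)."""

    pre: tuple[float, float] = (5.0, 36.0)
    post: tuple[float, float] = (64.0, 75.0)

    def __post_init__(self) -> None:
        for name, (a, b) in (("pre", self.pre), ("post", self.post)):
            if not b > a:
                raise ValueError(f"{name} window must have positive length")
        if self.pre[1] > self.post[0]:
            raise ValueError("pre window must end before the post window starts")

    def sample_masks(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pre = (t >= self.pre[0]) & (t <= self.pre[1])
        post = (t >= self.post[0]) & (t <= self.post[1])
        for name, m in (("pre", pre), ("post", post)):
            if m.sum() < 32:
                raise ValueError(f"{name} noise window has fewer than 32 samples")
        return pre, post


@dataclass
class SnrSpectrum:
    """Per-frequency power SNR of the reference measurement."""

    freq: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if self.freq.shape != self.snr.shape:
            raise ValueError("freq and snr must have the same shape")
        if not np.all(np.isfinite(self.snr)) or np.any(self.snr <= 0):
            raise ValueError("snr must be finite and strictly positive")


@dataclass
class SpectralTrace:
    """Complex reflectivity spectrum of one pixel on a uniform THz grid."""

    freq: np.ndarray
    value: np.ndarray
    pixel_index: tuple[int, int] | None = None

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.value)


@dataclass
class SpectraCube:
    """Deconvolved spectra of every pixel of a scan."""

    freq: np.ndarray
    values: np.ndarray  # (ny, nx, nf) complex

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def trace(self, iy: int, ix: int) -> SpectralTrace:
        return SpectralTrace(self.freq, self.values[iy, ix], pixel_index=(ix, iy))


# ---------------------------------------------------------------------------
# shift-invariant wavelet transform plumbing
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _swt_level_shifts(wavelet: str, n_levels: int, n: int) -> tuple[int, ...]:
    """Per-level circular shift between event time and the peak of its
    detail-coefficient response, measured on a unit impulse.

    Used to align the noise-window sample indices with the coefficient
    indices they dominate (the transform itself is not phase compensated).
    Order: level 1 (finest) ... level ``n_levels``.
    """
    x = np.zeros(n)
    x[n // 2] = 1.0
    coeffs = pywt.swt(x, wavelet, level=n_levels, trim_approx=True, norm=True)
    details = coeffs[1:][::-1]  # finest first
    return tuple(int(np.argmax(np.abs(d)) - n // 2) for d in details)


def _validate_transform_length(n: int, n_levels: int) -> None:
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if 2**n_levels > n:
        raise ValueError(f"n_levels={n_levels} exceeds log2 of record length {n}")
    if n % (2**n_levels) != 0:
        raise ValueError(
            f"record length {n} is not a multiple of 2^{n_levels}; resample or "
            "pad the record to a supported length before denoising (no "
            "implicit padding is applied)"
        )


def _check_windows_clear_of_pulse(amp2d: np.ndarray, win_mask: np.ndarray) -> None:
    """Reject windows that overlap the main-pulse support.

    The pulse support is taken as samples above half the peak, but only
    when the peak clearly rises above the robust noise scale — a
    noise-only trace has no pulse to protect.
    """
    a = np.abs(amp2d)
    peak = a.max(axis=-1, keepdims=True)
    mad = np.median(np.abs(amp2d - np.median(amp2d, axis=-1, keepdims=True)), axis=-1, keepdims=True)
    floor = 8.0 * 1.4826 * mad
    support = (a > 0.5 * peak) & (peak > floor) & (peak > 0)
    if np.any(support & win_mask):
        raise ValueError("noise windows overlap the main-pulse support")


def _swt_denoise_core(
    amp2d: np.ndarray,
    t: np.ndarray,
    windows: NoiseWindows,
    wavelet: str,
    n_levels: int,
    rule: str,
    k_sigma: float,
):
    """Shared threshold/denoise engine on a stack of waveforms.

    Returns ``(denoised (m, n), thresholds (m, n_levels))``.
    """
    amp2d = np.atleast_2d(np.asarray(amp2d, dtype=float))
    n = amp2d.shape[-1]
    _validate_transform_length(n, n_levels)
    pre, post = windows.sample_masks(t)
    win = pre | post
    _check_windows_clear_of_pulse(amp2d, win)

    coeffs = pywt.swt(amp2d, wavelet, level=n_levels, trim_approx=True, norm=True, axis=-1)
    approx, details_coarse_first = coeffs[0], coeffs[1:]
    shifts = _swt_level_shifts(wavelet, n_levels, n)

    win_idx = np.nonzero(win)[0]
    thresholds = np.empty((amp2d.shape[0], n_levels))
    new_details = []
    for j, d in enumerate(details_coarse_first):
        level = n_levels - j  # coarse-first ordering from pywt
        idx = (win_idx + shifts[level - 1]) % n
        sel = np.abs(d[:, idx])
        if rule == "max":
            thr = sel.max(axis=-1)
        elif rule == "ksigma":
            thr = k_sigma * sel.std(axis=-1)
        else:
            raise ValueError(f"unknown threshold rule {rule!r}")
        thresholds[:, level - 1] = thr
        new_details.append(np.where(np.abs(d) <= thr[:, None], 0.0, d))

    den = pywt.iswt([approx] + new_details, wavelet, norm=True, axis=-1)
    return den, thresholds


def level_thresholds(
    waveform: Waveform,
    windows: NoiseWindows,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
    rule: str = "max",
    k_sigma: float = 3.0,
) -> np.ndarray:
    """Per-level hard thresholds from the two noise windows.

    Returned array is ordered level 1 (finest detail) to ``n_levels``.  The
    default ``rule="max"`` takes the largest coefficient magnitude whose
    aligned time index falls inside either window, so every noise-window
    coefficient is zeroed by the subsequent hard thresholding.
    """
    _, thr = _swt_denoise_core(
        waveform.amplitude[None, :], waveform.t, windows, wavelet, n_levels, rule, k_sigma
    )
    return thr[0]


def modwt_denoise(
    waveform: Waveform,
    windows: NoiseWindows,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
    rule: str = "max",
    k_sigma: float = 3.0,
) -> Waveform:
    """Wavelet-shrinkage denoising of one waveform.

    Level-dependent hard thresholding on the shift-invariant transform:
    detail coefficients with magnitude at or below the level's threshold
    are zeroed, all others (and the approximation) pass unchanged.
    """
    den, _ = _swt_denoise_core(
        waveform.amplitude[None, :], waveform.t, windows, wavelet, n_levels, rule, k_sigma
    )
    return Waveform(waveform.t, den[0], pixel_index=waveform.pixel_index, kind=waveform.kind)


def denoise_scan(
    cube: ScanCube,
    windows: NoiseWindows | None = None,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
    rule: str = "max",
    k_sigma: float = 3.0,
) -> ScanCube:
    """Denoise every pixel waveform and the reference of a scan (vectorized)."""
    windows = windows or NoiseWindows()
    ny, nx, nt = cube.waveforms.shape
    flat = cube.waveforms.reshape(ny * nx, nt)
    den, _ = _swt_denoise_core(flat, cube.t, windows, wavelet, n_levels, rule, k_sigma)
    ref_den, _ = _swt_denoise_core(
        cube.reference.amplitude[None, :], cube.t, windows, wavelet, n_levels, rule, k_sigma
    )
    return ScanCube(
        t=cube.t,
        waveforms=den.reshape(ny, nx, nt),
        reference=Waveform(cube.t, ref_den[0], kind="reference"),
        truth_sites=cube.truth_sites,
        truth_biopsy_mask=cube.truth_biopsy_mask,
        truth_hydration=cube.truth_hydration,
        config=cube.config,
        window=cube.window,
        debye=cube.debye,
    )


# ---------------------------------------------------------------------------
# SNR estimation and deconvolution
# ---------------------------------------------------------------------------


def estimate_snr_spectrum(
    reference: Waveform,
    windows: NoiseWindows | None = None,
    ceiling: float = SNR_CEILING,
) -> SnrSpectrum:
    """Per-frequency power SNR of the reference.

    Noise power is the Welch periodogram of the pre-pulse window segment,
    interpolated onto the record's rfft grid and scaled to the expected
    squared-magnitude of a full-record FFT of that noise
    (``P_noise(f) = PSD(f) * fs * N / 2`` for white noise of variance
    ``sigma^2``, this is ``N sigma^2``).  The ratio ``|S_ref|^2 / P_noise``
    is clipped to ``[1e-12, ceiling]``; a noiseless reference therefore
    reports the documented ceiling everywhere.
    """
    windows = windows or NoiseWindows()
    t = reference.t
    dt = reference.dt
    n = t.size
    pre, _ = windows.sample_masks(t)
    seg = reference.amplitude[pre]
    peak_idx = int(np.argmax(np.abs(reference.amplitude)))
    if pre[peak_idx]:
        raise ValueError("pre window contains the main pulse")

    freq = np.fft.rfftfreq(n, dt)
    spec_power = np.abs(np.fft.rfft(reference.amplitude)) ** 2

    fs = 1.0 / dt  # THz
    f_seg, psd = sps.welch(seg, fs=fs, nperseg=min(256, seg.size))
    p_noise = np.interp(freq, f_seg, psd) * fs * n / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(p_noise > 0, spec_power / p_noise, np.inf)
    snr = np.clip(snr, SNR_FLOOR, ceiling)
    return SnrSpectrum(freq=freq, snr=snr)


def wiener_deconvolve(
    sample: Waveform, reference: Waveform, snr: SnrSpectrum
) -> SpectralTrace:
    """SNR-regularized frequency-domain deconvolution of one pixel."""
    if sample.t.shape != reference.t.shape or not np.allclose(sample.t, reference.t):
        raise ValueError("sample and reference must share the same time grid")
    freq = np.fft.rfftfreq(sample.t.size, sample.dt)
    if freq.shape != snr.freq.shape or not np.allclose(freq, snr.freq):
        raise ValueError("SNR spectrum is on a different frequency grid")
    s = np.fft.rfft(sample.amplitude)
    r = np.fft.rfft(reference.amplitude)
    value = s * np.conj(r) / (np.abs(r) ** 2 + 1.0 / snr.snr)
    return SpectralTrace(freq=freq, value=value, pixel_index=sample.pixel_index)


def naive_deconvolve(sample: Waveform, reference: Waveform) -> SpectralTrace:
    """Plain spectral ratio, kept as the unregularized comparison mode.

    Diverges at reference spectral nulls (values may be non-finite).
    """
    if sample.t.shape != reference.t.shape or not np.allclose(sample.t, reference.t):
        raise ValueError("sample and reference must share the same time grid")
    freq = np.fft.rfftfreq(sample.t.size, sample.dt)
    s = np.fft.rfft(sample.amplitude)
    r = np.fft.rfft(reference.amplitude)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = s / r
    return SpectralTrace(freq=freq, value=value, pixel_index=sample.pixel_index)


def deconvolve_scan(
    cube: ScanCube,
    windows: NoiseWindows | None = None,
    snr: SnrSpectrum | None = None,
) -> SpectraCube:
    """Wiener-deconvolve every pixel of a (typically denoised) scan."""
    windows = windows or NoiseWindows()
    if snr is None:
        snr = estimate_snr_spectrum(cube.reference, windows)
    s = np.fft.rfft(cube.waveforms, axis=-1)
    r = np.fft.rfft(cube.reference.amplitude)
    values = s * np.conj(r) / (np.abs(r) ** 2 + 1.0 / snr.snr)
    return SpectraCube(freq=snr.freq, values=values)


def preprocess_scan(
    cube: ScanCube,
    windows: NoiseWindows | None = None,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
) -> tuple[ScanCube, SpectraCube]:
    """Denoise then deconvolve a scan; returns (denoised cube, spectra)."""
    windows = windows or NoiseWindows()
    den = denoise_scan(cube, windows, wavelet=wavelet, n_levels=n_levels)
    return den, deconvolve_scan(den, windows)
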