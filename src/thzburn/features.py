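"""Spectral-image formation, biopsy-pixel detection, and ROI observations.

The classifier's predictor space is built here: for each burn, ``k``
(default fifteen) 4x4-pixel regions of interest are drawn at random from
positions that avoid the biopsy mask, and each ROI contributes one
observation — the sixteen-pixel mean reflectivity amplitude spectrum
restricted to the analysis band (default 0.1-0.5 THz) — plus the scalar
band area used for images and the ANOVA stage.

Biopsy pixels are located from the phase of the first Fabry-Perot window
echo: the punch leaves an air gap behind the window, so the echo-gated
segment of an air-backed pixel correlates positively with the reference's
echo template, while tissue-backed pixels (whose complex window-tissue
reflection enters the echo squared) correlate negatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_LEVELS,
    DEFAULT_WAVELET,
    NoiseWindows,
    SpectraCube,
    SpectralTrace,
    denoise_scan,
)
from .simulate import ScanCube, WindowSpec


@dataclass(frozen=True)
class BandSpec:
    """The analysis band in THz (inclusive on the FFT bin grid)."""

    f_lo: float = 0.1
    f_hi: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError("band requires 0 < f_lo < f_hi")

    def mask(self, freq: np.ndarray) -> np.ndarray:
        if self.f_hi > freq[-1]:
            raise ValueError(
                f"band upper edge {self.f_hi} THz exceeds the grid Nyquist {freq[-1]:.3f}"
            )
        return (freq >= self.f_lo) & (freq <= self.f_hi)


@dataclass
class RoiSet:
    """k square ROIs (top-left pixel indices) drawn for one burn/iteration."""

    rois: np.ndarray  # (k, 2) of (iy, ix)
    size: int = 4
    iteration_id: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.rois = np.asarray(self.rois, dtype=int).reshape(-1, 2)

    @property
    def k(self) -> int:
        return len(self.rois)

    def pixel_indices(self, roi: int) -> tuple[np.ndarray, np.ndarray]:
        iy, ix = self.rois[roi]
        yy, xx = np.mgrid[iy : iy + self.size, ix : ix + self.size]
        return yy.ravel(), xx.ravel()


# ---------------------------------------------------------------------------
# band-limited spectral features
# ---------------------------------------------------------------------------


def band_area(trace, band: BandSpec = BandSpec(), freq: np.ndarray | None = None) -> float:
    """Area under the reflectivity amplitude curve over the analysis band
    (trapezoidal rule on the in-band FFT bins)."""
    if isinstance(trace, SpectralTrace):
        freq, amp = trace.freq, trace.amplitude
    else:
        if freq is None:
            raise ValueError("freq grid required when passing a bare amplitude array")
        amp = np.abs(np.asarray(trace))
    m = band.mask(freq)
    return float(np.trapezoid(amp[m], freq[m]))


def form_image(
    spectra: SpectraCube,
    band: BandSpec = BandSpec(),
    invalid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Band-area map over the FOV, normalized to max 1; invalid pixels NaN."""
    m = band.mask(spectra.freq)
    img = np.trapezoid(spectra.amplitude[..., m], spectra.freq[m], axis=-1)
    img = img.astype(float)
    if invalid_mask is not None:
        img[invalid_mask] = np.nan
    top = np.nanmax(img)
    if top > 0:
        img = img / top
    return img


# ---------------------------------------------------------------------------
# biopsy-pixel detection from Fabry-Perot echo phase
# ---------------------------------------------------------------------------


def detect_biopsy_mask(
    cube: ScanCube,
    window: WindowSpec | None = None,
    windows: NoiseWindows | None = None,
    denoise: bool = True,
    gate_halfwidth_ps: float = 5.0,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Binary biopsy map from the phase of the first window echo.

    Each pixel's waveform is gated around the nominal round-trip delay
    (echo position of the reference's main peak) and correlated with the
    reference's echo template; a positive correlation marks an air-like
    echo phase, i.e. a biopsy pixel.
    """
    window = window or cube.window
    if denoise:
        cube = denoise_scan(cube, windows or NoiseWindows(), wavelet=wavelet, n_levels=n_levels)
    t, dt = cube.t, float(cube.t[1] - cube.t[0])
    ref = cube.reference.amplitude
    p0 = int(np.argmax(np.abs(ref)))
    t_echo = t[p0] + window.round_trip_ps
    if t_echo + gate_halfwidth_ps > t[-1]:
        raise ValueError(
            f"first Fabry-Perot echo at {t_echo:.1f} ps falls outside the "
            f"{t[-1]:.1f} ps record for window spec {window}"
        )
    lo = int(round((t_echo - gate_halfwidth_ps) / dt))
    hi = int(round((t_echo + gate_halfwidth_ps) / dt)) + 1
    lo = max(lo, 0)
    template = ref[lo:hi]
    corr = np.tensordot(cube.waveforms[..., lo:hi], template, axes=([-1], [0]))
    return corr > 0


# ---------------------------------------------------------------------------
# randomized ROI sampling and the observation table
# ---------------------------------------------------------------------------


def admissible_positions(mask: np.ndarray, size: int = 4) -> np.ndarray:
    """(n, 2) array of top-left (iy, ix) of size x size blocks fully inside
    the grid and free of masked pixels."""
    ny, nx = mask.shape
    if ny < size or nx < size:
        return np.empty((0, 2), dtype=int)
    c = np.pad(np.cumsum(np.cumsum(mask.astype(int), axis=0), axis=1), ((1, 0), (1, 0)))
    block = (
        c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]
    )
    iy, ix = np.nonzero(block == 0)
    return np.stack([iy, ix], axis=1)


def sample_rois(
    mask: np.ndarray,
    k: int = 15,
    size: int = 4,
    rng: np.random.Generator | int | None = None,
    disjoint: bool = False,
    iteration_id: int = 0,
) -> RoiSet:
    """Draw ``k`` ROIs uniformly from the admissible top-left positions.

    ROIs may overlap each other (only the biopsy mask is excluded) unless
    ``disjoint=True``.  Reproducible for a given seed/generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = admissible_positions(mask, size)
    if len(pos) < k:
        raise ValueError(
            f"only {len(pos)} admissible {size}x{size} positions available, need {k}"
        )
    if not disjoint:
        pick = rng.choice(len(pos), size=k, replace=False)
        rois = pos[pick]
    else:
        order = rng.permutation(len(pos))
        chosen: list[np.ndarray] = []
        for i in order:
            cand = pos[i]
            if all(
                abs(cand[0] - c[0]) >= size or abs(cand[1] - c[1]) >= size
                for c in chosen
            ):
                chosen.append(cand)
                if len(chosen) == k:
                    break
        if len(chosen) < k:
            raise ValueError(
                f"could not place {k} disjoint ROIs ({len(chosen)} found)"
            )
        rois = np.stack(chosen)
    return RoiSet(rois=rois, size=size, iteration_id=iteration_id)


def roi_mean_spectrum(spectra: SpectraCube, roiset: RoiSet, roi: int) -> np.ndarray:
    """Mean reflectivity amplitude spectrum over the ROI's pixels."""
    yy, xx = roiset.pixel_indices(roi)
    return spectra.amplitude[yy, xx].mean(axis=0)


def feature_columns(freq: np.ndarray, band: BandSpec) -> list[str]:
    return [f"f_{f:.6f}" for f in freq[band.mask(freq)]]


def build_observations(
    spectra_by_burn: dict,
    roisets_by_burn: dict,
    band: BandSpec,
    d_by_burn: dict,
    iteration_id: int = 0,
) -> pd.DataFrame:
    """One row per ROI: identifiers, severity label, in-band mean spectrum,
    and the scalar band area of that mean spectrum."""
    from .classify import assign_severity_label  # late import: no module cycle

    frames = []
    cols: list[str] | None = None
    for burn_id, spectra in spectra_by_burn.items():
        roiset = roisets_by_burn[burn_id]
        d = float(d_by_burn[burn_id])
        m = band.mask(spectra.freq)
        if cols is None:
            cols = feature_columns(spectra.freq, band)
        elif cols != feature_columns(spectra.freq, band):
            raise ValueError("all burns must share one in-band frequency grid")
        label = assign_severity_label(d)
        for roi in range(roiset.k):
            mean_spec = roi_mean_spectrum(spectra, roiset, roi)
            row = {
                "burn_id": burn_id,
                "roi_id": roi,
                "iteration_id": iteration_id,
                "label": label,
                "d": d,
                "band_area": float(np.trapezoid(mean_spec[m], spectra.freq[m])),
            }
            row.update(dict(zip(cols, mean_spec[m])))
            frames.append(row)
    out = pd.DataFrame(frames)
    return out


def observation_features(obs: pd.DataFrame) -> np.ndarray:
    """The predictor matrix (in-band bins) of an observation table."""
    cols = [c for c in obs.columns if c.startswith("f_")]
    return obs[cols].to_numpy(dtype=float)
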