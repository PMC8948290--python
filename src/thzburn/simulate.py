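"""Synthetic THz-TDS scan generator for window-backed skin phantoms.

Emulates a handheld reflection-mode terahertz time-domain scanner imaging
scald burns through a dielectric imaging window: per-pixel waveforms carry
the primary window-tissue reflection plus Fabry-Perot echoes from internal
round trips in the window, Gaussian acquisition noise scaled by the number
of time averages, and ground truth (severity labels, hydration map, biopsy
mask) for downstream stages.

The burn contrast mechanism is edema: deeper burns accumulate more
interstitial fluid, which raises the tissue's THz permittivity (modelled as
a scaling of the slow Debye relaxation amplitude), hence its refractive
index and the window-tissue Fresnel reflection.

Sign conventions
----------------
``debye_permittivity`` returns the loss convention ``eps' + i eps''`` with
``eps'' >= 0``.  The spectral forward model uses numpy's forward-FFT phase
``exp(-i 2 pi f t)``, under which a delay multiplies by ``exp(-i 2 pi f
tau)`` and a passive medium needs ``Im(n) <= 0``; the forward model
therefore conjugates the permittivity internally.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: speed of light in mm/ps (== m/us == ...); convenient for THz work
C_MM_PS = 0.299792458


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DebyeParams:
    """Double-Debye permittivity parameters of a water-rich tissue.

    Defaults are a published healthy-human-skin parameter set:
    ``eps(w) = eps_inf + (eps_s - eps_2)/(1 - i w tau1)
    + (eps_2 - eps_inf)/(1 - i w tau2)`` (loss convention, see module
    docstring).  ``tau1`` is the slow (collective) relaxation, ``tau2`` the
    fast one; both in seconds.
    """

    eps_static: float = 60.0
    eps_mid: float = 3.6
    eps_inf: float = 3.0
    tau1: float = 10.0e-12
    tau2: float = 0.18e-12

    def __post_init__(self) -> None:
        if not (self.eps_static >= self.eps_mid >= self.eps_inf > 0):
            raise ValueError(
                "DebyeParams requires eps_static >= eps_mid >= eps_inf > 0, "
                f"got {self.eps_static}, {self.eps_mid}, {self.eps_inf}"
            )
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError(
                f"DebyeParams requires tau1 > tau2 > 0, got {self.tau1}, {self.tau2}"
            )


@dataclass(frozen=True)
class WindowSpec:
    """Imaging-window optical model: flat real index, finite thickness.

    ``n_echoes`` is the number of modelled Fabry-Perot round trips beyond
    the primary back-face reflection.
    """

    refractive_index: float = 1.95
    thickness: float = 3.0e-3  # metres
    n_echoes: int = 2

    def __post_init__(self) -> None:
        if self.refractive_index <= 1:
            raise ValueError("window refractive_index must be > 1")
        if self.thickness <= 0:
            raise ValueError("window thickness must be > 0")
        if self.n_echoes < 1:
            raise ValueError(
                "n_echoes must be >= 1 (biopsy-mask detection needs at least "
                "one Fabry-Perot echo)"
            )

    @property
    def round_trip_ps(self) -> float:
        """Internal round-trip delay 2 n d / c in picoseconds."""
        return 2.0 * self.refractive_index * self.thickness * 1e3 / C_MM_PS


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and noise model of one raster scan."""

    nx: int = 27
    ny: int = 27
    pixel_size_mm: float = 1.0
    time_window_ps: float = 204.8
    dt_ps: float = 0.05
    n_averages: int = 20
    noise_rms: float = 0.01  # single-shot, amplitude units
    seed: int = 0
    pulse_delay_ps: float = 50.0
    pulse_width_ps: float = 0.4
    scatter_jitter: float = 0.05  # sd of per-pixel multiplicative reflectivity jitter

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one pixel")
        nyquist_thz = 0.5 / self.dt_ps
        if nyquist_thz < 2.0:
            raise ValueError(
                f"dt={self.dt_ps} ps gives Nyquist {nyquist_thz:.2f} THz < 2 THz"
            )
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        nt = self.time_window_ps / self.dt_ps
        if abs(nt - round(nt)) > 1e-9:
            raise ValueError("time_window_ps must be an integer multiple of dt_ps")

    @property
    def nt(self) -> int:
        return int(round(self.time_window_ps / self.dt_ps))

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.nx * self.pixel_size_mm, self.ny * self.pixel_size_mm)

    def time_axis(self) -> np.ndarray:
        return np.arange(self.nt) * self.dt_ps

    def freq_axis(self) -> np.ndarray:
        """rfft frequency grid in THz (dt in ps makes 1/ps == THz)."""
        return np.fft.rfftfreq(self.nt, self.dt_ps)


@dataclass(frozen=True)
class BurnSite:
    """A circular scald site with its Day-4 dermal burn percentage."""

    center_mm: tuple[float, float]  # (x, y) from the FOV corner
    radius_mm: float
    dermal_burn_pct: float
    hydration_delta: float | None = None  # None -> severity_to_hydration default

    def __post_init__(self) -> None:
        if not (0.0 <= self.dermal_burn_pct <= 100.0):
            raise ValueError("dermal_burn_pct must lie in [0, 100]")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass(frozen=True)
class BiopsyDisk:
    """A punch-biopsy air-gap disk (default 4-mm diameter)."""

    center_mm: tuple[float, float]
    diameter_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    burn_sites: tuple[BurnSite, ...] = ()
    biopsy_disks: tuple[BiopsyDisk, ...] = ()
    background_hydration: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "burn_sites", tuple(self.burn_sites))
        object.__setattr__(self, "biopsy_disks", tuple(self.biopsy_disks))


@dataclass
class Waveform:
    """A sampled time-domain THz trace on a uniform picosecond grid."""

    t: np.ndarray
    amplitude: np.ndarray
    pixel_index: tuple[int, int] | None = None
    kind: str = "sample"  # "sample" | "reference"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.t.shape != self.amplitude.shape:
            raise ValueError("time axis and amplitude must have the same length")
        d = np.diff(self.t)
        if self.t.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class ScanCube:
    """One scan: waveform grid, window-air reference, and ground truth."""

    t: np.ndarray
    waveforms: np.ndarray  # (ny, nx, nt)
    reference: Waveform
    truth_sites: pd.DataFrame  # site_id, label, d, center_x_mm, center_y_mm, radius_mm
    truth_biopsy_mask: np.ndarray  # (ny, nx) bool
    truth_hydration: np.ndarray  # (ny, nx) float
    config: ScanConfig
    window: WindowSpec
    debye: DebyeParams

    def __post_init__(self) -> None:
        ny, nx, nt = self.waveforms.shape
        if self.truth_biopsy_mask.shape != (ny, nx):
            raise ValueError("biopsy mask shape must match the pixel grid")
        if self.truth_hydration.shape != (ny, nx):
            raise ValueError("hydration map shape must match the pixel grid")
        if self.t.shape != (nt,):
            raise ValueError("time axis length must match waveforms")

    @property
    def shape(self) -> tuple[int, int]:
        return self.waveforms.shape[:2]

    def waveform(self, iy: int, ix: int) -> Waveform:
        return Waveform(self.t, self.waveforms[iy, ix], pixel_index=(ix, iy))


# ---------------------------------------------------------------------------
# optical physics
# ---------------------------------------------------------------------------


def debye_permittivity(params: DebyeParams, freq_thz: np.ndarray) -> np.ndarray:
    """Complex permittivity of the double-Debye model on a THz grid.

    Returns ``eps' + i eps''`` with non-negative imaginary part (loss
    convention).  ``freq_thz`` must be non-negative.
    """
    f = np.asarray(freq_thz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be >= 0")
    w = 2.0 * np.pi * f * 1e12  # rad/s
    eps = (
        params.eps_inf
        + (params.eps_static - params.eps_mid) / (1.0 - 1j * w * params.tau1)
        + (params.eps_mid - params.eps_inf) / (1.0 - 1j * w * params.tau2)
    )
    return eps


def refractive_index(eps: np.ndarray | complex) -> np.ndarray | complex:
    """Principal-branch complex refractive index n = sqrt(eps)."""
    eps = np.asarray(eps, dtype=complex)
    if np.any(eps == 0):
        raise ValueError("permittivity must be nonzero")
    return np.sqrt(eps)


def fresnel_reflection(n1, n2):
    """Normal-incidence Fresnel reflection coefficient (n1 - n2)/(n1 + n2)."""
    n1 = np.asarray(n1, dtype=complex)
    n2 = np.asarray(n2, dtype=complex)
    denom = n1 + n2
    if np.any(denom == 0):
        raise ValueError("n1 + n2 must be nonzero")
    return (n1 - n2) / denom


def tissue_permittivity(
    debye: DebyeParams, freq_thz: np.ndarray, hydration_delta: float = 0.0
) -> np.ndarray:
    """Permittivity of (possibly edematous) tissue.

    Edema scales the slow-relaxation amplitude: ``eps_s - eps_2`` is
    multiplied by ``1 + hydration_delta``, implemented by shifting
    ``eps_static`` so the double-Debye invariants keep holding.
    """
    if hydration_delta < 0:
        raise ValueError("hydration_delta must be >= 0")
    eps_static = debye.eps_mid + (1.0 + hydration_delta) * (
        debye.eps_static - debye.eps_mid
    )
    return debye_permittivity(replace(debye, eps_static=eps_static), freq_thz)


def sample_response_spectrum(
    window: WindowSpec, medium_eps: np.ndarray, freq_thz: np.ndarray
) -> np.ndarray:
    """Complex transfer function of the window-backed sample.

    Primary back-face (window-medium) reflection plus ``window.n_echoes``
    Fabry-Perot terms, each delayed by one extra internal round trip and
    attenuated by one extra back-face and front-face internal reflection:

        H(f) = t_aw t_wa * sum_{m=0}^{M} r_wm(f)^(m+1) r_int^m e^(-i 2 pi f m T)

    with T the round-trip delay, ``r_int`` the internal window-air
    front-face reflection, and ``t_aw t_wa = 4 n_w / (1 + n_w)^2`` the
    in/out transmission product.  ``medium_eps`` uses the ``eps' + i eps''``
    loss convention of :func:`debye_permittivity`; it is conjugated
    internally to match the forward-FFT delay convention.
    """
    f = np.asarray(freq_thz, dtype=float)
    eps = np.conj(np.asarray(medium_eps, dtype=complex))
    n_w = window.refractive_index
    n_m = refractive_index(eps)
    r_wm = fresnel_reflection(n_w, n_m)
    r_int = (n_w - 1.0) / (n_w + 1.0)
    t_prod = 4.0 * n_w / (1.0 + n_w) ** 2
    T = window.round_trip_ps
    # the uniform frequency grid implies the time-record length; echoes
    # delayed beyond it leave the record instead of wrapping circularly
    record_ps = np.inf
    if f.size > 1:
        record_ps = 1.0 / (f[1] - f[0])
    h = np.zeros_like(r_wm, dtype=complex)
    for m in range(window.n_echoes + 1):
        if m * T >= record_ps:
            break
        h += r_wm ** (m + 1) * r_int**m * np.exp(-2j * np.pi * f * m * T)
    return t_prod * h


def synth_reference_pulse(config: ScanConfig) -> Waveform:
    """Deterministic single-cycle incident pulse (derivative of a Gaussian).

    Peak (maximum) at ``config.pulse_delay_ps``, unit peak amplitude, zero
    DC content, amplitude spectrum covering roughly 0.1-1 THz for the
    default width.
    """
    t = config.time_axis()
    s = config.pulse_width_ps
    tc = config.pulse_delay_ps + s  # derivative-of-Gaussian max sits sigma early
    x = (tc - t) / s
    pulse = x * np.exp(0.5 * (1.0 - x**2))  # normalized to peak 1 at x = 1
    return Waveform(t, pulse, kind="reference")


def severity_to_hydration(d: float, max_delta: float = 0.35) -> float:
    """Monotone (linear by default) map from dermal burn percentage to the
    fractional increase of the slow Debye amplitude."""
    if not (0.0 <= d <= 100.0):
        raise ValueError("dermal burn percentage must lie in [0, 100]")
    return max_delta * d / 100.0


# ---------------------------------------------------------------------------
# scan assembly
# ---------------------------------------------------------------------------


def _pixel_centers_mm(config: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    px = config.pixel_size_mm
    xs = (np.arange(config.nx) + 0.5) * px
    ys = (np.arange(config.ny) + 0.5) * px
    return np.meshgrid(xs, ys)


def rasterize_disk(
    config: ScanConfig, center_mm: tuple[float, float], radius_mm: float
) -> np.ndarray:
    """Boolean (ny, nx) map of pixels whose centers lie inside the disk."""
    xg, yg = _pixel_centers_mm(config)
    return (xg - center_mm[0]) ** 2 + (yg - center_mm[1]) ** 2 <= radius_mm**2


def synth_scan(
    phantom: PhantomSpec,
    config: ScanConfig,
    window: WindowSpec,
    debye: DebyeParams,
) -> ScanCube:
    """Assemble a full scan cube from the forward model.

    Burn-site pixels carry the window-tissue response at the site's
    hydration, biopsy-disk pixels the window-air response; averaged
    Gaussian noise (sd ``noise_rms/sqrt(n_averages)``) is added per sample,
    and tissue pixels get a small multiplicative reflectivity jitter
    standing in for Mie-scattering heterogeneity.  Bit-reproducible for a
    given ``config.seed``.
    """
    from .classify import assign_severity_label  # late import: no module cycle

    rng = np.random.default_rng(config.seed)
    t = config.time_axis()
    freq = config.freq_axis()
    ny, nx, nt = config.ny, config.nx, config.nt

    # ground-truth maps ----------------------------------------------------
    hydration = np.full((ny, nx), float(phantom.background_hydration))
    rows = []
    fx, fy = config.fov_mm
    for sid, site in enumerate(phantom.burn_sites):
        cx, cy = site.center_mm
        if not (0 <= cx <= fx and 0 <= cy <= fy):
            raise ValueError(f"burn site {sid} center {site.center_mm} outside FOV")
        h = (
            site.hydration_delta
            if site.hydration_delta is not None
            else severity_to_hydration(site.dermal_burn_pct)
        )
        hydration[rasterize_disk(config, site.center_mm, site.radius_mm)] = h
        rows.append(
            dict(
                site_id=sid,
                label=assign_severity_label(site.dermal_burn_pct),
                d=site.dermal_burn_pct,
                center_x_mm=cx,
                center_y_mm=cy,
                radius_mm=site.radius_mm,
                hydration_delta=h,
            )
        )
    truth_sites = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "label",
            "d",
            "center_x_mm",
            "center_y_mm",
            "radius_mm",
            "hydration_delta",
        ],
    )

    mask = np.zeros((ny, nx), dtype=bool)
    for disk in phantom.biopsy_disks:
        r = disk.diameter_mm / 2.0
        cx, cy = disk.center_mm
        if cx - r < 0 or cy - r < 0 or cx + r > fx or cy + r > fy:
            logger.warning(
                "biopsy disk at %s extends beyond the FOV; clipping", disk.center_mm
            )
        mask |= rasterize_disk(config, disk.center_mm, r)

    # spectral forward model ----------------------------------------------
    pulse = synth_reference_pulse(config)
    E = np.fft.rfft(pulse.amplitude)
    h_air = sample_response_spectrum(window, np.ones_like(freq, dtype=complex), freq)

    spectra = np.empty((ny, nx, freq.size), dtype=complex)
    for h_value in np.unique(hydration):
        sel = (hydration == h_value) & ~mask
        if not np.any(sel):
            continue
        eps = tissue_permittivity(debye, freq, h_value)
        spectra[sel] = E * sample_response_spectrum(window, eps, freq)
    spectra[mask] = E * h_air

    # per-pixel scatter jitter on tissue pixels (air gaps are specular)
    jitter = np.ones((ny, nx))
    if config.scatter_jitter > 0:
        draw = 1.0 + rng.normal(0.0, config.scatter_jitter, size=(ny, nx))
        jitter = np.where(mask, 1.0, np.clip(draw, 0.05, None))
    waveforms = np.fft.irfft(spectra * jitter[..., None], n=nt)

    sigma = config.noise_rms / np.sqrt(config.n_averages)
    if sigma > 0:
        waveforms = waveforms + rng.normal(0.0, sigma, size=waveforms.shape)

    ref_amp = np.fft.irfft(E * h_air, n=nt)
    if sigma > 0:
        ref_amp = ref_amp + rng.normal(0.0, sigma, size=nt)
    reference = Waveform(t, ref_amp, kind="reference")

    return ScanCube(
        t=t,
        waveforms=waveforms,
        reference=reference,
        truth_sites=truth_sites,
        truth_biopsy_mask=mask,
        truth_hydration=hydration,
        config=config,
        window=window,
        debye=debye,
    )


# ---------------------------------------------------------------------------
# default phantoms (the study conditions)
# ---------------------------------------------------------------------------

#: Day-4 dermal burn percentages of the default ten-burn study:
#: four superficial partial-thickness, three deep partial-thickness,
#: three full-thickness sites.
DEFAULT_STUDY_D = (5.0, 15.0, 25.0, 35.0, 45.0, 60.0, 75.0, 85.0, 92.0, 98.0)


def single_burn_phantom(
    d: float,
    config: ScanConfig | None = None,
    radius_mm: float = 20.0,
    separation: float = 1.0,
    with_biopsy: bool = True,
) -> PhantomSpec:
    """One centered scald site filling most of the FOV, with the punch
    biopsy in the upper-right quadrant (mirroring how the scans were framed).

    ``separation`` scales the hydration contrast between severity grades
    (gamma in the signal-recovery property); labels always follow ``d``.
    """
    config = config or ScanConfig()
    fx, fy = config.fov_mm
    hyd = separation * severity_to_hydration(d)
    site = BurnSite(
        center_mm=(fx / 2, fy / 2),
        radius_mm=radius_mm,
        dermal_burn_pct=d,
        hydration_delta=hyd,
    )
    disks = ()
    if with_biopsy:
        disks = (BiopsyDisk(center_mm=(0.75 * fx, 0.25 * fy)),)
    return PhantomSpec(burn_sites=(site,), biopsy_disks=disks)


def default_study_phantoms(
    config: ScanConfig | None = None,
    d_values: Sequence[float] = DEFAULT_STUDY_D,
    separation: float = 1.0,
    radius_mm: float = 20.0,
) -> list[PhantomSpec]:
    """The default study set: one single-burn phantom per severity value."""
    return [
        single_burn_phantom(d, config, radius_mm=radius_mm, separation=separation)
        for d in d_values
    ]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def _attrs_from_dataclass(group: h5py.Group, obj) -> None:
    for f in dataclasses.fields(obj):
        group.attrs[f.name] = getattr(obj, f.name)


def save_scan(cube: ScanCube, path) -> None:
    """Write a ScanCube to the HDF5 scan container."""
    with h5py.File(path, "w") as fh:
        scan = fh.create_group("scan")
        scan.create_dataset("time_axis", data=cube.t)
        scan.create_dataset("waveforms", data=cube.waveforms)
        scan.create_dataset("reference", data=cube.reference.amplitude)
        truth = fh.create_group("truth")
        truth.create_dataset("biopsy_mask", data=cube.truth_biopsy_mask.astype(np.uint8))
        truth.create_dataset("hydration", data=cube.truth_hydration)
        sites = truth.create_group("sites")
        for col in cube.truth_sites.columns:
            data = cube.truth_sites[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            sites.create_dataset(col, data=data)
        _attrs_from_dataclass(fh.create_group("config"), cube.config)
        _attrs_from_dataclass(fh.create_group("window"), cube.window)
        _attrs_from_dataclass(fh.create_group("debye"), cube.debye)


def _dataclass_from_attrs(cls, group: h5py.Group):
    kwargs = {}
    for f in dataclasses.fields(cls):
        v = group.attrs[f.name]
        if isinstance(v, np.ndarray):
            v = tuple(v.tolist())
        elif isinstance(v, np.generic):
            v = v.item()
        kwargs[f.name] = v
    return cls(**kwargs)


def load_scan(path) -> ScanCube:
    """Read a ScanCube back from the HDF5 scan container."""
    with h5py.File(path, "r") as fh:
        config = _dataclass_from_attrs(ScanConfig, fh["config"])
        window = _dataclass_from_attrs(WindowSpec, fh["window"])
        debye = _dataclass_from_attrs(DebyeParams, fh["debye"])
        t = fh["scan/time_axis"][...]
        waveforms = fh["scan/waveforms"][...]
        reference = Waveform(t, fh["scan/reference"][...], kind="reference")
        mask = fh["truth/biopsy_mask"][...].astype(bool)
        hydration = fh["truth/hydration"][...]
        cols = {}
        for col in fh["truth/sites"]:
            data = fh[f"truth/sites/{col}"][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        truth_sites = pd.DataFrame(cols)
    return ScanCube(
        t=t,
        waveforms=waveforms,
        reference=reference,
        truth_sites=truth_sites,
        truth_biopsy_mask=mask,
        truth_hydration=hydration,
        config=config,
        window=window,
        debye=debye,
    )
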