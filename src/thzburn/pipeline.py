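"""Stage orchestration: configuration, seeds, artifacts, manifests.

A run is driven by one YAML config with a ``master_seed`` from which every
stage's randomness is derived deterministically (numpy ``SeedSequence``
spawning), so two runs with the same config produce identical observation
tables.  Each stage writes its artifacts plus a manifest (config hash,
seeds, sha256 checksums); a completed stage with an unchanged config is
skipped unless forced.

Stages
------
simulate    -> scans/burn_NN.h5            (HDF5 scan containers)
preprocess  -> spectra/burn_NN.h5          (/spectra/freq, /spectra/amplitude)
features    -> features/mask_NN.csv, image_NN.csv/.png, observations.csv
classify    -> classify/metrics.csv, roc_*.csv, summary.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import features as _features
from . import preprocess as _preprocess
from .classify import FAMILIES, EvalReport, PreprocessedBurn, evaluate_suite
from .features import BandSpec, detect_biopsy_mask, form_image
from .preprocess import NoiseWindows, SpectraCube, preprocess_scan
from .simulate import (
    DEFAULT_STUDY_D,
    DebyeParams,
    ScanConfig,
    ScanCube,
    WindowSpec,
    save_scan,
    load_scan,
    single_burn_phantom,
    synth_scan,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "classify")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulateParams:
    nx: int = 27
    ny: int = 27
    d_values: tuple[float, ...] = DEFAULT_STUDY_D
    separation: float = 1.0
    burn_radius_mm: float = 20.0
    biopsy_burns: tuple[int, ...] | None = None  # None -> every burn has a disk
    noise_rms: float = 0.01
    n_averages: int = 20
    scatter_jitter: float = 0.05
    time_window_ps: float = 204.8
    dt_ps: float = 0.05
    pulse_delay_ps: float = 50.0
    pulse_width_ps: float = 0.4


@dataclass
class PreprocessParams:
    wavelet: str = _preprocess.DEFAULT_WAVELET
    n_levels: int = _preprocess.DEFAULT_LEVELS
    pre_window_ps: tuple[float, float] = (5.0, 36.0)
    post_window_ps: tuple[float, float] = (64.0, 75.0)

    def noise_windows(self) -> NoiseWindows:
        return NoiseWindows(pre=tuple(self.pre_window_ps), post=tuple(self.post_window_ps))


@dataclass
class FeatureParams:
    f_lo_thz: float = 0.1
    f_hi_thz: float = 0.5
    k_rois: int = 15
    roi_size: int = 4

    def band(self) -> BandSpec:
        return BandSpec(f_lo=self.f_lo_thz, f_hi=self.f_hi_thz)


@dataclass
class ClassifyParams:
    families: tuple[str, ...] = FAMILIES
    n_search_evals: int = 30
    cv_folds: int = 5
    n_iterations: int = 10
    group_by_burn: bool = False


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    master_seed: int = 0
    simulate: SimulateParams = field(default_factory=SimulateParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)

    def validate(self) -> None:
        """Schema/constraint checks run before any compute."""
        self.features.band()  # raises on f_lo >= f_hi etc.
        self.preprocess.noise_windows()
        if self.classify.cv_folds < 2:
            raise ValueError("classify.cv_folds must be >= 2")
        if self.features.k_rois < 1:
            raise ValueError("features.k_rois must be >= 1")
        for fam in self.classify.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown classifier family {fam!r}")
        for i, d in enumerate(self.simulate.d_values):
            if not (0.0 <= d <= 100.0):
                raise ValueError(f"d_values[{i}]={d} outside [0, 100]")


def _tuplify(obj):
    if isinstance(obj, dict):
        return {k: _tuplify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    return obj


def config_from_dict(data: dict) -> PipelineConfig:
    data = _tuplify(data or {})
    sections = dict(
        simulate=SimulateParams,
        preprocess=PreprocessParams,
        features=FeatureParams,
        classify=ClassifyParams,
    )
    kwargs = {}
    for key, value in data.items():
        if key in sections:
            kwargs[key] = sections[key](**dict(value))
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        return obj

    return plain(cfg)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# deterministic seed derivation
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """A sub-2^31 integer seed derived from the master seed for one
    (stage, index) slot; stable across runs and platforms."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage), index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# in-memory study API (used by the stages, tests, and the acceptance script)
# ---------------------------------------------------------------------------


def build_study(cfg: PipelineConfig) -> list[ScanCube]:
    """Simulate the configured burn scans (one cube per burn)."""
    sim = cfg.simulate
    cubes = []
    for i, d in enumerate(sim.d_values):
        scan_cfg = ScanConfig(
            nx=sim.nx,
            ny=sim.ny,
            time_window_ps=sim.time_window_ps,
            dt_ps=sim.dt_ps,
            n_averages=sim.n_averages,
            noise_rms=sim.noise_rms,
            scatter_jitter=sim.scatter_jitter,
            pulse_delay_ps=sim.pulse_delay_ps,
            pulse_width_ps=sim.pulse_width_ps,
            seed=stage_seed(cfg.master_seed, "simulate", i),
        )
        with_biopsy = sim.biopsy_burns is None or i in sim.biopsy_burns
        phantom = single_burn_phantom(
            d,
            scan_cfg,
            radius_mm=sim.burn_radius_mm,
            separation=sim.separation,
            with_biopsy=with_biopsy,
        )
        cubes.append(synth_scan(phantom, scan_cfg, WindowSpec(), DebyeParams()))
    return cubes


def preprocess_study(
    cubes: list[ScanCube], cfg: PipelineConfig
) -> list[tuple[ScanCube, SpectraCube]]:
    """Denoise + deconvolve every scan; returns (denoised cube, spectra)."""
    prep = cfg.preprocess
    windows = prep.noise_windows()
    return [
        preprocess_scan(c, windows, wavelet=prep.wavelet, n_levels=prep.n_levels)
        for c in cubes
    ]


def burn_records(
    cubes: list[ScanCube],
    spectra: list[SpectraCube],
    cfg: PipelineConfig,
    masks: list[np.ndarray] | None = None,
) -> list[PreprocessedBurn]:
    """Assemble the classifier-stage inputs (masks detected if not given)."""
    prep = cfg.preprocess
    if masks is None:
        masks = [
            detect_biopsy_mask(
                c,
                windows=prep.noise_windows(),
                wavelet=prep.wavelet,
                n_levels=prep.n_levels,
            )
            for c in cubes
        ]
    return [
        PreprocessedBurn(
            burn_id=i, spectra=sp, mask=m, d=float(c.truth_sites["d"].iloc[0])
        )
        for i, (c, sp, m) in enumerate(zip(cubes, spectra, masks))
    ]


def run_study(cfg: PipelineConfig, permute_labels: bool = False) -> EvalReport:
    """Simulate-to-report in memory, honoring every config section."""
    cubes = build_study(cfg)
    pairs = preprocess_study(cubes, cfg)
    recs = burn_records(cubes, [sp for _, sp in pairs], cfg, masks=None)
    cls = cfg.classify
    return evaluate_suite(
        recs,
        families=cls.families,
        band=cfg.features.band(),
        k_rois=cfg.features.k_rois,
        roi_size=cfg.features.roi_size,
        n_iterations=cls.n_iterations,
        cv_folds=cls.cv_folds,
        n_search_evals=cls.n_search_evals,
        group_by_burn=cls.group_by_burn,
        permute_labels=permute_labels,
        seed=stage_seed(cfg.master_seed, "classify"),
    )


# ---------------------------------------------------------------------------
# file-based stages with manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, cfg: PipelineConfig, outputs: list[Path]) -> dict:
    manifest = {
        "config_hash": config_hash(cfg),
        "master_seed": cfg.master_seed,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_complete(stage_dir: Path, cfg: PipelineConfig) -> bool:
    mpath = stage_dir / "manifest.json"
    if not mpath.exists():
        return False
    with open(mpath) as fh:
        manifest = json.load(fh)
    return manifest.get("config_hash") == config_hash(cfg)


def _scan_paths(cfg: PipelineConfig, root: Path) -> list[Path]:
    return [
        root / "scans" / f"burn_{i:02d}.h5" for i in range(len(cfg.simulate.d_values))
    ]


def _run_simulate(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "scans"
    out.mkdir(parents=True, exist_ok=True)
    paths = _scan_paths(cfg, root)
    for cube, path in zip(build_study(cfg), paths):
        save_scan(cube, path)
    return paths


def _run_preprocess(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "spectra"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, scan_path in enumerate(_scan_paths(cfg, root)):
        if not scan_path.exists():
            raise FileNotFoundError(
                f"missing scan {scan_path}; run the 'simulate' stage first"
            )
        cube = load_scan(scan_path)
        _, spectra = preprocess_scan(
            cube,
            cfg.preprocess.noise_windows(),
            wavelet=cfg.preprocess.wavelet,
            n_levels=cfg.preprocess.n_levels,
        )
        path = out / f"burn_{i:02d}.h5"
        with h5py.File(path, "w") as fh:
            g = fh.create_group("spectra")
            g.create_dataset("freq", data=spectra.freq)
            g.create_dataset("amplitude", data=spectra.values)
        paths.append(path)
    return paths


def _load_spectra(path: Path) -> SpectraCube:
    with h5py.File(path, "r") as fh:
        return SpectraCube(freq=fh["spectra/freq"][...], values=fh["spectra/amplitude"][...])


def _run_features(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "features"
    out.mkdir(parents=True, exist_ok=True)
    band = cfg.features.band()
    paths = []
    spectra_by_burn, masks, d_by_burn = {}, {}, {}
    for i, scan_path in enumerate(_scan_paths(cfg, root)):
        spath = root / "spectra" / f"burn_{i:02d}.h5"
        for p, stage in ((scan_path, "simulate"), (spath, "preprocess")):
            if not p.exists():
                raise FileNotFoundError(f"missing {p}; run the '{stage}' stage first")
        cube = load_scan(scan_path)
        spectra = _load_spectra(spath)
        mask = detect_biopsy_mask(
            cube,
            windows=cfg.preprocess.noise_windows(),
            wavelet=cfg.preprocess.wavelet,
            n_levels=cfg.preprocess.n_levels,
        )
        img = form_image(spectra, band, invalid_mask=mask)
        mask_path = out / f"mask_{i:02d}.csv"
        img_path = out / f"image_{i:02d}.csv"
        np.savetxt(mask_path, mask.astype(int), fmt="%d", delimiter=",")
        np.savetxt(img_path, img, fmt="%.6f", delimiter=",")
        png_path = out / f"image_{i:02d}.png"
        _save_png_preview(img, png_path)
        paths += [mask_path, img_path, png_path]
        spectra_by_burn[i], masks[i] = spectra, mask
        d_by_burn[i] = float(cube.truth_sites["d"].iloc[0])

    # one representative observation table (iteration 0 of the classify seeds)
    rng = np.random.default_rng(stage_seed(cfg.master_seed, "features"))
    roisets = {
        i: _features.sample_rois(
            masks[i], k=cfg.features.k_rois, size=cfg.features.roi_size, rng=rng
        )
        for i in spectra_by_burn
    }
    obs = _features.build_observations(spectra_by_burn, roisets, band, d_by_burn)
    obs_path = out / "observations.csv"
    obs.to_csv(obs_path, index=False)
    paths.append(obs_path)
    return paths


def _save_png_preview(img: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(img, origin="lower", cmap="magma", vmin=0, vmax=1)
    ax.set_axis_off()
    fig.savefig(path, dpi=72, bbox_inches="tight")
    plt.close(fig)


def _run_classify(cfg: PipelineConfig, root: Path) -> list[Path]:
    out = root / "classify"
    out.mkdir(parents=True, exist_ok=True)
    cubes, spectra, masks = [], [], []
    for i, scan_path in enumerate(_scan_paths(cfg, root)):
        spath = root / "spectra" / f"burn_{i:02d}.h5"
        mpath = root / "features" / f"mask_{i:02d}.csv"
        for p, stage in (
            (scan_path, "simulate"),
            (spath, "preprocess"),
            (mpath, "features"),
        ):
            if not p.exists():
                raise FileNotFoundError(f"missing {p}; run the '{stage}' stage first")
        cubes.append(load_scan(scan_path))
        spectra.append(_load_spectra(spath))
        masks.append(np.loadtxt(mpath, delimiter=",").astype(bool))
    recs = burn_records(cubes, spectra, cfg, masks=masks)
    cls = cfg.classify
    report = evaluate_suite(
        recs,
        families=cls.families,
        band=cfg.features.band(),
        k_rois=cfg.features.k_rois,
        roi_size=cfg.features.roi_size,
        n_iterations=cls.n_iterations,
        cv_folds=cls.cv_folds,
        n_search_evals=cls.n_search_evals,
        group_by_burn=cls.group_by_burn,
        seed=stage_seed(cfg.master_seed, "classify"),
    )
    return write_report(report, out)


def write_report(report: EvalReport, out: Path) -> list[Path]:
    """Persist an EvalReport: long CSV, per-(family, class) ROC CSVs, JSON summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    metrics_path = out / "metrics.csv"
    report.results.to_csv(metrics_path, index=False)
    paths.append(metrics_path)
    for (family, target), curves in report.curves.items():
        rows = []
        for it, roc in enumerate(curves):
            for f, t in zip(roc.fpr, roc.tpr):
                rows.append(dict(iteration=it, fpr=f, tpr=t))
        p = out / f"roc_{family}_{target}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths.append(p)
    summary = {}
    for _, row in report.summary().iterrows():
        summary.setdefault(row["family"], {}).setdefault(row["class"], {})[
            row["metric"]
        ] = {"mean": row["mean"], "sd": row["std"]}
    spath = out / "summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    paths.append(spath)
    return paths


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "features": _run_features,
    "classify": _run_classify,
}


def run(stage: str, cfg: PipelineConfig, force: bool = False) -> list[Path]:
    """Run one stage (or ``"all"``); returns the artifact paths written.

    A stage whose manifest matches the current config hash is skipped
    unless ``force`` is set.
    """
    cfg.validate()
    root = Path(cfg.output_dir)
    stages = STAGES if stage == "all" else (stage,)
    if any(s not in STAGES for s in stages):
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    written: list[Path] = []
    for s in stages:
        stage_dir = root / {"simulate": "scans", "preprocess": "spectra"}.get(s, s)
        if not force and _stage_complete(stage_dir, cfg):
            logger.info("stage %s up to date; skipping (use force to rerun)", s)
            continue
        logger.info("running stage %s", s)
        outputs = _STAGE_RUNNERS[s](cfg, root)
        stage_dir.mkdir(parents=True, exist_ok=True)
        _write_manifest(stage_dir, cfg, outputs)
        written.extend(outputs)
    return written


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def tiny_config(output_dir: str = "out_tiny", master_seed: int = 0) -> PipelineConfig:
    """The tiny study: three 9x9 single-burn scans (one per severity class,
    the first carrying the 4-mm biopsy disk), 3 ROIs x 3 iterations,
    threefold CV.  Runs the whole suite in well under a minute per family.
    """
    return PipelineConfig(
        output_dir=output_dir,
        master_seed=master_seed,
        simulate=SimulateParams(
            nx=9, ny=9, d_values=(20.0, 60.0, 90.0), burn_radius_mm=5.0, biopsy_burns=(0,)
        ),
        features=FeatureParams(k_rois=3),
        classify=ClassifyParams(n_search_evals=8, cv_folds=3, n_iterations=3),
    )


def make_fixtures(size: str = "tiny", root: str | Path = "fixtures") -> Path:
    """Generate a self-contained fixture run directory with its config."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        cfg = tiny_config(output_dir=str(root / "tiny"))
    elif size == "default":
        cfg = PipelineConfig(output_dir=str(root / "default"))
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    cfg_path = root / f"{size}.yaml"
    save_config(cfg, cfg_path)
    run("simulate", cfg)
    return cfg_path
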