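"""End-to-end workflows: simulate, fit, glider benchmark, lasso, stats.

Each workflow takes a :class:`RunConfig`, writes its outputs under the
configured directory, and drops a ``*_config.json`` beside them containing
the fully resolved configuration plus SHA-256 hashes of the files the run
produced or consumed, so every result is traceable to its inputs.

Defaults are the desk-scale study conditions: 1000 synthetic panoramas,
10^4 mirror pairs, velocity SD 90 deg/s, and the standard photoreceptor
and filter constants (Gaussian FWHM 5.7 deg, receptor spacing 5.1 deg,
photoreceptor time constant 10 ms, correlator tau 20 ms, dt 5 ms, clip
duration 800 ms).  ``paper_scale=True`` raises the ensemble to the
5 x 10^5-pair size used for the published-quality fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import PhotoreceptorConfig, build_ensemble, load_ensemble, save_ensemble
from .filters import make_kernels, ensemble_readout
from .fitting import lasso_scan, ols_fit
from .gliders import GliderProtocol, glider_response
from .imagery import SynthImageParams, load_images, synth_image_ensemble
from .models import EstimatorModel, predictor_count, predictor_matrix
from .stats import moment_report, spatial_covariance

__all__ = ["RunConfig", "run_simulate", "run_fit", "run_glider", "run_lasso", "run_stats"]

log = logging.getLogger("emdkit")

#: ordered subsets of the model hierarchy; earlier entries are weight
#: subspaces of later ones, so training accuracy must not decrease
NESTED_CHAIN = ("hrc", "quadrant", "poly4", "poly6")


@dataclass
class RunConfig:
    """Resolved configuration for a reproducible run."""

    # image source: path to an Image1D collection, or synthetic parameters
    image_path: str | None = None
    synth: SynthImageParams = field(default_factory=lambda: SynthImageParams(
        spectral_slope=1.0, asymmetry=0.35, target_kurtosis=8.0, seed=0
    ))
    n_images: int = 1000
    n_motions: int = 10_000  # mirror pairs; the stored ensemble has twice as many clips
    seed: int = 0
    velocity_sd: float = 90.0
    photoreceptor: PhotoreceptorConfig = field(default_factory=PhotoreceptorConfig)
    filter_tau: float = 0.020
    models: tuple[str, ...] = ("hrc", "hrc+conv3", "quadrant", "poly2", "poly4", "poly6")
    n_splits: int = 20
    glider: GliderProtocol = field(default_factory=GliderProtocol)
    outdir: str = "runs"
    paper_scale: bool = False

    def __post_init__(self):
        if self.paper_scale:
            self.n_motions = 500_000

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        kwargs = dict(raw)
        if "synth" in kwargs:
            kwargs["synth"] = SynthImageParams(**kwargs["synth"])
        if "photoreceptor" in kwargs:
            kwargs["photoreceptor"] = PhotoreceptorConfig(**kwargs["photoreceptor"])
        if "glider" in kwargs:
            kwargs["glider"] = GliderProtocol(**kwargs["glider"])
        if "models" in kwargs:
            kwargs["models"] = tuple(kwargs["models"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(outdir: Path, name: str, config: RunConfig, files: list[Path]) -> None:
    record = {
        "config": config.to_dict(),
        "files": {str(p.name): _sha256(p) for p in files if p.exists()},
    }
    (outdir / f"{name}_config.json").write_text(json.dumps(record, indent=1))


def _load_or_synth_images(config: RunConfig):
    if config.image_path is not None:
        images = load_images(config.image_path)
        if not images:
            raise ValueError(f"no images found at {config.image_path}")
        return images
    return synth_image_ensemble(config.synth, config.n_images)


def run_simulate(config: RunConfig) -> Path:
    """Build and store the mirror-symmetrized naturalistic ensemble."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = _load_or_synth_images(config)
    ens = build_ensemble(
        images, config.n_motions, seed=config.seed,
        cfg=config.photoreceptor, velocity_sd=config.velocity_sd,
    )
    path = outdir / "ensemble.h5"
    save_ensemble(ens, path)
    manifest = pd.DataFrame(
        {"image_ref": ens.image_refs, "velocity": ens.velocities, "offset": ens.offsets}
    )
    manifest_path = outdir / "ensemble_manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    log.info(
        "simulated %d clips from %d images; realized velocity SD %.2f deg/s",
        len(ens), len(images), float(ens.velocities.std()),
    )
    _write_provenance(outdir, "simulate", config, [path, manifest_path])
    return path


def run_fit(config: RunConfig, ensemble_path: str | Path | None = None) -> pd.DataFrame:
    """Fit every requested architecture and tabulate cross-validated accuracy."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = Path(ensemble_path) if ensemble_path else outdir / "ensemble.h5"
    if not path.exists():
        raise FileNotFoundError(f"no ensemble at {path}; run simulate first")
    ens = load_ensemble(path)
    kernels = make_kernels(tau=config.filter_tau, dt=ens.cfg.dt)
    F = ensemble_readout(ens, kernels)
    v = ens.velocities

    rows = []
    train_r = {}
    for arch in config.models:
        X = predictor_matrix(arch, F)
        fit = ols_fit(X, v, n_splits=config.n_splits, seed=config.seed)
        train_r[arch] = fit.r_train
        rows.append(
            {
                "architecture": arch,
                "n_predictors": predictor_count(arch),
                "r_test": fit.r_test,
                "accuracy_sd": fit.accuracy_sd,
                "r_train": fit.r_train,
                "mse_test": fit.mse_test,
            }
        )
        model = EstimatorModel(architecture=arch, weights=fit.weights, scale=fit.scale)
        model.save(outdir / f"model_{arch.replace('+', '_')}.json")

    chain = [a for a in NESTED_CHAIN if a in train_r]
    for lo, hi in zip(chain, chain[1:]):
        if train_r[hi] < train_r[lo] - 1e-9:
            raise AssertionError(
                f"nesting violated: training r of {hi} ({train_r[hi]:.4f}) fell below "
                f"{lo} ({train_r[lo]:.4f})"
            )

    table = pd.DataFrame(rows)
    table_path = outdir / "accuracy_table.csv"
    table.to_csv(table_path, index=False)
    _write_provenance(outdir, "fit", config, [path, table_path])
    return table


def run_glider(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Glider response tables for every fitted model found in the run directory."""
    outdir = Path(config.outdir)
    model_files = sorted(outdir.glob("model_*.json"))
    if not model_files:
        raise FileNotFoundError(f"no fitted models in {outdir}; run fit first")
    tables = {}
    written = []
    for mf in model_files:
        model = EstimatorModel.load(mf)
        table = glider_response(model, protocol=config.glider, cfg=config.photoreceptor)
        frame = table.to_frame()
        out = outdir / f"glider_{mf.stem.removeprefix('model_')}.csv"
        frame.to_csv(out, index=False)
        tables[mf.stem.removeprefix("model_")] = frame
        written.append(out)
    _write_provenance(outdir, "glider", config, written)
    return tables


def run_lasso(config: RunConfig, architecture: str = "poly6") -> pd.DataFrame:
    """Penalty sweep with OLS refits over one architecture's predictors."""
    outdir = Path(config.outdir)
    path = outdir / "ensemble.h5"
    if not path.exists():
        raise FileNotFoundError(f"no ensemble at {path}; run simulate first")
    ens = load_ensemble(path)
    kernels = make_kernels(tau=config.filter_tau, dt=ens.cfg.dt)
    F = ensemble_readout(ens, kernels)
    v = ens.velocities
    r_hrc = ols_fit(predictor_matrix("hrc", F), v, n_splits=1, seed=config.seed).r_test
    scan = lasso_scan(
        predictor_matrix(architecture, F), v, seed=config.seed, r_baseline=r_hrc
    )
    frame = scan.to_frame()
    out = outdir / f"lasso_{architecture}.csv"
    frame.to_csv(out, index=False)
    _write_provenance(outdir, "lasso", config, [out])
    return frame


def run_stats(config: RunConfig) -> dict:
    """Moment report and spatial covariance of the configured image source."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = _load_or_synth_images(config)
    arr = np.stack([im.contrast for im in images])
    report = moment_report(arr)
    cov = spatial_covariance(arr, max_lag=30.0, pixel_pitch=images[0].pixel_pitch)
    (outdir / "image_moments.json").write_text(json.dumps(report.to_dict(), indent=1))
    pd.DataFrame({"lag_deg": np.arange(cov.size), "covariance": cov}).to_csv(
        outdir / "spatial_covariance.csv", index=False
    )
    _write_provenance(
        outdir, "stats", config,
        [outdir / "image_moments.json", outdir / "spatial_covariance.csv"],
    )
    return report.to_dict()
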