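"""End-to-end pipeline: simulate → preprocess → cluster → render.

Each stage is a plain function over a validated :class:`PipelineConfig`;
the command line in :mod:`msiseg.cli` is a thin wrapper. Stages exchange
documented artifacts in the output directory (HDF5 bundle, HDF5 profile
matrix, CSV tables, NPZ model, PNG rasters, JSON export), so a monolithic
run and a sequence of standalone stage runs produce byte-identical output
for the same global seed. All stage randomness derives deterministically
from that one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import h2som, preprocess, viz
from .io import (
    MSIDataset,
    default_background_mz,
    default_peak_list,
    load_peak_list,
    read_bundle,
    write_bundle,
)
from .phantom import PhantomSpec, generate_phantom_series

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_cluster",
    "stage_render",
    "derive_stage_seed",
]

log = logging.getLogger(__name__)

_STAGE_INDEX = {"simulate": 0, "cluster": 1}


def derive_stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global one."""
    ss = np.random.SeedSequence([abs(int(seed)) % (2 ** 31),
                                 _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    n_time_points: int = 8
    grid_shape: tuple[int, int] = (80, 40)
    drift_range: tuple[float, float] = (-0.3, 0.3)
    drift_per_dataset: list[float] | None = None
    noise_sigma2: float = 4.0
    gain_sigma: float = 0.25

    def to_spec(self) -> PhantomSpec:
        return PhantomSpec(n_time_points=self.n_time_points,
                           grid_shape=tuple(self.grid_shape),
                           drift_range=tuple(self.drift_range),
                           drift_per_dataset=self.drift_per_dataset,
                           noise_sigma2=self.noise_sigma2,
                           gain_sigma=self.gain_sigma)


class InputSection(_Section):
    bundle: str | None = None
    phantom: PhantomSection | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.bundle is None) == (self.phantom is None):
            raise ValueError(
                "input needs exactly one of 'bundle' or 'phantom'")
        return self


class PreprocessSection(_Section):
    bin_width: float = preprocess.DEFAULT_BIN_WIDTH
    recal_cutoff_da: float = preprocess.DEFAULT_RECAL_CUTOFF_DA
    recal_passes: list[str] = list(preprocess.RECAL_PASSES)
    background_ref_mz: list[float] | None = None
    background_r_threshold: float = 0.9
    ve_filter_enabled: bool = True
    peak_list: str | None = None


class H2SOMSection(_Section):
    n_rings: int = 3
    beam_width: int = 2
    iters_per_level: int | None = None
    learning_rate: tuple[float, float] = (0.5, 0.01)
    neighborhood: tuple[float, float] = (0.2, 0.05)

    def to_params(self) -> h2som.H2SOMParams:
        return h2som.H2SOMParams(
            n_rings=self.n_rings, beam_width=self.beam_width,
            iters_per_level=self.iters_per_level,
            learning_rate=tuple(self.learning_rate),
            neighborhood=tuple(self.neighborhood))


class VizSection(_Section):
    levels: list[int] = [1, 2, 3]
    rotation: float = 0.0


class PipelineConfig(_Section):
    input: InputSection
    preprocess: PreprocessSection = PreprocessSection()
    h2som: H2SOMSection = H2SOMSection()
    viz: VizSection = VizSection()
    seed: int = 0


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _update_log(outdir: Path, config: PipelineConfig, seed: int,
                stage: str, payload: dict) -> None:
    path = outdir / "run_log.json"
    data = {}
    if path.exists():
        data = json.loads(path.read_text())
    data.setdefault("config_sha256", _config_hash(config))
    data.setdefault("seed", int(seed))
    data.setdefault("versions", {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    })
    data.setdefault("stages", {})
    data["stages"][stage] = payload
    path.write_text(json.dumps(data, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing upstream artifact: {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, seed: int, outdir: Path) -> Path:
    """Generate the phantom series and write the bundle plus ground truth."""
    if config.input.phantom is None:
        raise ValueError("simulate stage requires a phantom input section")
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.input.phantom.to_spec()
    datasets, truth = generate_phantom_series(
        spec, derive_stage_seed(seed, "simulate"))
    bundle = outdir / "bundle.h5"
    write_bundle(datasets, bundle)
    (outdir / "truth.json").write_text(json.dumps({
        "seed": truth.seed,
        "drift_da": {str(t): d for t, d in truth.drift.items()},
        "regions": sorted(truth.profile_table.index),
    }, indent=2))
    masks_dir = outdir / "masks"
    masks_dir.mkdir(exist_ok=True)
    from PIL import Image

    region_codes = {"background": 0, "whole seed": 1, "endosperm": 2,
                    "embryo": 3, "unlabeled": 4}
    for t, mask in truth.masks.items():
        coded = np.vectorize(region_codes.get)(mask).astype(np.uint8)
        Image.fromarray(coded, mode="L").save(masks_dir / f"mask_t{t}.png")
    _update_log(outdir, config, seed, "simulate", {
        "n_datasets": len(datasets),
        "spectra": int(sum(d.n_spectra for d in datasets)),
    })
    return bundle


def _load_datasets(config: PipelineConfig, outdir: Path,
                   stage: str) -> list[MSIDataset]:
    if config.input.bundle is not None:
        return read_bundle(_require(Path(config.input.bundle), stage))
    return read_bundle(_require(outdir / "bundle.h5", stage))


def stage_preprocess(config: PipelineConfig, seed: int, outdir: Path) -> Path:
    """Run the preprocessing chain and persist X* plus reports."""
    outdir.mkdir(parents=True, exist_ok=True)
    datasets = _load_datasets(config, outdir, "preprocess")
    if sum(d.n_spectra for d in datasets) == 0:
        raise ValueError("preprocess: bundle contains no spectra")
    pc = config.preprocess
    peaks = (load_peak_list(pc.peak_list) if pc.peak_list
             else default_peak_list())
    bg = pc.background_ref_mz
    if bg is None:
        ref = default_background_mz()
        bg = ref["matrix"] + ref["tape"]
    result = preprocess.run_preprocessing(
        datasets, peaks,
        bin_width=pc.bin_width,
        recal_cutoff_da=pc.recal_cutoff_da,
        recal_passes=tuple(pc.recal_passes),
        background_ref_mz=bg,
        background_r_threshold=pc.background_r_threshold,
        ve_filter_enabled=pc.ve_filter_enabled)

    result.report.to_csv(outdir / "recalibration.csv")
    profiles = result.profiles
    path = outdir / "profiles.h5"
    with h5py.File(path, "w") as f:
        f.attrs["axis_start"] = result.binned.axis_start
        f.attrs["bin_width"] = result.binned.bin_width
        f.create_dataset("matrix", data=profiles.matrix)
        f.create_dataset("feature_mz", data=profiles.feature_mz)
        f.create_dataset("feature_bins", data=profiles.feature_bins)
        f.create_dataset("feature_labels", data=np.array(
            [s.encode() for s in profiles.feature_labels]))
        for col in ("t", "x", "y"):
            f.create_dataset(f"index_{col}",
                             data=profiles.index[col].to_numpy())
        f.create_dataset("index_r", data=np.array(
            [s.encode() for s in profiles.index["r"]]))
    info = result.informative
    (outdir / "informative.json").write_text(json.dumps({
        "ve_threshold": info.ve_threshold,
        "n_retained_bins": int(len(info.retained_bins)),
        "counts": {k: int(v) for k, v in result.counts.items()},
    }, indent=2))
    _update_log(outdir, config, seed, "preprocess", result.counts)
    return path


def _load_profiles(path: Path) -> preprocess.PeakProfileSet:
    with h5py.File(path, "r") as f:
        index = pd.DataFrame({
            "t": f["index_t"][()],
            "r": [s.decode() for s in f["index_r"][()]],
            "x": f["index_x"][()],
            "y": f["index_y"][()]})
        return preprocess.PeakProfileSet(
            feature_mz=f["feature_mz"][()],
            feature_labels=[s.decode() for s in f["feature_labels"][()]],
            feature_bins=f["feature_bins"][()],
            matrix=f["matrix"][()],
            index=index)


def stage_cluster(config: PipelineConfig, seed: int, outdir: Path) -> Path:
    """Train the H2SOM on X* and export the model and assignments."""
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = _load_profiles(
        _require(outdir / "profiles.h5", "cluster"))
    params = config.h2som.to_params()
    model = h2som.train(profiles, params=params,
                        seed=derive_stage_seed(seed, "cluster"))
    model.save(outdir / "model.npz")
    assignment = h2som.assign(model, profiles, level=model.lattice.n_rings)
    assignment.to_frame().to_csv(outdir / "assignments.csv", index=False)
    _update_log(outdir, config, seed, "cluster", {
        "profiles": int(profiles.n_profiles),
        "features": int(profiles.n_features),
        "nodes": int(model.lattice.n_nodes),
    })
    return outdir / "assignments.csv"


def stage_render(config: PipelineConfig, seed: int, outdir: Path) -> Path:
    """Render cluster maps per dataset and level; write the JSON export."""
    outdir.mkdir(parents=True, exist_ok=True)
    model = h2som.H2SOMModel.load(
        _require(outdir / "model.npz", "render"))
    table = pd.read_csv(_require(outdir / "assignments.csv", "render"))
    datasets = _load_datasets(config, outdir, "render")
    n_rings = model.lattice.n_rings
    ancestors = np.column_stack(
        [np.zeros(len(table), dtype=np.int64)]
        + [table[f"level{k}_id"].to_numpy() for k in range(1, n_rings + 1)])
    assignment = h2som.ClusterAssignment(
        leaf_ids=table["leaf_id"].to_numpy(),
        ancestors=ancestors,
        index=table[["t", "r", "x", "y"]],
        n_rings=n_rings)
    positions = viz.poincare_positions(model.lattice)
    cmap = viz.colorize(positions, rotation=config.viz.rotation)
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    written = []
    for ds in datasets:
        for level in config.viz.levels:
            seg = viz.render_cluster_map(assignment, cmap, ds, level)
            p = maps_dir / f"map_t{ds.time_point}_level{level}.png"
            seg.save_png(p)
            written.append(p.name)
    for level in config.viz.levels:
        profile_table = viz.export_cluster_profiles(model, assignment, level)
        profile_table.to_csv(outdir / f"cluster_profiles_level{level}.csv",
                             index=False)
    viz.export_json(outdir / "viewer_export.json", model, cmap, assignment)
    _update_log(outdir, config, seed, "render", {"maps": written})
    return maps_dir


_STAGES = ("simulate", "preprocess", "cluster", "render")


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None
                 ) -> Path:
    """Run every stage in order; equals running the stages standalone."""
    outdir = Path(outdir)
    if seed is None:
        seed = config.seed
    if config.input.phantom is not None:
        stage_simulate(config, seed, outdir)
    stage_preprocess(config, seed, outdir)
    stage_cluster(config, seed, outdir)
    stage_render(config, seed, outdir)
    return outdir
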