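"""Reading and writing MSI datasets, region masks, peak lists and bundles.

The on-disk formats are imzML 1.1 (continuous and processed mode, via
pyimzml), region masks as CSV ``(x, y, label)`` tables or indexed PNG
rasters, target peak lists as TSV, and an internal HDF5 "bundle" that stores
a whole multi-time-point series with labels for fast random access.

Internal conventions: pixel coordinates are 0-based with ``x`` the column
and ``y`` the row (imzML's 1-based coordinates are shifted on read), and
spectra are kept in row-major order over ``(y, x)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LABEL_EMBRYO",
    "LABEL_ENDOSPERM",
    "LABEL_WHOLE_SEED",
    "LABEL_BACKGROUND",
    "LABEL_UNLABELED",
    "REGION_PRECEDENCE",
    "FOREGROUND_LABELS",
    "RawSpectrum",
    "MSIDataset",
    "TargetPeakList",
    "read_imzml",
    "write_imzml",
    "attach_region_masks",
    "load_mask_csv",
    "load_mask_png",
    "write_bundle",
    "read_bundle",
    "bundle_roundtrip",
    "load_peak_list",
    "default_peak_list",
    "default_background_mz",
    "BundleReadError",
]

LABEL_EMBRYO = "embryo"
LABEL_ENDOSPERM = "endosperm"
LABEL_WHOLE_SEED = "whole seed"
LABEL_BACKGROUND = "background"
LABEL_UNLABELED = "unlabeled"

#: Overlap resolution order for region masks: first entry wins.
REGION_PRECEDENCE = (LABEL_EMBRYO, LABEL_ENDOSPERM, LABEL_WHOLE_SEED,
                     LABEL_BACKGROUND)
ALLOWED_LABELS = REGION_PRECEDENCE + (LABEL_UNLABELED,)

#: Labels whose spectra take part in the analysis (regions of interest).
FOREGROUND_LABELS = frozenset(
    (LABEL_EMBRYO, LABEL_ENDOSPERM, LABEL_WHOLE_SEED))

_LABEL_DTYPE = "U16"


class BundleReadError(IOError):
    """Raised when an HDF5 bundle cannot be read (corrupt or truncated)."""


@dataclass
class RawSpectrum:
    """A single mass spectrum recorded at one raster pixel.

    ``mz_values`` must be strictly ascending and ``intensities`` non-negative
    with matching length; ``pixel`` is the 0-based ``(x, y)`` grid position.
    """

    mz_values: np.ndarray
    intensities: np.ndarray
    pixel: tuple[int, int]

    def validate(self) -> None:
        if len(self.mz_values) != len(self.intensities):
            raise ValueError(
                f"pixel {self.pixel}: m/z and intensity lengths differ")
        if len(self.mz_values) and np.any(np.diff(self.mz_values) <= 0):
            raise ValueError(
                f"pixel {self.pixel}: m/z values are not strictly ascending")
        if len(self.intensities) and np.min(self.intensities) < 0:
            raise ValueError(f"pixel {self.pixel}: negative intensity")


@dataclass
class MSIDataset:
    """One 2D MSI acquisition: spectra on a grid plus per-pixel region labels.

    ``grid_shape`` is ``(nx, ny)``; ``labels`` is a ``(ny, nx)`` array of
    region names drawn from :data:`ALLOWED_LABELS`. Spectra are stored in
    row-major ``(y, x)`` order.
    """

    time_point: int
    spectra: list[RawSpectrum]
    grid_shape: tuple[int, int]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        nx, ny = self.grid_shape
        if self.labels is None:
            self.labels = np.full((ny, nx), LABEL_UNLABELED,
                                  dtype=_LABEL_DTYPE)
        for s in self.spectra:
            x, y = s.pixel
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError(
                    f"pixel {s.pixel} outside grid {self.grid_shape}")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def label_of(self, x: int, y: int) -> str:
        return str(self.labels[y, x])


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def read_imzml(path: str | os.PathLike) -> MSIDataset:
    """Read an imzML file (continuous or processed mode) into a dataset.

    Coordinates are shifted from imzML's 1-based to 0-based convention and
    spectra sorted row-major over ``(y, x)``. All labels start out
    ``unlabeled``; attach masks with :func:`attach_region_masks`.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    try:
        nx = parser.imzmldict.get("max count of pixels x", 0)
        ny = parser.imzmldict.get("max count of pixels y", 0)
        records = []
        for i, (cx, cy, _cz) in enumerate(parser.coordinates):
            mzs, ints = parser.getspectrum(i)
            records.append((int(cx) - 1, int(cy) - 1,
                            np.asarray(mzs, dtype=float),
                            np.asarray(ints, dtype=float)))
    finally:
        if parser.m is not None:
            parser.m.close()
    if not records:
        raise ValueError(f"{path}: imzML file contains no spectra")
    if not nx:
        nx = max(r[0] for r in records) + 1
    if not ny:
        ny = max(r[1] for r in records) + 1
    records.sort(key=lambda r: (r[1], r[0]))
    spectra = []
    for x, y, mzs, ints in records:
        s = RawSpectrum(mzs, ints, (x, y))
        s.validate()
        spectra.append(s)
    return MSIDataset(time_point=0, spectra=spectra, grid_shape=(nx, ny))


def write_imzml(ds: MSIDataset, path: str | os.PathLike,
                mode: str = "auto") -> None:
    """Write a dataset as imzML (+ .ibd); coordinates become 1-based.

    ``mode`` is ``"continuous"``, ``"processed"`` or ``"auto"`` (continuous
    iff every spectrum shares one m/z axis). Labels are not representable in
    imzML and are dropped; use the bundle format to keep them.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode == "auto":
        shared = all(
            np.array_equal(s.mz_values, ds.spectra[0].mz_values)
            for s in ds.spectra[1:])
        mode = "continuous" if shared else "processed"
    with ImzMLWriter(str(path), mode=mode) as writer:
        for s in ds.spectra:
            x, y = s.pixel
            writer.addSpectrum(s.mz_values, s.intensities, (x + 1, y + 1))


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

def load_mask_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Load a mask table with columns ``x, y, label``."""
    table = pd.read_csv(path)
    missing = {"x", "y", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: mask table missing columns {missing}")
    return table[["x", "y", "label"]]


def load_mask_png(path: str | os.PathLike,
                  palette: dict[int, str]) -> pd.DataFrame:
    """Load an indexed PNG mask; ``palette`` maps pixel value -> label."""
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel (indexed)")
    ys, xs = np.nonzero(np.isin(arr, list(palette)))
    labels = [palette[int(arr[y, x])] for x, y in zip(xs, ys)]
    return pd.DataFrame({"x": xs, "y": ys, "label": labels})


def attach_region_masks(
        ds: MSIDataset,
        masks: pd.DataFrame | dict[str, np.ndarray]) -> MSIDataset:
    """Return a copy of ``ds`` with region labels set from masks.

    ``masks`` is either a table with columns ``x, y, label`` or a mapping
    ``label -> (ny, nx) boolean raster``. Pixels claimed by several regions
    resolve by the fixed precedence embryo > endosperm > whole seed >
    background; unclaimed pixels keep their current label.
    """
    nx, ny = ds.grid_shape
    per_label: dict[str, np.ndarray] = {}
    if isinstance(masks, dict):
        for label, raster in masks.items():
            if label not in ALLOWED_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            raster = np.asarray(raster, dtype=bool)
            if raster.shape != (ny, nx):
                raise ValueError(
                    f"mask for {label!r} has shape {raster.shape}, "
                    f"expected {(ny, nx)}")
            per_label[label] = raster
    else:
        bad = set(masks["label"]) - set(ALLOWED_LABELS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        for label, sub in masks.groupby("label"):
            raster = np.zeros((ny, nx), dtype=bool)
            xs = sub["x"].to_numpy(dtype=int)
            ys = sub["y"].to_numpy(dtype=int)
            if xs.size and (xs.min() < 0 or xs.max() >= nx
                            or ys.min() < 0 or ys.max() >= ny):
                raise ValueError(
                    f"mask for {label!r} has coordinates outside the "
                    f"{(nx, ny)} grid")
            raster[ys, xs] = True
            per_label[str(label)] = raster

    labels = ds.labels.copy()
    # Apply lowest precedence first so higher precedence overwrites.
    for label in reversed(REGION_PRECEDENCE):
        if label in per_label:
            labels[per_label[label]] = label
    return MSIDataset(time_point=ds.time_point, spectra=ds.spectra,
                      grid_shape=ds.grid_shape, labels=labels)


# ---------------------------------------------------------------------------
# HDF5 bundle
# ---------------------------------------------------------------------------
# Layout: one group per dataset, /dataset_<t>/{mz, intensity, offsets,
# coords, labels} with grid shape and time point as group attributes.
# Spectra are ragged; mz/intensity are concatenated with CSR-style offsets.

def write_bundle(datasets: list[MSIDataset], path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "msiseg-bundle"
        f.attrs["n_datasets"] = len(datasets)
        f.attrs["order"] = [ds.time_point for ds in datasets]
        for ds in datasets:
            g = f.create_group(f"dataset_{ds.time_point}")
            g.attrs["time_point"] = ds.time_point
            g.attrs["grid_shape"] = ds.grid_shape
            mz = np.concatenate([s.mz_values for s in ds.spectra]) \
                if ds.spectra else np.empty(0)
            inten = np.concatenate([s.intensities for s in ds.spectra]) \
                if ds.spectra else np.empty(0)
            offsets = np.zeros(len(ds.spectra) + 1, dtype=np.int64)
            np.cumsum([len(s.mz_values) for s in ds.spectra],
                      out=offsets[1:])
            coords = np.array([s.pixel for s in ds.spectra],
                              dtype=np.int32).reshape(-1, 2)
            g.create_dataset("mz", data=mz)
            g.create_dataset("intensity", data=inten)
            g.create_dataset("offsets", data=offsets)
            g.create_dataset("coords", data=coords)
            g.create_dataset(
                "labels", data=np.char.encode(ds.labels, "utf-8"))


def read_bundle(path: str | os.PathLike) -> list[MSIDataset]:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise BundleReadError(f"{path}: cannot open bundle: {exc}") from exc
    datasets = []
    with f:
        order = list(f.attrs.get("order", []))
        names = [f"dataset_{t}" for t in order] if order else sorted(f.keys())
        for name in names:
            try:
                g = f[name]
                mz = g["mz"][()]
                inten = g["intensity"][()]
                offsets = g["offsets"][()]
                coords = g["coords"][()]
                labels = np.char.decode(g["labels"][()], "utf-8") \
                    .astype(_LABEL_DTYPE)
                t = int(g.attrs["time_point"])
                grid_shape = tuple(int(v) for v in g.attrs["grid_shape"])
            except (KeyError, OSError) as exc:
                raise BundleReadError(
                    f"{path}: dataset {name!r} unreadable: {exc}") from exc
            spectra = [
                RawSpectrum(mz[offsets[i]:offsets[i + 1]],
                            inten[offsets[i]:offsets[i + 1]],
                            (int(coords[i, 0]), int(coords[i, 1])))
                for i in range(len(coords))
            ]
            datasets.append(MSIDataset(time_point=t, spectra=spectra,
                                       grid_shape=grid_shape, labels=labels))
    return datasets


def bundle_roundtrip(datasets: list[MSIDataset],
                     path: str | os.PathLike) -> list[MSIDataset]:
    """Write ``datasets`` to ``path`` and read them back."""
    write_bundle(datasets, path)
    return read_bundle(path)


# ---------------------------------------------------------------------------
# target peak list
# ---------------------------------------------------------------------------

@dataclass
class TargetPeakList:
    """Curated target features: m/z, label, compound class, near-isobar flag.

    The table is sorted by m/z; labels are unique. Entries flagged as
    duplicates sit within one bin width of another target and are expected
    to collapse during feature selection.
    """

    table: pd.DataFrame

    @property
    def mz(self) -> np.ndarray:
        return self.table["mz"].to_numpy(dtype=float)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def flagged(self) -> np.ndarray:
        return self.table["flagged_duplicate"].to_numpy(dtype=bool)

    def __len__(self) -> int:
        return len(self.table)


_PEAK_COLUMNS = ["mz", "label", "class", "flagged_duplicate"]
_PEAK_CLASSES = {"oligosaccharide", "lipid", "secondary", "unknown"}


def load_peak_list(path: str | os.PathLike) -> TargetPeakList:
    """Load a TSV peak list with columns mz/label/class/flagged_duplicate."""
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise ValueError(f"{path}: peak list is empty")
    missing = set(_PEAK_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: peak list missing columns {missing}")
    table = table[_PEAK_COLUMNS].copy()
    mz = pd.to_numeric(table["mz"], errors="coerce")
    if mz.isna().any():
        bad = table.loc[mz.isna(), "mz"].iloc[0]
        raise ValueError(f"{path}: non-numeric m/z value {bad!r}")
    table["mz"] = mz.astype(float)
    if table["flagged_duplicate"].dtype == object:
        table["flagged_duplicate"] = (
            table["flagged_duplicate"].astype(str).str.lower()
            .map({"true": True, "false": False, "1": True, "0": False}))
    table["flagged_duplicate"] = table["flagged_duplicate"].astype(bool)
    bad_cls = set(table["class"]) - _PEAK_CLASSES
    if bad_cls:
        raise ValueError(f"{path}: unknown peak classes {sorted(bad_cls)}")
    table = table.drop_duplicates()
    dup = table.duplicated("mz", keep=False)
    if dup.any():
        mzs = sorted(table.loc[dup, "mz"].unique())
        raise ValueError(
            f"{path}: identical m/z with different annotations: {mzs}")
    if table["label"].duplicated().any():
        raise ValueError(f"{path}: duplicate labels with different m/z")
    table = table.sort_values("mz", kind="stable").reset_index(drop=True)
    return TargetPeakList(table)


def default_peak_list() -> TargetPeakList:
    """The shipped target list (detected compounds; see package data)."""
    with resources.as_file(
            resources.files("msiseg") / "data" / "target_peaks.tsv") as p:
        return load_peak_list(p)


def default_background_mz() -> dict[str, list[float]]:
    """Shipped DHB-matrix and adhesive-tape reference m/z values."""
    import yaml

    text = (resources.files("msiseg") / "data" /
            "background_mz.yaml").read_text()
    data = yaml.safe_load(text)
    return {"matrix": [float(v) for v in data["matrix"]],
            "tape": [float(v) for v in data["tape"]]}
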