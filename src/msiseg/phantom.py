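"""Synthetic multi-time-point MSI phantom with full ground truth.

The phantom emulates the structure of a germinating-seed imaging series:
an elliptical seed on a background, containing an endosperm ellipse and an
embryo lobe whose area grows with the time point. Each region carries its
own metabolite profile over the shipped target features; sodium/potassium
adduct pairs of the same compound are weighted complementarily along a
radial gradient inside the endosperm (their sum is spatially flat while
each adduct alone shows a gradient). On top of the regional signal the
generator adds DHB-matrix-like ions in every pixel, tape-like ions in
background pixels only, a handful of unstructured pure-noise channels, a
per-pixel log-normal gain factor, heteroscedastic Gaussian noise with
variance proportional to the mean (truncated at zero), and a per-dataset
translation of the m/z axis (drift).

Everything that was applied is recorded in :class:`PhantomTruth` so every
downstream stage can be validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    LABEL_BACKGROUND,
    LABEL_EMBRYO,
    LABEL_ENDOSPERM,
    LABEL_WHOLE_SEED,
    MSIDataset,
    RawSpectrum,
    TargetPeakList,
    default_background_mz,
    default_peak_list,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "phantom_default",
    "generate_phantom_series",
    "default_profile_table",
    "sample_heteroscedastic",
]

_FOREGROUND = (LABEL_EMBRYO, LABEL_ENDOSPERM, LABEL_WHOLE_SEED)

# Mean intensity levels (arbitrary units) for the region profiles.
_LEVEL_HIGH = 200.0
_LEVEL_MID = 60.0
_LEVEL_LOW = 10.0


def default_profile_table(peaks: TargetPeakList) -> pd.DataFrame:
    """Region × feature mean intensities for the default phantom.

    Assignment follows the compound classes: secondary metabolites
    (hordatines, hydroxycinnamic acid amides) dominate the embryo,
    oligosaccharides and lipids the endosperm, and the unknown signals the
    remaining seed tissue, with low cross-region baselines. A deterministic
    per-feature modulation (five-step ramp) avoids identical columns.
    """
    mz = peaks.mz
    cls = peaks.table["class"].to_numpy()
    n = len(mz)
    scale = 0.6 + 0.2 * (np.arange(n) % 5)  # 0.6 .. 1.4, deterministic
    prof = {r: np.zeros(n) for r in _FOREGROUND}
    for i in range(n):
        c = cls[i]
        if c == "secondary":
            prof[LABEL_EMBRYO][i] = _LEVEL_HIGH * scale[i]
            prof[LABEL_ENDOSPERM][i] = 0.0
            prof[LABEL_WHOLE_SEED][i] = _LEVEL_LOW * scale[i] * 0.5
        elif c == "oligosaccharide":
            prof[LABEL_ENDOSPERM][i] = _LEVEL_HIGH * scale[i]
            prof[LABEL_EMBRYO][i] = _LEVEL_LOW * scale[i]
            prof[LABEL_WHOLE_SEED][i] = _LEVEL_LOW * scale[i] * 0.5
        elif c == "lipid":
            prof[LABEL_ENDOSPERM][i] = _LEVEL_MID * scale[i]
            prof[LABEL_WHOLE_SEED][i] = _LEVEL_LOW * scale[i]
            prof[LABEL_EMBRYO][i] = 0.0
        else:  # unknown -> husk/tissue-like signal in the remaining seed
            prof[LABEL_WHOLE_SEED][i] = _LEVEL_HIGH * scale[i]
            prof[LABEL_ENDOSPERM][i] = _LEVEL_LOW * scale[i] * 0.5
            prof[LABEL_EMBRYO][i] = _LEVEL_LOW * scale[i] * 0.5
    table = pd.DataFrame(prof, index=mz).T
    table.index.name = "region"
    return table


def _default_adduct_pairs(peaks: TargetPeakList) -> list[tuple[float, float]]:
    """Na/K adduct pairs (same compound) present in the peak list."""
    by_label = dict(zip(peaks.labels, peaks.mz))
    pairs = []
    for label, mz_na in by_label.items():
        if label.endswith("[M+Na]+"):
            partner = label.replace("[M+Na]+", "[M+K]+")
            if partner in by_label:
                pairs.append((float(mz_na), float(by_label[partner])))
    return sorted(pairs)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic series; defaults are the study layout.

    Geometry is in pixels on an ``(nx, ny)`` grid; the embryo axes grow
    linearly with the time point. ``drift_range`` is the uniform interval
    (Da) from which per-dataset m/z translations are drawn unless
    ``drift_per_dataset`` pins them explicitly. ``noise_sigma2`` is the
    variance-per-unit-mean of the heteroscedastic noise; ``gain_sigma`` the
    log-standard-deviation of the per-pixel multiplicative gain.

    ``peak_fwhm_da`` gives ions the finite width of profile-mode TOF data:
    each ion is emitted as three m/z samples (center ± fwhm/2) carrying
    (0.5, 0.25, 0.25) of its intensity, so a peak spans two to three 0.1 Da
    bins as in real spectra. Set 0 for idealized stick spectra.
    """

    n_time_points: int = 8
    grid_shape: tuple[int, int] = (80, 40)  # (nx, ny)
    seed_center: tuple[float, float] = (40.0, 20.0)
    seed_axes: tuple[float, float] = (36.0, 16.0)
    endosperm_center: tuple[float, float] = (50.0, 20.0)
    endosperm_axes: tuple[float, float] = (22.0, 11.0)
    embryo_center: tuple[float, float] = (16.0, 20.0)
    embryo_axes_start: tuple[float, float] = (6.0, 4.0)
    embryo_growth: tuple[float, float] = (0.9, 0.45)  # px per time step
    peaks: TargetPeakList = field(default_factory=default_peak_list)
    profile_table: pd.DataFrame | None = None
    adduct_pairs: list[tuple[float, float]] | None = None
    adduct_weight_range: tuple[float, float] = (0.2, 0.8)
    peak_fwhm_da: float = 0.15
    drift_range: tuple[float, float] = (-0.3, 0.3)
    drift_per_dataset: list[float] | None = None
    region_drift: dict[str, float] | None = None
    noise_sigma2: float = 4.0
    gain_sigma: float = 0.25
    matrix_mz: list[float] | None = None
    tape_mz: list[float] | None = None
    noise_mz: list[float] = field(default_factory=lambda: [
        412.57, 476.33, 512.71, 633.19, 710.93])
    background_level: float = 80.0
    noise_channel_scale: float = 30.0

    def __post_init__(self) -> None:
        if self.profile_table is None:
            self.profile_table = default_profile_table(self.peaks)
        if self.adduct_pairs is None:
            self.adduct_pairs = _default_adduct_pairs(self.peaks)
        if self.matrix_mz is None or self.tape_mz is None:
            bg = default_background_mz()
            if self.matrix_mz is None:
                self.matrix_mz = bg["matrix"]
            if self.tape_mz is None:
                self.tape_mz = bg["tape"]
        if (np.asarray(self.profile_table.to_numpy()) < 0).any():
            raise ValueError("profile_table has negative mean intensities")

    def validate_regions(self) -> None:
        missing = set(_FOREGROUND) - set(self.profile_table.index)
        if missing:
            raise ValueError(
                f"profile_table missing regions {sorted(missing)}")


@dataclass
class PhantomTruth:
    """Ground truth of one generated series."""

    masks: dict[int, np.ndarray]          # t -> (ny, nx) label raster
    drift: dict[int, float]               # t -> applied m/z translation (Da)
    profile_table: pd.DataFrame
    seed: int


def phantom_default() -> PhantomSpec:
    """The default 8-time-point phantom (study layout)."""
    return PhantomSpec()


def sample_heteroscedastic(mean: np.ndarray, rng: np.random.Generator,
                           sigma2: float) -> np.ndarray:
    """Draw intensities with variance ``sigma2 * mean``, truncated at 0."""
    mean = np.asarray(mean, dtype=float)
    if sigma2 == 0:
        return mean.copy()
    noise = rng.normal(0.0, 1.0, size=mean.shape) * np.sqrt(sigma2 * mean)
    return np.clip(mean + noise, 0.0, None)


def _ellipse_mask(nx: int, ny: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    cx, cy = center
    ax, ay = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _region_masks(spec: PhantomSpec, t: int) -> np.ndarray:
    nx, ny = spec.grid_shape
    labels = np.full((ny, nx), LABEL_BACKGROUND, dtype="U16")
    seed = _ellipse_mask(nx, ny, spec.seed_center, spec.seed_axes)
    labels[seed] = LABEL_WHOLE_SEED
    endo = _ellipse_mask(nx, ny, spec.endosperm_center, spec.endosperm_axes)
    labels[seed & endo] = LABEL_ENDOSPERM
    ex = spec.embryo_axes_start[0] + spec.embryo_growth[0] * (t - 1)
    ey = spec.embryo_axes_start[1] + spec.embryo_growth[1] * (t - 1)
    embryo = _ellipse_mask(nx, ny, spec.embryo_center, (ex, ey))
    labels[seed & embryo] = LABEL_EMBRYO
    return labels


def _adduct_weight(spec: PhantomSpec, nx: int, ny: int) -> np.ndarray:
    """Normalized radial position inside the endosperm ellipse, in [0, 1]."""
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    cx, cy = spec.endosperm_center
    ax, ay = spec.endosperm_axes
    rho = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2)
    return np.clip(rho, 0.0, 1.0)


def generate_phantom_series(
        spec: PhantomSpec,
        seed: int) -> tuple[list[MSIDataset], PhantomTruth]:
    """Generate one dataset per time point plus the applied ground truth.

    Per pixel the spectrum is ``gain × (region profile + background)`` with
    heteroscedastic noise, on an m/z axis translated by the dataset's drift.
    Deterministic for a fixed ``(spec, seed)``.
    """
    spec.validate_regions()
    rng = np.random.default_rng(abs(int(seed)) % (2 ** 32))
    nx, ny = spec.grid_shape
    n_px = nx * ny

    feat_mz = spec.peaks.mz
    n_feat = len(feat_mz)
    all_mz = np.concatenate([
        feat_mz,
        np.asarray(spec.matrix_mz, dtype=float),
        np.asarray(spec.tape_mz, dtype=float),
        np.asarray(spec.noise_mz, dtype=float),
    ])
    if len(np.unique(all_mz)) != len(all_mz):
        raise ValueError("feature/background/noise m/z values collide")
    # Finite peak width: each ion becomes three m/z samples carrying fixed
    # fractions of its intensity (a coarse profile-mode peak shape).
    if spec.peak_fwhm_da > 0:
        half = spec.peak_fwhm_da / 2.0
        exp_mz = np.concatenate(
            [all_mz - half, all_mz, all_mz + half])
        exp_src = np.tile(np.arange(len(all_mz)), 3)
        exp_w = np.concatenate([
            np.full(len(all_mz), 0.25),
            np.full(len(all_mz), 0.50),
            np.full(len(all_mz), 0.25)])
    else:
        exp_mz = all_mz.copy()
        exp_src = np.arange(len(all_mz))
        exp_w = np.ones(len(all_mz))
    # one shared, strictly ascending axis; coinciding samples merge
    uniq_mz, inverse = np.unique(exp_mz, return_inverse=True)
    spread = np.zeros((len(all_mz), len(uniq_mz)))
    spread[exp_src, inverse] += exp_w
    n_total = len(all_mz)
    n_matrix, n_tape = len(spec.matrix_mz), len(spec.tape_mz)
    i_matrix = np.arange(n_feat, n_feat + n_matrix)
    i_tape = np.arange(n_feat + n_matrix, n_feat + n_matrix + n_tape)
    i_noise = np.arange(n_total - len(spec.noise_mz), n_total)

    # Deterministic per-ion background level variation (not seeded: part of
    # the phantom's fixed chemistry, not of the noise model).
    bg_scale = 0.8 + 0.4 * ((np.arange(len(all_mz)) * 7) % 5) / 4.0

    # Per-dataset drifts, drawn up front in time-point order.
    if spec.drift_per_dataset is not None:
        if len(spec.drift_per_dataset) != spec.n_time_points:
            raise ValueError("drift_per_dataset length != n_time_points")
        drifts = [float(d) for d in spec.drift_per_dataset]
    else:
        lo, hi = spec.drift_range
        drifts = [float(rng.uniform(lo, hi))
                  for _ in range(spec.n_time_points)]

    prof = spec.profile_table
    pair_idx = []
    mz_to_col = {float(m): i for i, m in enumerate(feat_mz)}
    for mz_na, mz_k in spec.adduct_pairs:
        if mz_na in mz_to_col and mz_k in mz_to_col:
            pair_idx.append((mz_to_col[mz_na], mz_to_col[mz_k]))

    w_lo, w_hi = spec.adduct_weight_range
    weight = _adduct_weight(spec, nx, ny).ravel()  # row-major (y, x)
    xs = np.tile(np.arange(nx), ny)
    ys = np.repeat(np.arange(ny), nx)

    datasets: list[MSIDataset] = []
    masks: dict[int, np.ndarray] = {}
    for t in range(1, spec.n_time_points + 1):
        labels = _region_masks(spec, t)
        masks[t] = labels.copy()
        flat_labels = labels.ravel()

        mean = np.zeros((n_px, n_total))
        for region in _FOREGROUND:
            sel = flat_labels == region
            if sel.any():
                mean[np.ix_(sel, np.arange(n_feat))] = \
                    prof.loc[region].to_numpy()[None, :]
        # Complementary Na/K weighting inside the endosperm: Na follows
        # (1 - w), K follows w, each mapped into [w_lo, w_hi] so the summed
        # image stays flat while each adduct alone carries the gradient.
        endo = flat_labels == LABEL_ENDOSPERM
        if endo.any() and pair_idx:
            w = weight[endo]
            f_na = w_lo + (w_hi - w_lo) * (1.0 - w)
            f_k = w_lo + (w_hi - w_lo) * w
            for c_na, c_k in pair_idx:
                mean[endo, c_na] *= f_na / ((w_lo + w_hi) / 2.0)
                mean[endo, c_k] *= f_k / ((w_lo + w_hi) / 2.0)
        mean[:, i_matrix] = spec.background_level * bg_scale[i_matrix]
        bgpx = flat_labels == LABEL_BACKGROUND
        mean[np.ix_(bgpx, i_tape)] = \
            spec.background_level * bg_scale[i_tape][None, :]

        inten = sample_heteroscedastic(mean, rng, spec.noise_sigma2)
        if len(i_noise):
            inten[:, i_noise] = np.abs(
                rng.normal(0.0, spec.noise_channel_scale,
                           size=(n_px, len(i_noise))))
        if spec.gain_sigma > 0:
            gain = rng.lognormal(0.0, spec.gain_sigma, size=n_px)
            inten *= gain[:, None]

        axis = uniq_mz + drifts[t - 1]
        inten_spread = inten @ spread
        spectra = [
            RawSpectrum(axis, inten_spread[i],
                        (int(xs[i]), int(ys[i])))
            for i in range(n_px)
        ]
        datasets.append(MSIDataset(time_point=t, spectra=spectra,
                                   grid_shape=spec.grid_shape,
                                   labels=labels))

    truth = PhantomTruth(masks=masks,
                         drift={t: drifts[t - 1]
                                for t in range(1, spec.n_time_points + 1)},
                         profile_table=prof.copy(), seed=int(seed))
    return datasets, truth
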