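"""Joint preprocessing of multiple MSI datasets.

The chain turns a list of datasets into a targeted peak-profile matrix:

1. bin all spectra onto one common m/z axis (sum of signals per 0.1 Da bin),
2. square-root transform (variance stabilization for heteroscedastic noise),
3. three-pass m/z recalibration by FFT cross-correlation against median
   spectra (region-within-dataset, then dataset, then region-across-time),
   with every single shift strictly below a 0.5 Da cutoff,
4. remove intensity images that positively correlate with known matrix or
   tape reference m/z values,
5. remove spectra outside the regions of interest,
6. remove uninformative images by the variance-explained (VE) criterion:
   VE of the first singular component of each image, thresholded at the
   mean VE over all images,
7. normalize every remaining spectrum to the median of its positive
   intensities,
8. select the targeted features, collapsing near-isobars that share a bin.

The binned data live in a sparse spectra × bins matrix with a hierarchical
row index (t, r, x, y); filters shrink rows/columns but keep the original
bin identity so m/z values remain addressable throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
import scipy.sparse as sp
from scipy.linalg import svdvals

from .io import FOREGROUND_LABELS, MSIDataset, TargetPeakList

__all__ = [
    "BinnedMatrix",
    "RecalibrationReport",
    "InformativeSet",
    "PeakProfileSet",
    "bin_to_common_axis",
    "sqrt_transform",
    "median_spectrum",
    "estimate_shift",
    "recalibrate_multipass",
    "filter_background_images",
    "filter_roi_spectra",
    "variance_explained",
    "filter_informative_images",
    "normalize_median",
    "select_features",
    "run_preprocessing",
    "PreprocessResult",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_RECAL_CUTOFF_DA",
    "RECAL_PASSES",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_RECAL_CUTOFF_DA = 0.5
#: The three recalibration passes, in order.
RECAL_PASSES = ("region-within-dataset", "dataset", "region-across-time")

_EDGE_EPS = 1e-9  # half-open bin edges, robust to float representation


@dataclass
class BinnedMatrix:
    """Spectra × m/z bins on a common axis, with hierarchical row index.

    ``bins`` holds the original column index of each retained column so bin
    k of the current matrix covers
    ``[axis_start + bins[k]*bin_width, axis_start + (bins[k]+1)*bin_width)``.
    ``index`` is a DataFrame with columns ``t, r, x, y`` (one row per
    spectrum).
    """

    axis_start: float
    bin_width: float
    matrix: sp.csr_matrix
    index: pd.DataFrame
    bins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.bins is None:
            self.bins = np.arange(self.matrix.shape[1], dtype=np.int64)
        if self.matrix.shape[0] != len(self.index):
            raise ValueError("matrix rows and index length differ")
        if self.matrix.shape[1] != len(self.bins):
            raise ValueError("matrix columns and bin map length differ")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_mz(self) -> np.ndarray:
        """Center m/z of each retained bin."""
        return self.axis_start + (self.bins + 0.5) * self.bin_width

    def select_rows(self, rows: np.ndarray) -> "BinnedMatrix":
        return BinnedMatrix(self.axis_start, self.bin_width,
                            self.matrix[rows].tocsr(),
                            self.index.iloc[rows].reset_index(drop=True),
                            self.bins.copy())

    def select_bins(self, cols: np.ndarray) -> "BinnedMatrix":
        return BinnedMatrix(self.axis_start, self.bin_width,
                            self.matrix[:, cols].tocsr(),
                            self.index.copy(), self.bins[cols].copy())


@dataclass
class RecalibrationReport:
    """Per-spectrum, per-pass shifts applied during recalibration."""

    # columns: spectrum, round, pass, shift_bins, shift_da
    table: pd.DataFrame
    cutoff_da: float
    passes: tuple[str, ...]

    def validate(self) -> None:
        if np.any(np.abs(self.table["shift_da"].to_numpy())
                  >= self.cutoff_da):
            raise AssertionError("recorded shift at or above cutoff")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class InformativeSet:
    """Rows/bins retained by the filters, the VE statistics, and P."""

    retained_bins: np.ndarray        # original bin indices kept
    retained_rows: np.ndarray        # positions into the post-recal matrix
    ve_per_image: np.ndarray         # dataset-averaged VE per tested bin
    ve_threshold: float
    normalized: BinnedMatrix | None = None   # the matrix P
    selected: "PeakProfileSet | None" = None


@dataclass
class PeakProfileSet:
    """The targeted sub-matrix X*: informative spectra × selected features."""

    feature_mz: np.ndarray           # target m/z, ascending
    feature_labels: list[str]
    feature_bins: np.ndarray         # original bin index per feature
    matrix: np.ndarray               # dense (rows × features)
    index: pd.DataFrame              # t, r, x, y per row

    @property
    def n_profiles(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# binning and transforms
# ---------------------------------------------------------------------------

def _bin_of(mz: np.ndarray, axis_start: float, width: float) -> np.ndarray:
    return np.floor((mz - axis_start + _EDGE_EPS) / width).astype(np.int64)


def bin_to_common_axis(datasets: list[MSIDataset],
                       bin_width: float = DEFAULT_BIN_WIDTH) -> BinnedMatrix:
    """Sum raw intensities into half-open bins on one common m/z axis.

    The axis spans all datasets; the bin grid is anchored at integer
    multiples of ``bin_width``. Total in-range intensity is conserved
    exactly; one row is produced per recorded spectrum, indexed with
    ``(t, r, x, y)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spectra_count = sum(ds.n_spectra for ds in datasets)
    if not datasets or spectra_count == 0:
        raise ValueError("no spectra to bin")

    lo = min(s.mz_values.min() for ds in datasets for s in ds.spectra
             if len(s.mz_values))
    hi = max(s.mz_values.max() for ds in datasets for s in ds.spectra
             if len(s.mz_values))
    axis_start = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.floor((hi - axis_start + _EDGE_EPS) / bin_width)) + 1

    rows, cols, vals = [], [], []
    idx_t, idx_r, idx_x, idx_y = [], [], [], []
    col_cache: dict[int, np.ndarray] = {}
    row = 0
    for ds in sorted(datasets, key=lambda d: d.time_point):
        for s in ds.spectra:
            key = id(s.mz_values)
            c = col_cache.get(key)
            if c is None:
                c = _bin_of(s.mz_values, axis_start, bin_width)
                col_cache[key] = c
            nz = s.intensities != 0
            rows.append(np.full(int(nz.sum()), row, dtype=np.int64))
            cols.append(c[nz])
            vals.append(np.asarray(s.intensities, dtype=float)[nz])
            x, y = s.pixel
            idx_t.append(ds.time_point)
            idx_r.append(ds.label_of(x, y))
            idx_x.append(x)
            idx_y.append(y)
            row += 1

    coo = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(row, n_bins))
    index = pd.DataFrame({"t": idx_t, "r": idx_r, "x": idx_x, "y": idx_y})
    return BinnedMatrix(float(axis_start), float(bin_width),
                        coo.tocsr(), index)


def sqrt_transform(M: BinnedMatrix) -> BinnedMatrix:
    """Element-wise square root; rejects negative (corrupt) intensities."""
    data = M.matrix.data
    if len(data) and data.min() < 0:
        raise ValueError("negative intensity in binned matrix")
    out = M.matrix.copy()
    out.data = np.sqrt(out.data)
    return BinnedMatrix(M.axis_start, M.bin_width, out,
                        M.index.copy(), M.bins.copy())


def _sparse_column_median(X: sp.spmatrix) -> np.ndarray:
    """Per-column median over rows, counting implicit zeros."""
    X = X.tocsc()
    m, n = X.shape
    if m == 0:
        raise ValueError("median of zero rows is undefined")
    med = np.zeros(n)
    lo, hi = (m - 1) // 2, m // 2
    nnz = np.diff(X.indptr)
    # With non-negative data the median can only be nonzero when the column
    # has more than m - 1 - lo stored entries; negatives force the slow path.
    candidates = np.nonzero(nnz > 0)[0]
    for j in candidates:
        v = X.data[X.indptr[j]:X.indptr[j + 1]]
        k = len(v)
        nneg = int((v < 0).sum())
        if nneg == 0 and hi < m - k:
            continue  # zeros occupy both median positions
        v = np.sort(v)
        def at(p: int) -> float:
            if p < nneg:
                return v[p]
            if p < nneg + (m - k):
                return 0.0
            return v[p - (m - k)]
        med[j] = 0.5 * (at(lo) + at(hi))
    return med


def median_spectrum(rows: BinnedMatrix | sp.spmatrix | np.ndarray
                    ) -> np.ndarray:
    """Per-bin median across a set of spectra (rows)."""
    if isinstance(rows, BinnedMatrix):
        rows = rows.matrix
    if sp.issparse(rows):
        return _sparse_column_median(rows)
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise ValueError("median_spectrum needs a non-empty 2D input")
    return np.median(rows, axis=0)


# ---------------------------------------------------------------------------
# recalibration
# ---------------------------------------------------------------------------

def _lag_order(max_lag: int) -> np.ndarray:
    """Candidate lags ordered by the tie rule: |lag| asc, negative first."""
    out = [0]
    for k in range(1, max_lag + 1):
        out.extend((-k, k))
    return np.array(out, dtype=np.int64)


def _xcorr_best_lags(S: np.ndarray, ref: np.ndarray,
                     max_lag: int) -> np.ndarray:
    """Best alignment lag per row of ``S`` against ``ref`` (FFT based).

    The score of lag λ is sum_j S[i, j] * ref[j + λ]; the returned λ is the
    one a +λ-bin shift of the spectrum needs to best match the reference.
    Ties resolve to the smallest |λ|, negative before positive.
    """
    # float32 keeps the transform fast; the argmax over lags is insensitive
    # to the reduced precision.
    S = np.atleast_2d(np.asarray(S, dtype=np.float32))
    ref = np.asarray(ref, dtype=np.float32)
    n = S.shape[1]
    if ref.shape[0] != n:
        raise ValueError("spectrum and reference lengths differ")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if max_lag == 0:
        return np.zeros(S.shape[0], dtype=np.int64)
    nf = scipy.fft.next_fast_len(n + max_lag, real=True)
    fs = scipy.fft.rfft(S, nf, axis=1)
    fr = scipy.fft.rfft(ref, nf)
    corr = scipy.fft.irfft(np.conj(fs) * fr[None, :], nf, axis=1)
    lags = _lag_order(max_lag)
    vals = corr[:, lags % nf]
    return lags[np.argmax(vals, axis=1)]


def estimate_shift(spectrum: np.ndarray, reference: np.ndarray,
                   max_lag: int) -> int:
    """Best integer-bin lag aligning ``spectrum`` to ``reference``.

    Inputs are expected on the same axis, square-root transformed and
    median-normalized (the cross-correlation is intensity-weighted, so
    normalization keeps single dominant peaks from hijacking the match).
    """
    return int(_xcorr_best_lags(np.asarray(spectrum, dtype=float)[None, :],
                                reference, max_lag)[0])


def _median_normalize_sparse_rows(X: sp.csr_matrix) -> sp.csr_matrix:
    """Scale each row by the median of its positive entries (if any)."""
    X = X.tocsr(copy=True)
    for i in range(X.shape[0]):
        v = X.data[X.indptr[i]:X.indptr[i + 1]]
        pos = v[v > 0]
        if len(pos):
            X.data[X.indptr[i]:X.indptr[i + 1]] = v / np.median(pos)
    return X


def _support_columns(X: sp.spmatrix, max_lag: int) -> np.ndarray:
    """Columns with any signal, dilated by ``max_lag`` on either side.

    Cross-correlation terms at |lag| <= max_lag only involve columns within
    ``max_lag`` of an occupied column of the spectrum (and the reference's
    support is a subset of the spectra's union support), so estimating lags
    on this column subset is exactly equivalent to using the full axis —
    the empty stretches in between contribute nothing at any allowed lag.
    """
    nnz = np.diff(X.tocsc().indptr)
    occupied = np.nonzero(nnz > 0)[0]
    if len(occupied) == 0:
        return occupied
    mask = np.zeros(X.shape[1], dtype=bool)
    for off in range(-max_lag, max_lag + 1):
        idx = occupied + off
        idx = idx[(idx >= 0) & (idx < X.shape[1])]
        mask[idx] = True
    return np.nonzero(mask)[0]


def _apply_row_shifts(X: sp.csr_matrix, lags: np.ndarray) -> sp.csr_matrix:
    """Translate each row by its lag in bins, zero-filling at the edges."""
    coo = X.tocoo()
    newcol = coo.col + lags[coo.row]
    keep = (newcol >= 0) & (newcol < X.shape[1])
    return sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], newcol[keep])),
        shape=X.shape).tocsr()


def recalibrate_multipass(
        M: BinnedMatrix,
        cutoff_da: float = DEFAULT_RECAL_CUTOFF_DA,
        passes: tuple[str, ...] = RECAL_PASSES,
        chunk_rows: int = 1024,
        max_rounds: int = 5,
) -> tuple[BinnedMatrix, RecalibrationReport]:
    """Multi-pass recalibration toward median spectra, run to a fixpoint.

    Pass 1 aligns every spectrum to the median of its (t, r) stratum, pass 2
    to the median of its dataset M_t, pass 3 to the all-time median of its
    region M_r. Reference medians are recomputed at the start of each pass;
    lags are estimated on median-normalized copies while the stored matrix
    keeps its (unnormalized, square-root) values. Each single shift is an
    integer number of bins strictly below ``cutoff_da``.

    The three-pass cycle repeats (up to ``max_rounds``) until a cycle
    applies no shift at all: when the m/z spread between datasets
    approaches the cutoff, the first cycle's median references are built
    from barely-overlapping spectra and only rough-align the batch; the
    recomputed medians of the next cycle are then well-supported and pull
    the stragglers in. Every recorded shift still respects the cutoff
    individually.
    """
    unknown = set(passes) - set(RECAL_PASSES)
    if unknown:
        raise ValueError(f"unknown recalibration passes {sorted(unknown)}")
    max_lag = int(np.ceil(cutoff_da / M.bin_width)) - 1
    group_cols = {"region-within-dataset": ["t", "r"],
                  "dataset": ["t"],
                  "region-across-time": ["r"]}
    work = M.matrix.tocsr(copy=True)
    records = []
    for round_no in range(max_rounds):
        round_shifted = False
        for pass_name in passes:
            lags_all = np.zeros(work.shape[0], dtype=np.int64)
            # Lag estimation runs on the support columns only (see
            # _support_columns); shifts are applied on the full axis.
            support = _support_columns(work, max_lag)
            compact = work[:, support].tocsr()
            grouped = M.index.groupby(group_cols[pass_name], sort=True)
            for _, sub in grouped:
                rows = sub.index.to_numpy()
                if len(rows) == 0:
                    log.warning("empty stratum in pass %s skipped",
                                pass_name)
                    continue
                stratum = _median_normalize_sparse_rows(compact[rows])
                ref = _sparse_column_median(stratum)
                if not np.any(ref):
                    # The median spectrum is identically zero when drift
                    # spreads the datasets so far apart that no bin is
                    # occupied by half the rows; the mean spectrum then
                    # keeps the consensus information (a hump over the
                    # drift spread) and serves as the fallback reference.
                    ref = np.asarray(stratum.mean(axis=0)).ravel()
                    log.info("pass %s: median reference degenerate for a "
                             "stratum of %d spectra; using the mean",
                             pass_name, len(rows))
                if not np.any(ref):
                    continue  # stratum is entirely empty
                for start in range(0, len(rows), chunk_rows):
                    blk = slice(start, start + chunk_rows)
                    dense = stratum[blk].toarray().astype(np.float32)
                    lags_all[rows[blk]] = _xcorr_best_lags(dense, ref,
                                                           max_lag)
            if np.any(lags_all):
                round_shifted = True
                work = _apply_row_shifts(work, lags_all)
            records.append(pd.DataFrame({
                "spectrum": np.arange(work.shape[0]),
                "round": round_no,
                "pass": pass_name,
                "shift_bins": lags_all,
                "shift_da": lags_all * M.bin_width,
            }))
        if not round_shifted:
            break
    report = RecalibrationReport(pd.concat(records, ignore_index=True),
                                 cutoff_da=cutoff_da, passes=tuple(passes))
    report.validate()
    out = BinnedMatrix(M.axis_start, M.bin_width, work, M.index.copy(),
                       M.bins.copy())
    return out, report


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _mz_to_current_col(M: BinnedMatrix, mz_values: np.ndarray) -> np.ndarray:
    """Map m/z values to current column positions (-1 if absent)."""
    target = _bin_of(np.asarray(mz_values, dtype=float),
                     M.axis_start, M.bin_width)
    pos = {int(b): i for i, b in enumerate(M.bins)}
    return np.array([pos.get(int(b), -1) for b in target], dtype=np.int64)


def filter_background_images(
        M: BinnedMatrix,
        reference_mz: list[float],
        r_threshold: float = 0.9,
) -> tuple[BinnedMatrix, np.ndarray]:
    """Drop intensity images positively correlated with background ions.

    Pearson correlation is computed between each candidate bin's vectorized
    image and each reference bin's, over the foreground (region-of-
    interest) pixels of all datasets: there, background-derived images
    reduce to the shared pixel-to-pixel sensitivity pattern — so they
    correlate strongly with each other — while tissue-driven images are
    dominated by their own spatial pattern and decorrelate from it. Bins
    whose maximum correlation reaches ``r_threshold`` are removed, as are
    the reference bins themselves. Constant images (e.g. tape ions absent
    from the foreground) have undefined correlation and are retained.
    Returns the reduced matrix and the removed original bin indices.
    """
    if not reference_mz:
        warnings.warn("empty background reference list; filter is a no-op")
        return M, np.array([], dtype=np.int64)
    ref_cols = _mz_to_current_col(M, np.asarray(reference_mz))
    missing = np.asarray(reference_mz)[ref_cols < 0]
    if len(missing):
        warnings.warn(
            f"background reference m/z outside axis ignored: {missing}")
    ref_cols = np.unique(ref_cols[ref_cols >= 0])
    if len(ref_cols) == 0:
        return M, np.array([], dtype=np.int64)

    fg = M.index["r"].isin(FOREGROUND_LABELS).to_numpy()
    X = (M.matrix[np.nonzero(fg)[0]] if fg.any() and not fg.all()
         else M.matrix).tocsc()
    m = X.shape[0]
    col_sum = np.asarray(X.sum(axis=0)).ravel()
    col_sq = np.asarray(X.multiply(X).sum(axis=0)).ravel()
    mean = col_sum / m
    var = col_sq / m - mean ** 2
    std = np.sqrt(np.clip(var, 0.0, None))

    cross = np.asarray((X.T @ X[:, ref_cols]).todense()) / m  # n × k
    denom = std[:, None] * std[ref_cols][None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cross - mean[:, None] * mean[ref_cols][None, :]) / denom
    corr[denom == 0] = np.nan  # constant image on either side: undefined
    max_corr = np.nanmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)

    remove = max_corr >= r_threshold
    constant = std == 0
    n_const = int(np.count_nonzero(constant & ~remove))
    if n_const:
        log.info("%d constant intensity images retained "
                 "(correlation undefined)", n_const)
    remove[constant] = False
    remove[ref_cols] = True
    removed_bins = M.bins[remove]
    return M.select_bins(np.nonzero(~remove)[0]), removed_bins


def filter_roi_spectra(M: BinnedMatrix) -> BinnedMatrix:
    """Remove spectra outside the regions of interest."""
    keep = M.index["r"].isin(FOREGROUND_LABELS).to_numpy()
    if not keep.any():
        raise ValueError("no spectra inside the regions of interest")
    return M.select_rows(np.nonzero(keep)[0])


def variance_explained(image: np.ndarray) -> float:
    """VE of the first singular component of an image's row matrix.

    ``VE = s1^2 / sum(s_k^2)`` over the singular values; 1.0 for a rank-1
    image, small for noise-like images, defined as 0 for all-zero input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("image must be 2D with at least 2 rows and columns")
    if not np.any(image):
        return 0.0
    s = svdvals(image)
    s2 = s ** 2
    return float(s2[0] / s2.sum())


def _per_dataset_rasters(M: BinnedMatrix):
    """Yield (t, rows, (h, w), (iy, ix)) raster geometry per dataset.

    The raster is the zero-filled bounding box of the dataset's retained
    pixels (the seed area once background spectra are gone).
    """
    for t, sub in M.index.groupby("t", sort=True):
        rows = sub.index.to_numpy()
        xs = sub["x"].to_numpy()
        ys = sub["y"].to_numpy()
        x0, y0 = xs.min(), ys.min()
        w = int(xs.max() - x0 + 1)
        h = int(ys.max() - y0 + 1)
        yield t, rows, (h, w), (ys - y0, xs - x0)


def _column_select_dense(M: BinnedMatrix, cols: np.ndarray) -> np.ndarray:
    return np.asarray(M.matrix[:, cols].todense(), dtype=float)


def filter_informative_images(
        M: BinnedMatrix) -> tuple[BinnedMatrix, InformativeSet]:
    """Keep bins whose images carry structure, by the mean-VE rule.

    Every dataset's zero-filled bounding-box raster of the bin's intensity
    image is stacked row-wise into one matrix and VE computed on the stack
    (one joint decision per bin for the whole batch; a bin that is
    structured in only part of the datasets keeps its structure visible,
    because all-zero blocks contribute nothing to any singular value). The
    threshold is the mean VE over all bins and bins at or above it are
    retained (inclusive boundary). Every bin of the matrix contributes an
    image: vacant bins score 0, sit below the mean and are removed — on
    real batches they are the bulk of the axis, so this filter is where
    most of the bin reduction happens.
    """
    n = M.n_bins
    ve = np.zeros(n)
    Xc = M.matrix.tocsc()
    nnz = np.diff(Xc.indptr)
    candidates = np.nonzero(nnz > 0)[0]
    geoms = list(_per_dataset_rasters(M))
    if candidates.size and geoms:
        heights = [h for _t, _r, (h, w), _ in geoms]
        width = max(w for _t, _r, (h, w), _ in geoms)
        offsets = np.concatenate([[0], np.cumsum(heights)])
        stack = np.zeros((int(offsets[-1]), width))
        subs = [(M.matrix[rows][:, candidates].toarray(), (h, w), (iy, ix))
                for _t, rows, (h, w), (iy, ix) in geoms]
        for k, j in enumerate(candidates):
            stack[:] = 0.0
            occupied = False
            for g, (sub, (h, w), (iy, ix)) in enumerate(subs):
                col = sub[:, k]
                if not np.any(col):
                    continue
                occupied = True
                stack[offsets[g] + iy, ix] = col
            if occupied:
                ve[j] = variance_explained(stack)
    threshold = float(ve.mean()) if n else 0.0
    keep = ve >= threshold
    out = M.select_bins(np.nonzero(keep)[0])
    info = InformativeSet(retained_bins=M.bins[keep],
                          retained_rows=np.arange(M.n_spectra),
                          ve_per_image=ve, ve_threshold=threshold)
    return out, info


# ---------------------------------------------------------------------------
# normalization and feature selection
# ---------------------------------------------------------------------------

def normalize_median(M: BinnedMatrix) -> tuple[BinnedMatrix, np.ndarray]:
    """Divide each spectrum by the median of its positive intensities.

    Rows with no positive retained intensity are dropped with a warning.
    Returns the normalized matrix P and the positions of the surviving rows.
    """
    X = M.matrix.tocsr(copy=True)
    keep = np.ones(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        v = X.data[X.indptr[i]:X.indptr[i + 1]]
        pos = v[v > 0]
        if len(pos) == 0:
            keep[i] = False
            continue
        X.data[X.indptr[i]:X.indptr[i + 1]] = v / np.median(pos)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} spectra without positive "
                      "intensities dropped during normalization")
    rows = np.nonzero(keep)[0]
    P = BinnedMatrix(M.axis_start, M.bin_width, X[rows].tocsr(),
                     M.index.iloc[rows].reset_index(drop=True),
                     M.bins.copy())
    return P, rows


def select_features(P: BinnedMatrix, peaks: TargetPeakList,
                    bin_width: float | None = None,
                    window_bins: int = 2) -> PeakProfileSet:
    """Extract the targeted features from P, collapsing shared bins.

    Each target m/z is snapped to the retained bin within ``window_bins``
    of its nominal position that carries the most signal (recalibration
    only aligns spectra to within one bin of the batch consensus, which
    itself may sit a bin or two off the nominal position), and the feature
    intensity is integrated over the retained bins within ``window_bins``
    of that center — the usual tolerance-window extraction, wide enough
    that a one-bin residual misalignment never clips a finite-width peak.
    Targets snapped to the same center bin collide and only the lowest m/z
    of each collision group is kept. Output columns are ordered by
    ascending feature m/z. Rows whose selected profile is entirely zero
    are dropped.
    """
    if bin_width is None:
        bin_width = P.bin_width
    order = np.argsort(peaks.mz, kind="stable")
    mz_sorted = peaks.mz[order]
    labels_sorted = [peaks.labels[i] for i in order]

    pos = {int(b): i for i, b in enumerate(P.bins)}
    col_mean = np.asarray(P.matrix.mean(axis=0)).ravel()
    offsets = range(-window_bins, window_bins + 1)
    chosen: dict[int, tuple[float, str]] = {}
    for mz, label in zip(mz_sorted, labels_sorted):
        nominal = int(_bin_of(np.array([mz]), P.axis_start, bin_width)[0])
        cand = [pos[nominal + off] for off in offsets
                if (nominal + off) in pos]
        if not cand:
            continue
        col = max(cand, key=lambda c: (col_mean[c], -c))
        if col not in chosen:  # collision: first (lowest) m/z wins
            chosen[col] = (float(mz), label)
    if not chosen:
        raise ValueError("no target peak maps into the binned axis")

    items = sorted(chosen.items(), key=lambda kv: kv[1][0])
    cols = np.array([c for c, _ in items], dtype=np.int64)
    feat_mz = np.array([v[0] for _, v in items])
    feat_labels = [v[1] for _, v in items]
    matrix = np.zeros((P.n_spectra, len(cols)))
    for k, c in enumerate(cols):
        b = int(P.bins[c])
        window = [pos[b + off] for off in offsets if (b + off) in pos]
        matrix[:, k] = _column_select_dense(P, np.array(window)).sum(axis=1)
    nonzero = matrix.any(axis=1)
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} profiles with no signal on "
                      "the selected features dropped")
    matrix = matrix[nonzero]
    index = P.index.iloc[np.nonzero(nonzero)[0]].reset_index(drop=True)
    return PeakProfileSet(feature_mz=feat_mz, feature_labels=feat_labels,
                          feature_bins=P.bins[cols].copy(),
                          matrix=matrix, index=index)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    binned: BinnedMatrix
    recalibrated: BinnedMatrix
    report: RecalibrationReport
    informative: InformativeSet
    profiles: PeakProfileSet
    counts: dict[str, int]


def run_preprocessing(
        datasets: list[MSIDataset],
        peaks: TargetPeakList,
        bin_width: float = DEFAULT_BIN_WIDTH,
        recal_cutoff_da: float = DEFAULT_RECAL_CUTOFF_DA,
        recal_passes: tuple[str, ...] = RECAL_PASSES,
        background_ref_mz: list[float] | None = None,
        background_r_threshold: float = 0.9,
        ve_filter_enabled: bool = True,
) -> PreprocessResult:
    """The full chain: bin → sqrt → recalibrate → background filter →
    ROI filter → VE filter → median normalize → select features."""
    counts: dict[str, int] = {}
    binned = bin_to_common_axis(datasets, bin_width)
    counts["spectra_in"] = binned.n_spectra
    counts["bins_in"] = binned.n_bins
    M = sqrt_transform(binned)
    M, report = recalibrate_multipass(M, recal_cutoff_da, recal_passes)
    recalibrated = M
    if background_ref_mz is None:
        from .io import default_background_mz
        bg = default_background_mz()
        background_ref_mz = bg["matrix"] + bg["tape"]
    M, removed = filter_background_images(M, background_ref_mz,
                                          background_r_threshold)
    counts["bins_after_background_filter"] = M.n_bins
    M = filter_roi_spectra(M)
    counts["spectra_in_roi"] = M.n_spectra
    if ve_filter_enabled:
        M, info = filter_informative_images(M)
    else:
        info = InformativeSet(retained_bins=M.bins.copy(),
                              retained_rows=np.arange(M.n_spectra),
                              ve_per_image=np.array([]), ve_threshold=0.0)
    counts["bins_informative"] = M.n_bins
    P, kept_rows = normalize_median(M)
    info.retained_rows = kept_rows
    info.normalized = P
    counts["spectra_informative"] = P.n_spectra
    profiles = select_features(P, peaks, bin_width)
    info.selected = profiles
    counts["profiles_out"] = profiles.n_profiles
    counts["features_out"] = profiles.n_features
    return PreprocessResult(binned=binned, recalibrated=recalibrated,
                            report=report, informative=info,
                            profiles=profiles, counts=counts)
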