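"""Voxelwise feature extraction for multimodal MRI classification.

Three per-subject feature maps are supported:

* **GMV** — gray matter volume; the structural volume itself (already
  modulated and smoothed upstream).
* **ALFF** — amplitude of low-frequency fluctuations; the mean single-sided
  spectral amplitude of each voxel's time series over a low-frequency band
  (0.01–0.08 Hz by default), divided by the subject's within-mask global mean.
* **ReHo** — regional homogeneity; Kendall's coefficient of concordance *W*
  between a voxel's time series and its 26 neighbors (27-voxel cluster),
  divided by the subject's within-mask global mean.

Maps are flattened to subject × voxel matrices over a fixed in-mask voxel
order so that classifier weight vectors can be scattered back into volumes.

Spectral convention for ALFF: the series is linearly detrended, the
single-sided DFT amplitude ``a_k = 2|X_k|/n`` is formed per frequency bin,
and ALFF is the mean of ``a_k`` over bins whose frequency ``k/(n·tr)`` lies
inside the band, boundaries inclusive.

ReHo convention: ranks over time per series with average ranks for ties, and
no tie-correction factor in the denominator (the form used by common
resting-state toolkits):  ``W = 12·S / (K²·(n³ − n))`` with
``S = Σ_t (R_t − R̄)²`` the dispersion of the rank sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("GMV", "ALFF", "ReHo")

#: FWHM-to-sigma conversion for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class BandError(ValueError):
    """Raised when a spectral band contains no DFT bins."""


@dataclass(frozen=True)
class BrainMask:
    """Boolean brain mask; ``D`` is the number of in-mask voxels."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 3:
            raise ValueError("mask must be a 3-D boolean grid")
        if not grid.any():
            raise ValueError("mask is empty: needs at least one voxel")

    @property
    def D(self) -> int:
        return int(self.grid.sum())

    def voxel_order(self) -> np.ndarray:
        """Fixed linear order of in-mask voxels (fastest-varying first axis).

        Returns flat indices into ``grid.ravel(order='F')``; shared by every
        feature and subject so that maps and weight vectors are mutually
        invertible.
        """
        return np.flatnonzero(self.grid.ravel(order="F"))


@dataclass
class FeatureMap:
    """One subject's 3-D feature map (dimensionless after global-mean scaling)."""

    subject_id: str
    feature: str
    values: np.ndarray


@dataclass
class FeatureMatrix:
    """Subjects × in-mask-voxels matrix for one feature."""

    feature: str
    values: np.ndarray  # (n_subjects, D)
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationParams:
    """Per-voxel z-score statistics estimated on a training row set.

    The denominator is the population standard deviation (divide by n).
    Columns that are constant on the training rows are flagged and map to
    zero everywhere.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.constant is None:
            self.constant = self.sd == 0


# ---------------------------------------------------------------------------
# temporal preprocessing
# ---------------------------------------------------------------------------

def discard_volumes(functional: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` time points of a 4-D (x, y, z, t) series."""
    functional = np.asarray(functional)
    if functional.ndim != 4:
        raise ValueError("functional must be 4-D (x, y, z, t)")
    n_t = functional.shape[-1]
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= n_t:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of length {n_t}"
        )
    return functional[..., n_discard:]


def smooth_gaussian(volume: np.ndarray, fwhm: float, voxel_size) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D volume.

    ``sigma = fwhm / (2·sqrt(2·ln 2))`` per axis, converted from mm to voxel
    units through ``voxel_size``.  A periodic ("wrap") boundary rule is used,
    which conserves the total sum exactly.  ``fwhm = 0`` is the identity.
    """
    volume = np.asarray(volume, dtype=float)
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return volume.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma = fwhm * FWHM_TO_SIGMA / voxel_size
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="wrap")


def _smooth_functional(functional: np.ndarray, fwhm: float, voxel_size) -> np.ndarray:
    """Spatially smooth every volume of a 4-D series (no temporal smoothing)."""
    if fwhm == 0:
        return np.asarray(functional, dtype=float).copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma = list(fwhm * FWHM_TO_SIGMA / voxel_size) + [0.0]
    return ndimage.gaussian_filter(np.asarray(functional, dtype=float),
                                   sigma=sigma, mode="wrap")


# ---------------------------------------------------------------------------
# ALFF
# ---------------------------------------------------------------------------

def _band_bins(n: int, tr: float, band) -> np.ndarray:
    f_lo, f_hi = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= f_lo < f_hi <= nyquist + 1e-12):
        raise ValueError(
            f"band {band} must satisfy 0 <= f_lo < f_hi <= Nyquist ({nyquist:g} Hz)"
        )
    freqs = np.fft.rfftfreq(n, d=tr)
    sel = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if not sel.any():
        raise BandError(
            f"band {band} Hz contains no DFT bins at frequency resolution "
            f"{1.0 / (n * tr):g} Hz (n={n}, tr={tr})"
        )
    return sel


def compute_alff(series, tr: float, band=(0.01, 0.08)) -> float:
    """Mean in-band single-sided DFT amplitude of one time series.

    The series is linearly detrended first; a constant series gives 0.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("series must be 1-D with at least 4 samples")
    n = x.size
    sel = _band_bins(n, tr, band)
    if np.ptp(x) == 0:  # no fluctuation at all
        return 0.0
    x = signal.detrend(x, type="linear")
    amp = 2.0 * np.abs(np.fft.rfft(x)) / n
    return float(amp[sel].mean())


def alff_map(functional: np.ndarray, tr: float, band, mask: BrainMask) -> FeatureMap:
    """Voxelwise ALFF within the mask, then global-mean scaling.

    Spatial smoothing, where wanted, is applied to the series *before* this
    call (see :func:`extract_feature_matrices` for the pipeline order).
    """
    functional = np.asarray(functional, dtype=float)
    if functional.shape[:3] != mask.grid.shape:
        raise ValueError("functional and mask spatial dims differ")
    n = functional.shape[-1]
    sel = _band_bins(n, tr, band)
    x = signal.detrend(functional, axis=-1, type="linear")
    amp = 2.0 * np.abs(np.fft.rfft(x, axis=-1)) / n
    values = amp[..., sel].mean(axis=-1)
    values[~mask.grid] = 0.0
    return _global_mean_scale(FeatureMap("", "ALFF", values), mask)


# ---------------------------------------------------------------------------
# ReHo
# ---------------------------------------------------------------------------

def compute_reho(neighborhood) -> float:
    """Kendall's coefficient of concordance W of K time series.

    ``W = 12·Σ_t (R_t − R̄)² / (K²·(n³ − n))`` where ``R_t`` is the sum over
    series of the time-ranks at time ``t`` (average ranks for ties).  Constant
    series contribute fully tied ranks; if every series is constant the
    concordance is defined as 0.
    """
    arr = np.asarray(neighborhood, dtype=float)
    if arr.ndim != 2:
        raise ValueError("neighborhood must be K series x n time points "
                         "(mismatched series lengths?)")
    K, n = arr.shape
    if K < 2:
        raise ValueError("need at least 2 series")
    if n < 2:
        raise ValueError("need at least 2 time points")
    ranks = stats.rankdata(arr, axis=1)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    return 12.0 * S / (K ** 2 * (n ** 3 - n))


def _neighbor_sums(values: np.ndarray, mask: np.ndarray):
    """Sum 4-D ``values`` and count mask voxels over 3x3x3 neighborhoods.

    Exact shift-and-add accumulation with zero padding, so the sums equal the
    direct per-voxel summation bit for bit.
    """
    x, y, z, t = values.shape
    pad_v = np.zeros((x + 2, y + 2, z + 2, t), dtype=values.dtype)
    pad_v[1:-1, 1:-1, 1:-1] = values
    pad_m = np.zeros((x + 2, y + 2, z + 2), dtype=np.int64)
    pad_m[1:-1, 1:-1, 1:-1] = mask
    sums = np.zeros_like(values)
    counts = np.zeros(mask.shape, dtype=np.int64)
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                sums += pad_v[dx:dx + x, dy:dy + y, dz:dz + z]
                counts += pad_m[dx:dx + x, dy:dy + y, dz:dz + z]
    return sums, counts


def reho_map(functional: np.ndarray, mask: BrainMask) -> FeatureMap:
    """Voxelwise Kendall's W over 3x3x3 in-mask neighborhoods, then scaling.

    Edge and partial neighborhoods use however many in-mask neighbors exist
    (minimum 2, else the voxel gets 0).
    """
    functional = np.asarray(functional, dtype=float)
    if functional.shape[:3] != mask.grid.shape:
        raise ValueError("functional and mask spatial dims differ")
    n = functional.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 time points after discarding")
    ranks = stats.rankdata(functional, axis=-1)
    ranks[~mask.grid] = 0.0
    R, K = _neighbor_sums(ranks, mask.grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        Rbar = K[..., None] * (n + 1) / 2.0
        S = ((R - Rbar) ** 2).sum(axis=-1)
        W = 12.0 * S / (K.astype(float) ** 2 * (n ** 3 - n))
    W[(K < 2) | ~mask.grid] = 0.0
    return _global_mean_scale(FeatureMap("", "ReHo", W), mask)


# ---------------------------------------------------------------------------
# scaling, vectorization, normalization
# ---------------------------------------------------------------------------

def _global_mean_scale(fmap: FeatureMap, mask: BrainMask) -> FeatureMap:
    """Divide by the within-mask global mean so the in-mask mean is 1."""
    m = fmap.values[mask.grid].mean()
    if m == 0:
        logger.warning("global mean of %s map is zero; scaling skipped", fmap.feature)
        return fmap
    fmap.values = fmap.values / m
    return fmap


def vectorize(maps: list[FeatureMap], mask: BrainMask) -> FeatureMatrix:
    """Stack subject maps into an n × D matrix in the fixed voxel order."""
    if not maps:
        raise ValueError("no maps given")
    feature = maps[0].feature
    order = mask.voxel_order()
    rows, ids = [], []
    for fmap in maps:
        if fmap.feature != feature:
            raise ValueError("maps mix feature names")
        if fmap.values.shape != mask.grid.shape:
            raise ValueError("map and mask dims differ")
        rows.append(fmap.values.ravel(order="F")[order])
        ids.append(fmap.subject_id)
    return FeatureMatrix(feature, np.asarray(rows), ids)


def map_from_vector(w: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Scatter a D-vector back into a 3-D volume (inverse of vectorization)."""
    w = np.asarray(w, dtype=float)
    if w.shape != (mask.D,):
        raise ValueError(f"vector length {w.shape} does not match mask D={mask.D}")
    flat = np.zeros(mask.grid.size, dtype=float)
    flat[mask.voxel_order()] = w
    return flat.reshape(mask.grid.shape, order="F")


def zscore_fit(matrix: FeatureMatrix, train_rows) -> NormalizationParams:
    """Fit per-voxel z-score statistics on the designated training rows."""
    train_rows = np.asarray(train_rows)
    if train_rows.dtype == bool:
        train_rows = np.flatnonzero(train_rows)
    if train_rows.size < 2:
        raise ValueError("need at least 2 training rows to fit a z-score")
    X = matrix.values[train_rows]
    return NormalizationParams(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))


def zscore_apply(matrix: FeatureMatrix, params: NormalizationParams) -> FeatureMatrix:
    """Apply train-fitted z-score statistics; constant columns map to 0."""
    sd = np.where(params.constant, 1.0, params.sd)
    values = (matrix.values - params.mean) / sd
    values[:, params.constant] = 0.0
    return FeatureMatrix(matrix.feature, values, list(matrix.subject_ids))


# ---------------------------------------------------------------------------
# subject-level pipeline
# ---------------------------------------------------------------------------

def extract_feature_matrices(scans, mask: BrainMask, band=(0.01, 0.08),
                             fwhm: float = 4.0, n_discard: int = 10,
                             features=FEATURE_NAMES) -> dict[str, FeatureMatrix]:
    """Full per-cohort feature extraction.

    Order of operations per subject: the leading ``n_discard`` functional
    volumes are dropped; ALFF is computed on spatially smoothed series
    (``fwhm`` mm); ReHo is computed on the unsmoothed series and the ReHo map
    smoothed afterwards; structural volumes arrive already smoothed and are
    used as the GMV map directly.
    """
    maps: dict[str, list[FeatureMap]] = {f: [] for f in features}
    for scan in scans:
        if "GMV" in maps:
            maps["GMV"].append(
                FeatureMap(scan.subject_id, "GMV", np.asarray(scan.structural, float)))
        if "ALFF" in maps or "ReHo" in maps:
            func = discard_volumes(scan.functional, n_discard)
        if "ALFF" in maps:
            smoothed = _smooth_functional(func, fwhm, scan.voxel_size)
            fmap = alff_map(smoothed, scan.tr, band, mask)
            fmap.subject_id = scan.subject_id
            maps["ALFF"].append(fmap)
        if "ReHo" in maps:
            fmap = reho_map(func, mask)
            fmap.values = smooth_gaussian(fmap.values, fwhm, scan.voxel_size)
            fmap.subject_id = scan.subject_id
            maps["ReHo"].append(fmap)
    return {f: vectorize(ms, mask) for f, ms in maps.items()}
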