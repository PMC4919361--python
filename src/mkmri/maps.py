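"""Discrimination maps from per-feature SVM weight vectors.

Every in-mask voxel carries a signed classifier weight; thresholding the
absolute weights at a fraction (default 30%) of the maximum gives a spatial
representation of the regions contributing most to the group discrimination.
Weights are multivariate: retained voxels mark relative contribution, not
local statistical significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import BrainMask, map_from_vector, zscore_apply, zscore_fit
from .mkl import MultiKernelSVC, extract_weight_vectors

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.30


@dataclass
class DiscriminationMap:
    feature: str
    weights: np.ndarray          # signed 3-D weight volume, 0 outside mask
    threshold_fraction: float
    retained: np.ndarray         # boolean 3-D mask of suprathreshold voxels


def build_discrimination_map(w, mask: BrainMask, theta: float = DEFAULT_THRESHOLD,
                             feature: str = "") -> DiscriminationMap:
    """Scatter a D-vector of weights into the volume and threshold by |w|.

    A voxel is retained iff ``|w| >= theta * max|w|`` over in-mask voxels;
    out-of-mask voxels are zero and never retained.  An all-zero weight
    vector yields an empty map.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (mask.D,):
        raise ValueError(f"weight length {w.shape} does not match mask D={mask.D}")
    if not (0 < theta <= 1):
        raise ValueError("threshold fraction must lie in (0, 1]")
    volume = map_from_vector(w, mask)
    w_max = np.abs(w).max()
    if w_max == 0:
        retained = np.zeros_like(mask.grid)
    else:
        retained = (np.abs(volume) >= theta * w_max) & mask.grid
    return DiscriminationMap(feature=feature, weights=volume,
                             threshold_fraction=theta, retained=retained)


def fit_full_and_map(feature_matrices: dict, labels, mask: BrainMask,
                     C: float = 100.0, theta: float = DEFAULT_THRESHOLD,
                     normalize_kernels: bool = True):
    """Fit the multi-kernel SVM on all subjects and map each feature's weights.

    Normalization is fitted on the full cohort (the map describes the model
    trained on everyone, not a cross-validation fold).  Returns
    ``(maps, beta)`` with one :class:`DiscriminationMap` per feature.
    """
    names = list(feature_matrices)
    n = len(np.asarray(labels))
    rows = np.arange(n)
    X = []
    for name in names:
        fm = feature_matrices[name]
        X.append(zscore_apply(fm, zscore_fit(fm, rows)).values)
    clf = MultiKernelSVC(C=C, kernel="linear", normalize_kernels=normalize_kernels)
    clf.fit(X, np.asarray(labels))
    weights = extract_weight_vectors(clf)
    maps = []
    for name, beta_f, w in zip(names, clf.beta_, weights):
        if np.abs(w).max() == 0:
            logger.warning("feature %s has zero weight (beta=%g): empty map",
                           name, beta_f)
        maps.append(build_discrimination_map(w, mask, theta=theta, feature=name))
    return maps, clf.beta_
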