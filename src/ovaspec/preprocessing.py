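"""Spectral preprocessing: SNV scatter correction and SPXY sample splitting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .hsi_io import SpectraTable

logger = logging.getLogger(__name__)

__all__ = ["snv", "SNVTransformer", "SplitResult", "spxy_split"]


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Each row (or the single vector) is centered to mean 0 and divided by its
    sample standard deviation (N-1 denominator), removing multiplicative
    scatter and additive baseline shifts.  Constant spectra have no scatter
    information and raise ``ValueError``.
    """
    x = np.asarray(spectrum, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 spectral points")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    # constant spectra leave sd at float-roundoff scale, not exactly 0
    if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(mean))):
        raise ValueError("degenerate (constant) spectrum: SNV undefined")
    out = (x - mean) / sd
    return out[0] if squeeze else out


class SNVTransformer(TransformerMixin, BaseEstimator):
    """Row-wise SNV as a stateless scikit-learn transformer."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D spectra matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return snv(X)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass
class SplitResult:
    """Calibration/prediction partition (disjoint, exhaustive)."""

    calibration_ids: list
    prediction_ids: list
    calibration_idx: np.ndarray
    prediction_idx: np.ndarray

    def to_csv(self, path) -> None:
        rows = [(i, "calibration") for i in self.calibration_ids] + [
            (i, "prediction") for i in self.prediction_ids
        ]
        pd.DataFrame(rows, columns=["sample_id", "subset"]).to_csv(path, index=False)


def spxy_split(
    X, y, calib_fraction: float = 2.0 / 3.0, sample_ids=None
) -> SplitResult:
    """Sample-set partitioning based on joint X-y distances (SPXY).

    The pairwise distance is the Euclidean spectral distance plus the
    absolute response difference, each normalized by its maximum over all
    pairs.  The calibration set is seeded with the maximally distant pair
    and grown greedily by the max-min-distance rule until it holds
    ``round(calib_fraction * n)`` samples; the remainder is the prediction
    set.  Deterministic; ties break toward the lowest sample index.
    """
    if isinstance(X, SpectraTable):
        if sample_ids is None:
            sample_ids = list(X.sample_ids)
        X = X.spectra
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("SPXY needs at least 3 samples")
    if len(y) != n:
        raise ValueError("X rows and y entries must align")
    if not 0 < calib_fraction < 1:
        raise ValueError("calib_fraction must be in (0, 1)")
    if sample_ids is None:
        sample_ids = list(range(n))

    d_x = squareform(pdist(X, metric="euclidean"))
    d_y = np.abs(y[:, None] - y[None, :])
    max_dx, max_dy = d_x.max(), d_y.max()
    if max_dx == 0 and max_dy == 0:
        logger.warning("spxy_split: all samples identical; tie broken by index order")
        d = np.zeros_like(d_x)
    else:
        d = (d_x / max_dx if max_dx > 0 else d_x) + (d_y / max_dy if max_dy > 0 else d_y)

    n_cal = int(np.floor(calib_fraction * n + 0.5))
    n_cal = max(2, min(n_cal, n - 1))

    # seed with the maximally joint-distant pair (argmax of the flattened
    # matrix lands on the smallest (i, j) among ties)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    if i == j:  # all pairs at distance 0; fall back to index order
        i, j = 0, 1
    selected = [min(i, j), max(i, j)]
    dmin = np.minimum(d[selected[0]], d[selected[1]])
    dmin[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(dmin))
        selected.append(nxt)
        dmin = np.minimum(dmin, d[nxt])
        dmin[nxt] = -np.inf

    cal = np.array(sorted(selected), dtype=int)
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(
        calibration_ids=[sample_ids[k] for k in cal],
        prediction_ids=[sample_ids[k] for k in pred],
        calibration_idx=cal,
        prediction_idx=pred,
    )
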