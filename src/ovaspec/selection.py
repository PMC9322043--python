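"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

CARS whittles a full spectral grid down to a small informative subset by
alternating, for a fixed number of Monte-Carlo runs:

1. fit a PLS model on a random subset of the calibration samples and take
   the absolute regression coefficient of each retained wavelength as its
   weight;
2. force the retained count down an exponentially decreasing schedule (EDF)
   by keeping the top-weight wavelengths;
3. adaptively resample (ARS): draw wavelengths with replacement with
   probability proportional to weight and keep those drawn at least once —
   'survival of the fittest' among the EDF survivors;
4. refit PLS on the survivors with all calibration samples and record its
   cross-validated RMSE.

The subset belonging to the run with minimum RMSECV wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .hsi_io import SpectraTable
from .regression import PLSRRegressor, _cv_rmse_per_lv

logger = logging.getLogger(__name__)

__all__ = ["edf_ratio", "CARSSelector", "CARSResult", "cars", "rebuild_on_features"]


def edf_ratio(run: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing retention ratio r_i = a * exp(-k*i).

    The constants are pinned by the boundary conditions r_1 = 1 (all p
    variables eligible at the first run) and r_N = 2/p (two variables at the
    last), giving a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1).
    """
    if not 1 <= run <= n_runs:
        raise ValueError("run index must satisfy 1 <= run <= n_runs")
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n_runs == 1:
        return 1.0
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * run))


def _edf_count(run: int, n_runs: int, p: int) -> int:
    return max(2, int(np.floor(edf_ratio(run, n_runs, p) * p + 0.5)))


@dataclass
class CARSResult:
    """Outcome of one CARS selection: winning subset and per-run traces."""

    selected_indices: np.ndarray
    wavelengths_nm: np.ndarray | None
    rmsecv_trace: np.ndarray
    retained_counts: np.ndarray
    coefficient_paths: list
    best_run: int
    retained_sets: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_wavelengths_nm": (
                None
                if self.wavelengths_nm is None
                else [float(w) for w in self.wavelengths_nm]
            ),
            "rmsecv_trace": [float(v) for v in self.rmsecv_trace],
            "retained_counts": [int(c) for c in self.retained_counts],
            "best_run": int(self.best_run),
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=2)

    def trace_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "run": np.arange(1, len(self.rmsecv_trace) + 1),
                "retained_count": self.retained_counts,
                "rmsecv": self.rmsecv_trace,
            }
        ).to_csv(path, index=False)


class CARSSelector(SelectorMixin, BaseEstimator):
    """CARS as a scikit-learn feature selector.

    Parameters
    ----------
    n_runs : Monte-Carlo sampling runs (the EDF schedule length).
    cv_folds : folds for the recorded RMSECV and the internal LV choice.
    mc_fraction : fraction of calibration samples drawn (without
        replacement) per run.
    max_lv : cap on latent variables of the subset PLS models; the working
        cap is min(max_lv, n_retained, n_mc - 1).
    random_state : seed for all Monte-Carlo draws.
    """

    def __init__(
        self,
        n_runs: int = 100,
        cv_folds: int = 5,
        mc_fraction: float = 0.8,
        max_lv: int = 10,
        random_state: int | None = 0,
    ):
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.mc_fraction = mc_fraction
        self.max_lv = max_lv
        self.random_state = random_state

    def _best_lv(self, X, y, seed: int) -> int:
        cap = min(self.max_lv, X.shape[1], X.shape[0] - 1)
        if cap <= 1:
            return 1
        rmse = _cv_rmse_per_lv(X, y, cap, self.cv_folds, seed)
        return int(np.argmin(rmse)) + 1

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if p < 2:
            raise ValueError("CARS needs at least 2 variables")
        if n < self.cv_folds:
            raise ValueError("need at least cv_folds samples")
        rng = np.random.default_rng(self.random_state)
        n_mc = max(2, int(round(self.mc_fraction * n)))
        # the recorded RMSECV compares variable subsets across runs, so it
        # uses the same few CV partitions for every run (averaged to keep
        # the argmin from rewarding split luck rather than subset quality)
        trace_seeds = [int(s) for s in rng.integers(2**31, size=3)]

        retained = np.arange(p)
        trace, counts, paths, sets = [], [], [], []
        for run in range(1, self.n_runs + 1):
            # (1) MC sample + PLS weights
            mc = rng.choice(n, size=n_mc, replace=False)
            seed = int(rng.integers(2**31))
            h = self._best_lv(X[np.ix_(mc, retained)], y[mc], seed)
            model = PLSRRegressor(n_components=h).fit(X[np.ix_(mc, retained)], y[mc])
            w = np.abs(model.coef_)
            paths.append((retained.copy(), model.coef_.copy()))

            # (2) EDF: force the count down the schedule (never up)
            target = min(_edf_count(run, self.n_runs, p), retained.size)
            order = np.argsort(-w, kind="stable")[:target]
            edf_idx = retained[np.sort(order)]
            w_edf = w[np.sort(order)]

            # (3) ARS: weighted resampling with replacement among survivors
            total = w_edf.sum()
            if total <= 0:
                logger.warning("CARS run %d: all-zero weights; keeping EDF cut", run)
                keep = edf_idx
            else:
                # p draws regardless of the current subset size, as in the
                # original ARS: small informative subsets survive intact
                # while diffuse-weight subsets thin out gradually
                draws = rng.choice(edf_idx.size, size=p, replace=True,
                                   p=w_edf / total)
                keep = edf_idx[np.unique(draws)]
            if keep.size < 2:
                logger.warning("CARS run %d: retained set collapsed; stopping early", run)
                break
            retained = keep

            # (4) refit on all calibration samples, record CV error
            cap = min(self.max_lv, retained.size, n - 1)
            rmse_h = np.mean(
                [
                    _cv_rmse_per_lv(X[:, retained], y, cap, self.cv_folds, s)
                    for s in trace_seeds
                ],
                axis=0,
            )
            trace.append(float(rmse_h.min()))
            counts.append(retained.size)
            sets.append(retained.copy())

        if not trace:
            raise RuntimeError("CARS produced no completed runs")
        best = int(np.argmin(trace))
        self.rmsecv_trace_ = np.array(trace)
        self.retained_counts_ = np.array(counts, dtype=int)
        self.coefficient_paths_ = paths
        self.retained_sets_ = sets
        self.best_run_ = best
        self.selected_indices_ = np.sort(sets[best])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_indices_] = True
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def cars(
    X,
    y,
    n_runs: int = 100,
    cv_folds: int = 5,
    mc_fraction: float = 0.8,
    seed: int | None = 0,
    wavelengths_nm=None,
) -> CARSResult:
    """Functional CARS: accepts an array or :class:`SpectraTable`."""
    if isinstance(X, SpectraTable):
        wavelengths_nm = X.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        X = X.spectra
    sel = CARSSelector(
        n_runs=n_runs, cv_folds=cv_folds, mc_fraction=mc_fraction, random_state=seed
    ).fit(X, y)
    wl = None
    if wavelengths_nm is not None:
        wl = np.asarray(wavelengths_nm, dtype=float)[sel.selected_indices_]
    return CARSResult(
        selected_indices=sel.selected_indices_,
        wavelengths_nm=wl,
        rmsecv_trace=sel.rmsecv_trace_,
        retained_counts=sel.retained_counts_,
        coefficient_paths=sel.coefficient_paths_,
        best_run=sel.best_run_,
        retained_sets=sel.retained_sets_,
    )


def rebuild_on_features(table: SpectraTable, selected_indices) -> SpectraTable:
    """Column subset of a spectra table, preserving order and labels."""
    idx = np.asarray(selected_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty wavelength selection")
    if idx.min() < 0 or idx.max() >= table.wavelengths_nm.size:
        raise IndexError("selected index out of range")
    return SpectraTable(
        spectra=table.spectra[:, idx],
        wavelengths_nm=table.wavelengths_nm[idx],
        sample_ids=list(table.sample_ids),
    )
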