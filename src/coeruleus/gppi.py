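"""Generalized psychophysiological interaction (gPPI).

Context-dependent connectivity between a seed region and target voxels:
the seed BOLD series is deconvolved to an estimated neural series, the
neural series is multiplied by each condition's block indicator, each
product is re-convolved with the canonical HRF to give one interaction
regressor per condition, and a GLM per target with psychological +
physiological + interaction (+ nuisance) regressors yields interaction
betas.  The drug-minus-neutral interaction contrast is the gPPI measure;
the per-condition task regressors keep simple co-activation from
masquerading as connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import toeplitz

from .glm import (BlockSchedule, Design, FirstLevelFit, Hrf, fit_glm_ar1,
                  roi_mean)

__all__ = ["PpiRegressorSet", "GppiFit", "hrf_matrix", "deconvolve",
           "gcv_lambda", "build_ppi", "fit_gppi", "roi_gppi"]


@lru_cache(maxsize=8)
def _hrf_matrix_cached(T: int, tr: float, hrf: Hrf) -> np.ndarray:
    k = hrf.kernel_at_tr(tr)
    col = np.zeros(T)
    n = min(len(k), T)
    col[:n] = k[:n]
    return toeplitz(col, np.zeros(T))


def hrf_matrix(T: int, tr: float, hrf: Hrf | None = None) -> np.ndarray:
    """Lower-triangular Toeplitz convolution operator mapping a neural
    series on the scan grid to its BOLD response (TR-binned kernel)."""
    return _hrf_matrix_cached(T, float(tr), hrf or Hrf())


def _first_difference(T: int) -> np.ndarray:
    D = np.zeros((T - 1, T))
    idx = np.arange(T - 1)
    D[idx, idx] = -1.0
    D[idx, idx + 1] = 1.0
    return D


def gcv_lambda(bold: np.ndarray, tr: float, hrf: Hrf | None = None,
               grid: np.ndarray | None = None) -> float:
    """Generalized cross-validation choice of the deconvolution ridge
    weight over a log-spaced grid."""
    y = np.asarray(bold, dtype=float)
    T = len(y)
    H = hrf_matrix(T, tr, hrf)
    D = _first_difference(T)
    HtH = H.T @ H
    DtD = D.T @ D
    Hty = H.T @ y
    if grid is None:
        grid = np.logspace(-4, 2, 13)
    best_lam, best_score = float(grid[0]), np.inf
    for lam in grid:
        A = HtH + lam * DtD
        n_hat = np.linalg.solve(A, Hty)
        fitted = H @ n_hat
        # effective dof = trace of the hat matrix H A^-1 H'
        edf = float(np.trace(np.linalg.solve(A, HtH)))
        denom = max(T - edf, 1.0)
        score = T * float(np.sum((y - fitted) ** 2)) / denom ** 2
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


def deconvolve(bold: np.ndarray, tr: float, lam: float | None = None,
               hrf: Hrf | None = None) -> np.ndarray:
    """Estimate the underlying neural series from mean-corrected BOLD.

    Solves the ridge-regularized least-squares problem
    ``min ||bold - H n||^2 + lam ||D n||^2`` with H the HRF convolution
    operator and D the first-difference smoother.  ``lam=None`` selects the
    weight by generalized cross-validation.
    """
    y = np.asarray(bold, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("BOLD series contains non-finite values")
    if lam is None:
        lam = gcv_lambda(y, tr, hrf)
    if lam < 0:
        raise ValueError("regularization weight must be >= 0")
    T = len(y)
    H = hrf_matrix(T, tr, hrf)
    D = _first_difference(T)
    A = H.T @ H + lam * (D.T @ D)
    return np.linalg.solve(A, H.T @ y)


@dataclass
class PpiRegressorSet:
    """Physiological, psychological and per-condition interaction
    regressors for one subject and seed."""

    physio: np.ndarray                  # observed seed BOLD, T
    psych: dict[str, np.ndarray]        # convolved boxcar per condition
    interaction: dict[str, np.ndarray]  # PPI regressor per condition
    lam: float

    def __post_init__(self) -> None:
        T = len(self.physio)
        for d in (self.psych, self.interaction):
            for c, v in d.items():
                if len(v) != T:
                    raise ValueError(f"regressor {c!r} length mismatch")
        if set(self.psych) != set(self.interaction):
            raise ValueError("one interaction regressor per condition")


def build_ppi(neural: np.ndarray, seed_bold: np.ndarray,
              schedule: BlockSchedule, tr: float, n_scans: int,
              hrf: Hrf | None = None, lam: float = 0.0) -> PpiRegressorSet:
    """Construct the gPPI regressor set from a deconvolved neural series.

    The neural series is mean-corrected, multiplied by each condition's
    block indicator sampled on the scan grid, and re-convolved with the
    HRF.  Psychological regressors are the HRF-convolved boxcars; the
    physiological regressor is the observed seed BOLD itself.
    """
    neural = np.asarray(neural, dtype=float)
    if len(neural) != n_scans:
        raise ValueError("neural series length does not match scan count")
    if schedule.end_time() > n_scans * tr + 1e-9:
        raise ValueError("schedule does not fit within the scan window")
    hrf = hrf or Hrf()
    neural = neural - neural.mean()
    H = hrf_matrix(n_scans, tr, hrf)
    psych, inter = {}, {}
    for c in schedule.conditions:
        ind = schedule.indicator(tr, n_scans, c)
        psych[c] = H @ ind
        inter[c] = H @ (neural * ind)
    return PpiRegressorSet(physio=np.asarray(seed_bold, dtype=float),
                           psych=psych, interaction=inter, lam=lam)


@dataclass
class GppiFit:
    fit: FirstLevelFit
    interaction_beta: dict[str, np.ndarray]   # per condition, per target
    contrast: np.ndarray                      # drug - neutral, per target


def fit_gppi(targets: np.ndarray, ppi: PpiRegressorSet,
             nuisance: np.ndarray | None = None,
             contrast_pair: tuple[str, str] = ("drug", "neutral")
             ) -> GppiFit:
    """Whole-target gPPI GLM with AR(1) prewhitening.

    Design: psychological regressors, seed physiological regressor, one
    interaction regressor per condition, optional nuisance columns and an
    intercept.  The gPPI contrast is the interaction-beta difference for
    ``contrast_pair`` (drug - neutral by default).
    """
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    conds = sorted(ppi.psych)
    cols = [ppi.psych[c] for c in conds]
    names = [f"psych_{c}" for c in conds]
    cols.append(ppi.physio)
    names.append("physio")
    for c in conds:
        cols.append(ppi.interaction[c])
        names.append(f"ppi_{c}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != Y.shape[0]:
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance{j:02d}")
    cols.append(np.ones(Y.shape[0]))
    names.append("intercept")
    design = Design(matrix=np.column_stack(cols), names=names)
    fit = fit_glm_ar1(Y, design)
    betas = {c: fit.beta[names.index(f"ppi_{c}")] for c in conds}
    a, b = contrast_pair
    if a not in betas or b not in betas:
        raise ValueError(f"conditions {contrast_pair} not in design")
    return GppiFit(fit=fit, interaction_beta=betas,
                   contrast=betas[a] - betas[b])


def roi_gppi(contrast_map: np.ndarray, masks: list[np.ndarray]
             ) -> list[float]:
    """Mean gPPI contrast within each ROI mask (error on an empty mask)."""
    return [roi_mean(contrast_map, m) for m in masks]
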