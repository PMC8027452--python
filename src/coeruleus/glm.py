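"""Cue-reactivity general linear model.

Builds block designs convolved with the canonical double-gamma HRF, fits
first-level GLMs with AR(1) prewhitening, forms condition contrasts,
extracts ROI means, and runs group-level random-effects inference with
sign-flip permutation cluster-extent FWE correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hrf:
    """Canonical double-gamma hemodynamic response function.

    Parameters are the community defaults: response peaking near
    ``peak_delay`` seconds, an undershoot near ``undershoot_delay`` seconds
    scaled down by ``ratio``, truncated at ``length`` seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.length < 24.0:
            raise ValueError("HRF kernel length must be >= 24 s")
        if self.dt <= 0:
            raise ValueError("HRF sampling interval must be positive")

    def kernel(self) -> np.ndarray:
        """Kernel sampled at ``dt``; normalized to unit sum so a sustained
        unit boxcar reaches a plateau of 1."""
        t = np.arange(0.0, self.length + self.dt / 2, self.dt)
        peak = stats.gamma.pdf(t, self.peak_delay / self.peak_disp,
                               scale=self.peak_disp)
        under = stats.gamma.pdf(t, self.undershoot_delay / self.undershoot_disp,
                                scale=self.undershoot_disp)
        h = peak - under / self.ratio
        s = h.sum() * 1.0
        if s <= 0:
            raise ValueError("HRF kernel must sum to a positive value")
        return h / s

    def kernel_at_tr(self, tr: float, n: int | None = None) -> np.ndarray:
        """Kernel binned to the scan grid: each tap is the mean of the
        fine-grid kernel over one TR-wide bin (the exact discretization for
        a neural signal that is piecewise constant over scans).  The first
        tap is then nonzero, keeping the convolution operator full rank."""
        fine = self.kernel()
        per = max(int(round(tr / self.dt)), 1)
        n_taps = int(np.ceil(len(fine) / per))
        out = np.array([fine[i * per:(i + 1) * per].sum()
                        for i in range(n_taps)])
        if n is not None:
            out = out[:n]
        return out


# ---------------------------------------------------------------------------
# Block schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSchedule:
    """Onsets and durations (seconds) for a two-condition block design."""

    conditions: tuple[str, ...] = ("drug", "neutral")
    onsets: dict[str, np.ndarray] = field(default_factory=dict)
    durations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivals = []
        for c in self.conditions:
            on = np.asarray(self.onsets.get(c, []), dtype=float)
            du = np.asarray(self.durations.get(c, []), dtype=float)
            if on.shape != du.shape:
                raise ValueError(f"onsets/durations mismatch for {c!r}")
            if np.any(on < 0):
                raise ValueError("onsets must be >= 0")
            ivals.extend(zip(on, on + du))
        ivals.sort()
        for (a0, a1), (b0, _b1) in zip(ivals, ivals[1:]):
            if b0 < a1 - 1e-9:
                raise ValueError("overlapping blocks in schedule")

    @classmethod
    def alternating(cls, n_blocks: int = 6, block_cycle: float = 45.0,
                    fixation: float = 2.0, picture_duration: float = 36.0,
                    conditions: tuple[str, str] = ("drug", "neutral"),
                    ) -> "BlockSchedule":
        """Alternating two-condition design: each block opens with a
        fixation cross, then the picture period of ``picture_duration`` s.
        ``n_blocks`` blocks per condition, interleaved."""
        onsets = {c: [] for c in conditions}
        durs = {c: [] for c in conditions}
        for k in range(2 * n_blocks):
            c = conditions[k % 2]
            onsets[c].append(k * block_cycle + fixation)
            durs[c].append(picture_duration)
        return cls(conditions=conditions,
                   onsets={c: np.array(v) for c, v in onsets.items()},
                   durations={c: np.array(v) for c, v in durs.items()})

    def end_time(self) -> float:
        t = 0.0
        for c in self.conditions:
            on = np.asarray(self.onsets.get(c, []), dtype=float)
            du = np.asarray(self.durations.get(c, []), dtype=float)
            if len(on):
                t = max(t, float(np.max(on + du)))
        return t

    def indicator(self, tr: float, n_scans: int, condition: str) -> np.ndarray:
        """Block indicator sampled at scan acquisition times (0, TR, 2TR, ...)."""
        t = np.arange(n_scans) * tr
        ind = np.zeros(n_scans)
        on = np.asarray(self.onsets.get(condition, []), dtype=float)
        du = np.asarray(self.durations.get(condition, []), dtype=float)
        for o, d in zip(on, du):
            ind[(t >= o) & (t < o + d)] = 1.0
        return ind


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class Design:
    matrix: np.ndarray          # T x p
    names: list[str]

    @property
    def rank_deficient(self) -> bool:
        return np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]

    def collinear_columns(self, tol: float = 1e-8) -> list[str]:
        """Names of columns flagged by pivoted-QR as linearly dependent."""
        from scipy.linalg import qr
        _q, r, piv = qr(self.matrix, pivoting=True, mode="economic")
        d = np.abs(np.diag(r))
        bad = d < tol * max(d.max(), 1.0)
        return [self.names[piv[i]] for i in np.nonzero(bad)[0]]


def build_design(schedule: BlockSchedule, tr: float, n_scans: int,
                 nuisance: np.ndarray | None = None,
                 hrf: Hrf | None = None,
                 high_pass: float | None = 128.0) -> Design:
    """Boxcars per condition convolved with the HRF at fine resolution, then
    sampled at scan times; optional discrete-cosine high-pass columns,
    nuisance columns and a trailing intercept."""
    if schedule.end_time() > n_scans * tr + 1e-9:
        raise ValueError("schedule does not fit within the scan window")
    hrf = hrf or Hrf()
    k = hrf.kernel()
    dt = hrf.dt
    n_fine = int(np.ceil(n_scans * tr / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    cols, names = [], []
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    for c in schedule.conditions:
        box = np.zeros(n_fine)
        on = np.asarray(schedule.onsets.get(c, []), dtype=float)
        du = np.asarray(schedule.durations.get(c, []), dtype=float)
        for o, d in zip(on, du):
            box[(t_fine >= o) & (t_fine < o + d)] = 1.0
        reg = np.convolve(box, k)[:n_fine][scan_idx]
        cols.append(reg)
        names.append(c)
    if high_pass is not None and high_pass > 0:
        n_basis = int(np.floor(2.0 * n_scans * tr / high_pass))
        t = np.arange(n_scans)
        for j in range(1, n_basis + 1):
            cols.append(np.sqrt(2.0 / n_scans)
                        * np.cos(np.pi * j * (2 * t + 1) / (2 * n_scans)))
            names.append(f"cosine{j:02d}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance length does not match scan count")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance{j:02d}")
    cols.append(np.ones(n_scans))
    names.append("intercept")
    return Design(matrix=np.column_stack(cols), names=names)


# ---------------------------------------------------------------------------
# First-level fit with AR(1) prewhitening
# ---------------------------------------------------------------------------

@dataclass
class FirstLevelFit:
    beta: np.ndarray            # p x V
    resid_var: np.ndarray       # V
    rho: float
    design: Design
    df: int

    @property
    def names(self) -> list[str]:
        return self.design.names


def _ar1_whiten(M: np.ndarray, rho: float) -> np.ndarray:
    W = np.empty_like(M, dtype=float)
    W[0] = M[0] * np.sqrt(1.0 - rho ** 2)
    W[1:] = M[1:] - rho * M[:-1]
    return W


def fit_glm_ar1(Y: np.ndarray, design: Design | np.ndarray,
                names: list[str] | None = None) -> FirstLevelFit:
    """Two-pass AR(1)-prewhitened least squares.

    An OLS pass estimates a single lag-1 residual autocorrelation rho pooled
    across voxels; data and design are then filtered by the AR(1) whitening
    transform and refit.  For rho = 0 the result equals plain OLS.
    """
    if isinstance(design, Design):
        X = design.matrix
    else:
        X = np.asarray(design, dtype=float)
        design = Design(matrix=X, names=names or
                        [f"x{j}" for j in range(X.shape[1])])
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design; collinear columns: "
                         + ", ".join(design.collinear_columns()))
    if T <= rank + 2:
        raise ValueError("too few scans for the design")
    beta0, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta0
    num = float(np.sum(E[1:] * E[:-1]))
    den = float(np.sum(E * E))
    rho = num / den if den > 0 else 0.0
    rho = float(np.clip(rho, -0.99, 0.99))
    Xw = _ar1_whiten(X, rho)
    Yw = _ar1_whiten(Y, rho)
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid = Yw - Xw @ beta
    df = T - rank
    resid_var = np.sum(resid ** 2, axis=0) / df
    return FirstLevelFit(beta=beta, resid_var=resid_var, rho=rho,
                         design=design, df=df)


def contrast(fit: FirstLevelFit, weights: np.ndarray) -> np.ndarray:
    """Weighted combination of betas per voxel (a contrast map)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.beta.shape[0],):
        raise ValueError(f"weights length {w.shape} does not match "
                         f"{fit.beta.shape[0]} regressors")
    return w @ fit.beta


def contrast_weights(design: Design, plus: str, minus: str | None = None
                     ) -> np.ndarray:
    w = np.zeros(design.matrix.shape[1])
    w[design.names.index(plus)] = 1.0
    if minus is not None:
        w[design.names.index(minus)] = -1.0
    return w


def roi_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``values`` over the boolean ``mask``."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("value map and mask are on different lattices")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(values[mask].mean())


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

def group_onesample(cons: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Voxelwise one-sample t against 0 over N subject contrast maps.

    Returns (t map, df = N-1, zero-variance flag); zero-variance voxels get
    t = +/-inf (sign of the mean, 0 if the mean is 0 too).
    """
    cons = np.asarray(cons, dtype=float)
    n = cons.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    m = cons.mean(axis=0)
    sd = cons.std(axis=0, ddof=1)
    flag = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    signed_inf = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
    t = np.where(flag, signed_inf, t)
    return t, n - 1, flag


def _max_cluster_size(t: np.ndarray, thr: float, structure: np.ndarray) -> int:
    best = 0
    for sup in (t >= thr, t <= -thr):
        lab, nlab = ndimage.label(sup, structure=structure)
        if nlab:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def cluster_fwe(cons: np.ndarray, shape: tuple[int, ...],
                voxel_p: float = 0.001, n_perm: int = 1000,
                seed: int | None = 0) -> pd.DataFrame:
    """Cluster-extent FWE by sign-flip permutation.

    ``cons``: N x V subject contrast maps (V = prod(shape)).  Clusters are
    26-connected components of the one-sample t map above the two-sided
    voxelwise threshold at ``voxel_p``; the corrected p of a cluster is the
    proportion of permutations (random sign flips of whole subjects, the
    identity flip included) whose maximum cluster size reaches its size.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    cons = np.asarray(cons, dtype=float)
    n, v = cons.shape
    if int(np.prod(shape)) != v:
        raise ValueError("shape does not match map size")
    t, df, _ = group_onesample(cons)
    thr = float(stats.t.ppf(1.0 - voxel_p / 2.0, df))
    t3 = t.reshape(shape)
    structure = np.ones((3,) * len(shape), dtype=bool)
    rows = []
    for sign, sup in ((1, t3 >= thr), (-1, t3 <= -thr)):
        lab, nlab = ndimage.label(sup, structure=structure)
        for li in range(1, nlab + 1):
            vox = lab == li
            size = int(vox.sum())
            sub_t = np.where(vox, sign * t3, -np.inf)
            peak = np.unravel_index(int(np.argmax(sub_t)), shape)
            rows.append({"sign": sign, "size": size,
                         "peak": tuple(int(x) for x in peak),
                         "peak_t": float(t3[peak])})
    if not rows:
        return pd.DataFrame(columns=["sign", "size", "peak", "peak_t",
                                     "p_fwe"])
    rng = np.random.default_rng(seed)
    max_sizes = np.empty(n_perm + 1, dtype=int)
    max_sizes[0] = _max_cluster_size(t3, thr, structure)   # identity flip
    for b in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n)
        tb, _, _ = group_onesample(cons * flips[:, None])
        max_sizes[b + 1] = _max_cluster_size(tb.reshape(shape), thr,
                                             structure)
    for r in rows:
        r["p_fwe"] = float(np.mean(max_sizes >= r["size"]))
    out = pd.DataFrame(rows).sort_values("size", ascending=False)
    return out.reset_index(drop=True)
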