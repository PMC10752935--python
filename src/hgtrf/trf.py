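"""Temporal response function estimation by coordinate-descent boosting.

The response model is the linear convolution y(t) = Σ_τ Σ_p x_p(t−τ) h_p(τ) +
n(t), fitted per voxel and per dipole component.  Kernels are parameterized on
an overlapping basis of short Hamming windows (one window per lag sample) so
estimates vary smoothly over lags.  Fitting is greedy coordinate descent: at
each iteration, of all (predictor, window, ±δ) candidate steps the one that
most reduces training error is applied; cross-validated early stopping (fixed
patience, rollback to the best validation state) regularizes the estimate, and
the final kernel is the mean over folds.  Because every candidate coordinate
of every predictor is swept before a step is chosen, predictors compete to
explain variance and the predictor ordering cannot affect the estimates.

The inner loop works on sufficient statistics (Gram matrices of the lagged
design and residual-design correlations), so fitting many channels — all
voxels, components, subjects and conditions that share one predictor set — is
a single vectorized run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .predictors import Predictor
from .synth import SourceRecording, SourceSpace, lag_convolve

__all__ = [
    "LagBasis",
    "TRFFit",
    "AccuracyMap",
    "BoostDesign",
    "build_basis",
    "make_design",
    "boost_many",
    "boost_trf",
    "predict_response",
    "prediction_accuracy",
    "trf_amplitude",
    "smooth_accuracy",
]


@dataclass
class LagBasis:
    """Overlapping tapered windows mapping basis coefficients to lag kernels."""

    lag_grid_ms: np.ndarray     # (L,) lags covered, one per response sample
    rate: float
    width_ms: float
    matrix: np.ndarray          # (n_windows, L); kernel = coefficients @ matrix

    @property
    def n_lags(self) -> int:
        return self.lag_grid_ms.size

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def lag_samples(self) -> np.ndarray:
        return np.round(self.lag_grid_ms * self.rate / 1000.0).astype(int)


def build_basis(
    tmin_ms: float = -40.0,
    tmax_ms: float = 210.0,
    rate: float = 500.0,
    width_ms: float = 4.0,
) -> LagBasis:
    """Lag grid [tmin, tmax) at the response rate with one Hamming window per lag.

    At 500 Hz the default −40–210 ms window gives 125 lag samples (−40 … 208
    ms).  Each basis window is a ``width_ms``-wide Hamming taper centered on
    its lag sample; when the width equals one sample period the basis reduces
    to the identity (delta bases).
    """
    if tmin_ms >= tmax_ms:
        raise ValueError("tmin_ms must be below tmax_ms")
    step_ms = 1000.0 / rate
    lags = np.arange(tmin_ms, tmax_ms - 1e-9, step_ms)
    n = lags.size
    half = int(np.floor(width_ms / 2.0 / step_ms))
    taper = windows.hamming(2 * half + 1, sym=True)
    mat = np.zeros((n, n))
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        mat[i, lo:hi] = taper[lo - (i - half) : hi - (i - half)]
    return LagBasis(lags, rate, width_ms, mat)


@dataclass
class TRFFit:
    """Estimated vector kernels plus everything needed to predict and score."""

    kernels: np.ndarray              # (V, P, 3, L), mean over folds
    lag_grid_ms: np.ndarray
    rate: float
    fold_count: int
    predictor_labels: tuple[str, ...]
    fold_kernels: np.ndarray | None = None   # (F, V, P, 3, L)
    fold_slices: tuple[tuple[int, int], ...] = ()
    n_steps: np.ndarray | None = None        # boosting steps per channel (V*3,)
    n_ties: int = 0
    degenerate_channels: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    source_space: SourceSpace | None = None

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AccuracyMap:
    """Per-voxel prediction accuracies (Pearson r, in [-1, 1])."""

    values: np.ndarray
    smoothed: bool = False
    smoothing_sd_mm: float = 0.0


@dataclass
class BoostDesign:
    """Precomputed design shared by every response fitted to one predictor set."""

    X: np.ndarray                    # (T, C) lagged-and-tapered predictors
    basis: LagBasis
    n_predictors: int
    fold_slices: tuple[tuple[int, int], ...]
    G_train: np.ndarray              # (F, C, C)
    G_val: np.ndarray                # (F, C, C)

    @property
    def n_folds(self) -> int:
        return len(self.fold_slices)


def _lagged_matrix(x: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    n = x.size
    out = np.zeros((n, lag_samples.size))
    for i, s in enumerate(lag_samples):
        if s >= 0:
            out[s:, i] = x[: n - s] if s > 0 else x
        else:
            out[: n + s, i] = x[-s:]
    return out


def make_design(
    predictor_values: np.ndarray, basis: LagBasis, n_folds: int = 4
) -> BoostDesign:
    """Build the lagged design and per-fold Gram matrices.

    ``predictor_values``: (P, T).  Folds are contiguous time segments; for
    each fold the held-out segment is validation and the rest training.
    """
    pv = np.atleast_2d(np.asarray(predictor_values, dtype=np.float64))
    n_pred, n_t = pv.shape
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    lag_samples = basis.lag_samples
    cols = []
    for p in range(n_pred):
        cols.append(_lagged_matrix(pv[p], lag_samples) @ basis.matrix.T)
    X = np.concatenate(cols, axis=1)
    bounds = np.linspace(0, n_t, n_folds + 1).round().astype(int)
    fold_slices = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(n_folds))
    G_full = X.T @ X
    G_val = np.empty((n_folds, X.shape[1], X.shape[1]))
    for f, (lo, hi) in enumerate(fold_slices):
        Xv = X[lo:hi]
        G_val[f] = Xv.T @ Xv
    G_train = G_full[None] - G_val
    return BoostDesign(X, basis, n_pred, fold_slices, G_train, G_val)


def boost_many(
    design: BoostDesign,
    Y: np.ndarray,
    delta_fraction: float = 0.005,
    patience: int = 10,
    max_iter: int | None = None,
):
    """Vectorized boosting of many channels against one shared design.

    ``Y``: (n_channels, T).  Returns ``(coefs, info)`` where ``coefs`` has
    shape (n_folds, n_channels, C) in basis-window space and ``info`` carries
    per-channel step counts, the tie count, and the zero-variance channel
    mask.  Deterministic; ties in error reduction resolve to the lowest
    coordinate index (predictor-major) and to +δ before −δ.
    """
    X = design.X
    n_chan, n_t = Y.shape
    if n_t != X.shape[0]:
        raise ValueError("response length does not match the design")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite response values")
    n_coord = X.shape[1]
    if max_iter is None:
        max_iter = 40 * n_coord
    sd = Y.std(axis=1)
    degenerate = sd <= 0
    delta = delta_fraction * np.where(degenerate, 1.0, sd)

    C_full = Y @ X                      # (n_chan, C)
    coefs = np.zeros((design.n_folds, n_chan, n_coord))
    n_steps = np.zeros(n_chan, dtype=int)
    n_ties = 0
    for f, (lo, hi) in enumerate(design.fold_slices):
        Yv = Y[:, lo:hi]
        C_val = Yv @ X[lo:hi]
        C_tr = C_full - C_val
        E_val = (Yv**2).sum(axis=1)
        g_tr = np.diag(design.G_train[f]).copy()
        g_val = np.diag(design.G_val[f]).copy()
        coef = np.zeros((n_chan, n_coord))
        best = np.zeros((n_chan, n_coord))
        best_val = E_val.copy()
        wait = np.zeros(n_chan, dtype=int)
        active = ~degenerate.copy()
        it = 0
        while active.any() and it < max_iter:
            it += 1
            idx = np.flatnonzero(active)
            d = delta[idx][:, None]
            Ca = C_tr[idx]
            dE = d * d * g_tr[None, :] - 2.0 * d * np.abs(Ca)
            j = np.argmin(dE, axis=1)
            rows = np.arange(idx.size)
            dE_best = dE[rows, j]
            n_ties += int(((dE == dE_best[:, None]).sum(axis=1) > 1).sum())
            stall = dE_best >= 0
            if stall.any():
                active[idx[stall]] = False
            go = ~stall
            if not go.any():
                continue
            ci = idx[go]
            jj = j[go]
            step = np.where(Ca[rows[go], jj] >= 0, 1.0, -1.0) * delta[ci]
            coef[ci, jj] += step
            n_steps[ci] += 1
            dEv = -2.0 * step * C_val[ci, jj] + step * step * g_val[jj]
            E_val[ci] += dEv
            C_tr[ci] -= step[:, None] * design.G_train[f][jj]
            C_val[ci] -= step[:, None] * design.G_val[f][jj]
            improved = E_val[ci] < best_val[ci]
            imp = ci[improved]
            best[imp] = coef[imp]
            best_val[imp] = E_val[imp]
            wait[imp] = 0
            wait[ci[~improved]] += 1
            timed_out = ci[wait[ci] > patience]
            if timed_out.size:
                active[timed_out] = False
        coefs[f] = best
    info = {"n_steps": n_steps, "n_ties": n_ties, "degenerate": degenerate}
    return coefs, info


def _coefs_to_kernels(coefs: np.ndarray, basis: LagBasis, n_pred: int) -> np.ndarray:
    """(F, n_chan, P*W) window coefficients -> (F, n_chan, P, L) lag kernels."""
    f, n_chan, _ = coefs.shape
    c = coefs.reshape(f, n_chan, n_pred, basis.n_windows)
    return c @ basis.matrix


def boost_trf(
    predictors: list[Predictor],
    response: SourceRecording,
    basis: LagBasis,
    n_folds: int = 4,
    delta_fraction: float = 0.005,
    patience: int = 10,
    design: BoostDesign | None = None,
) -> TRFFit:
    """Fit joint multi-predictor vector TRFs for one recording.

    Each of the 3 dipole components of each voxel is fitted independently; the
    returned kernel is the mean across cross-validation folds, expanded
    through the Hamming basis.  Zero-variance components yield zero kernels
    and are flagged.
    """
    for p in predictors:
        if p.rate != response.rate:
            raise ValueError("predictor and response rates differ")
        if p.n_samples != response.n_times:
            raise ValueError("predictor and response lengths differ")
        if not np.isfinite(p.values).all():
            raise ValueError("non-finite predictor values")
    pv = np.stack([p.values for p in predictors])
    if design is None:
        design = make_design(pv, basis, n_folds)
    n_vox = response.n_voxels
    Y = response.data.reshape(n_vox * 3, response.n_times)
    coefs, info = boost_many(design, Y, delta_fraction, patience)
    kern = _coefs_to_kernels(coefs, basis, len(predictors))
    fold_kernels = kern.reshape(
        design.n_folds, n_vox, 3, len(predictors), basis.n_lags
    ).transpose(0, 1, 3, 2, 4)
    kernels = fold_kernels.mean(axis=0)
    config = {
        "n_folds": design.n_folds,
        "delta_fraction": delta_fraction,
        "patience": patience,
        "tmin_ms": float(basis.lag_grid_ms[0]),
        "tmax_ms": float(basis.lag_grid_ms[-1]),
        "width_ms": basis.width_ms,
        "rate": response.rate,
    }
    return TRFFit(
        kernels=kernels,
        lag_grid_ms=basis.lag_grid_ms,
        rate=response.rate,
        fold_count=design.n_folds,
        predictor_labels=tuple(p.source_label or p.kind for p in predictors),
        fold_kernels=fold_kernels,
        fold_slices=design.fold_slices,
        n_steps=info["n_steps"],
        n_ties=info["n_ties"],
        degenerate_channels=info["degenerate"].reshape(n_vox, 3),
        config=config,
        source_space=response.source_space,
    )


def predict_response(
    fit: TRFFit, predictors: list[Predictor], kernels: np.ndarray | None = None
) -> SourceRecording:
    """Forward prediction Σ_p x_p ⊛ h_p with zero-padded edges."""
    if kernels is None:
        kernels = fit.kernels
    n_vox = kernels.shape[0]
    n = predictors[0].n_samples
    data = np.zeros((n_vox, 3, n))
    for ip, pred in enumerate(predictors):
        data += lag_convolve(pred.values, kernels[:, ip], fit.lag_grid_ms, fit.rate)
    space = fit.source_space
    if space is None:
        coords = np.zeros((n_vox, 3))
        coords[:, 0] = np.arange(n_vox) * 7.0
        space = SourceSpace(coords, 7.0)
    return SourceRecording(data, fit.rate, space, {"predicted": True})


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; 0 where either row has zero variance."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = na * nb
    ok = denom > 0
    out = np.zeros(a.shape[:-1])
    out[ok] = (a * b).sum(axis=-1)[ok] / denom[ok]
    return out


def prediction_accuracy(
    fit: TRFFit,
    predictors: list[Predictor],
    response: SourceRecording,
    cross_validated: bool = True,
    reduction: str = "mean_component",
) -> AccuracyMap:
    """Per-voxel Pearson correlation between predicted and measured responses.

    With ``cross_validated`` (default) each time segment is predicted by the
    kernel trained with that segment held out, so accuracies are out-of-sample.
    ``reduction``: "mean_component" averages the per-component correlations;
    "concatenated" correlates the stacked 3-component series.
    """
    if cross_validated and fit.fold_kernels is not None and fit.fold_slices:
        pred = np.zeros_like(response.data)
        for f, (lo, hi) in enumerate(fit.fold_slices):
            full = predict_response(fit, predictors, kernels=fit.fold_kernels[f])
            pred[:, :, lo:hi] = full.data[:, :, lo:hi]
    else:
        pred = predict_response(fit, predictors).data
    if reduction == "mean_component":
        r = _pearson_rows(pred, response.data).mean(axis=1)
    elif reduction == "concatenated":
        v = response.n_voxels
        r = _pearson_rows(pred.reshape(v, -1), response.data.reshape(v, -1))
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return AccuracyMap(r)


def trf_amplitude(fit: TRFFit | np.ndarray) -> np.ndarray:
    """L2 norm over the 3 dipole components: (V, P, L) amplitude series."""
    kernels = fit.kernels if isinstance(fit, TRFFit) else np.asarray(fit)
    return np.linalg.norm(kernels, axis=-2)


def smooth_accuracy(
    acc: AccuracyMap, source_space: SourceSpace, sd_mm: float = 5.0
) -> AccuracyMap:
    """Gaussian smoothing over voxel positions, renormalized on the voxel set.

    Weights w_ij = exp(−d_ij²/(2·sd²)) over physical mm distances are
    normalized per target voxel so no weight leaks outside the available set;
    a constant map is unchanged and sd→0 is the identity.
    """
    values = np.asarray(acc.values, dtype=np.float64)
    if sd_mm <= 0:
        return AccuracyMap(values.copy(), smoothed=True, smoothing_sd_mm=sd_mm)
    coords = source_space.voxel_coords_mm
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-0.5 * d2 / sd_mm**2)
    w /= w.sum(axis=1, keepdims=True)
    return AccuracyMap(w @ values, smoothed=True, smoothing_sd_mm=sd_mm)
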