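"""End-to-end cohort analyses: predictors → TRFs → nulls → group statistics.

Two experiment designs are orchestrated over a (synthetic) cohort:

* **single-speaker** — per subject and speaker, the two-predictor model
  (carrier + envelope modulations) is fitted to that speaker's condition;
* **cocktail-party** — per subject and attention condition, the four-predictor
  model (carrier + envelope for both concurrent speakers) is fitted, and
  attended vs. ignored peak amplitudes are compared per predictor kind.

Both runs share the same machinery: a circular-shift null ensemble per fit,
noise-floor-corrected amplitudes, 20–50 ms peak extraction, cross-validated
prediction accuracies with 5-mm spatial smoothing, and one-tailed paired-t +
TFCE permutation tests over lags (amplitude vs. null) and over voxels
(accuracy vs. null).  Because every subject and condition in a cohort shares
one stimulus pair, all fits against one predictor set are batched through a
single precomputed boosting design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .nullmodels import SHIFT_FRACTIONS
from .stats import (
    GridAdjacency,
    compare_peaks_wilcoxon,
    extract_peaks,
    permutation_test,
    voxel_adjacency,
)
from .synth import COCKTAIL_LABELS, SyntheticCohort
from .trf import (
    AccuracyMap,
    LagBasis,
    _coefs_to_kernels,
    _pearson_rows,
    boost_many,
    build_basis,
    make_design,
    smooth_accuracy,
)

logger = logging.getLogger("hgtrf")

__all__ = ["RunConfig", "RunReport", "run_single_speaker", "run_cocktail_party"]


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis parameters; the hash stamps every output."""

    rate: float = 500.0
    band: tuple[float, float] = (70.0, 200.0)
    transition_hz: float = 5.0
    tmin_ms: float = -40.0
    tmax_ms: float = 210.0
    basis_width_ms: float = 4.0
    n_folds: int = 4
    delta_fraction: float = 0.005
    patience: int = 10
    shift_fractions: tuple[float, ...] = SHIFT_FRACTIONS
    peak_window_ms: tuple[float, float] = (20.0, 50.0)
    alpha: float = 0.05
    n_permutations: int = 1000
    smoothing_sd_mm: float = 5.0
    accuracy_cv: bool = True
    compute_accuracy: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.tmin_ms >= self.tmax_ms:
            raise ValueError("tmin_ms must be below tmax_ms")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.peak_window_ms[0] >= self.peak_window_ms[1]:
            raise ValueError("empty peak window")
        if len(self.shift_fractions) < 1 or not all(
            0 < f < 1 for f in self.shift_fractions
        ):
            raise ValueError("shift fractions must lie in (0, 1)")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def basis(self) -> LagBasis:
        return build_basis(self.tmin_ms, self.tmax_ms, self.rate, self.basis_width_ms)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "shift_fractions", "peak_window_ms"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Everything a run produced, traceable to the config hash and seed."""

    scenario: str
    config: dict
    config_hash: str
    seed: int
    n_subjects: int
    accuracy_summary: dict = field(default_factory=dict)
    amplitude_tests: dict = field(default_factory=dict)
    accuracy_tests: dict = field(default_factory=dict)
    wilcoxon: dict = field(default_factory=dict)
    peak_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    timings_s: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "accuracy_summary": self.accuracy_summary,
            "amplitude_tests": self.amplitude_tests,
            "accuracy_tests": self.accuracy_tests,
            "wilcoxon": self.wilcoxon,
            "n_peak_rows": int(len(self.peak_table)),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        )
        hio.save_peak_table(out / "peaks.tsv", self.peak_table)


def _derived_seed(base: int, tag: str) -> int:
    digest = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stack_responses(cohort: SyntheticCohort, condition: str) -> np.ndarray:
    """(S, V, 3, T) response stack for one condition."""
    return np.stack([s[condition].data for s in cohort.subjects])


class _BatchFits:
    """Per-variant kernels for a batch of responses sharing one design."""

    def __init__(self, design, coefs, n_resp, n_vox, n_pred, basis):
        kern = _coefs_to_kernels(coefs, basis, n_pred)  # (F, chan, P, L)
        f = design.n_folds
        self.fold_kernels = kern.reshape(
            f, n_resp, n_vox, 3, n_pred, basis.n_lags
        ).transpose(0, 1, 2, 4, 3, 5)  # (F, R, V, P, 3, L)
        self.kernels = self.fold_kernels.mean(axis=0)  # (R, V, P, 3, L)
        self.design = design
        self.basis = basis
        self._fold_coefs = coefs  # (F, chan, C) in basis-window space

    def amplitudes(self) -> np.ndarray:
        """(R, V, P, L) vector-norm amplitude series."""
        return np.linalg.norm(self.kernels, axis=-2)

    def cv_accuracy(self, Y: np.ndarray, rate: float) -> np.ndarray:
        """(R, V) cross-validated prediction accuracies (mean over components)."""
        n_resp, n_vox = self.kernels.shape[:2]
        t = Y.shape[-1]
        pred = np.zeros((n_resp, n_vox, 3, t))
        # predict each held-out segment with that fold's kernels via the design
        for f, (lo, hi) in enumerate(self.design.fold_slices):
            seg = self._fold_coefs[f] @ self.design.X[lo:hi].T
            pred[..., lo:hi] = seg.reshape(n_resp, n_vox, 3, hi - lo)
        return _pearson_rows(pred, Y).mean(axis=-1)


def _fit_variants(
    pred_values: np.ndarray,
    Y_flat: np.ndarray,
    basis: LagBasis,
    config: RunConfig,
    n_resp: int,
    n_vox: int,
):
    """Fit true + shifted-null variants of one predictor set to a response batch.

    Returns (true fit, [null fits]) as ``_BatchFits``; ``Y_flat`` has shape
    (n_resp * n_vox * 3, T).
    """
    n_pred = pred_values.shape[0]
    variants = [pred_values]
    n_samp = pred_values.shape[1]
    for frac in config.shift_fractions:
        shift = int(round(frac * n_samp))
        variants.append(np.roll(pred_values, shift, axis=1))
    fits = []
    for vi, pv in enumerate(variants):
        t0 = time.time()
        design = make_design(pv, basis, config.n_folds)
        coefs, info = boost_many(
            design, Y_flat, config.delta_fraction, config.patience
        )
        bf = _BatchFits(design, coefs, n_resp, n_vox, n_pred, basis)
        bf._fold_coefs = coefs
        fits.append(bf)
        logger.debug(
            "variant %d fitted in %.1f s (median steps %d)",
            vi, time.time() - t0, int(np.median(info["n_steps"])),
        )
    return fits[0], fits[1:]


def _adjacency_for(source_space):
    if source_space.grid_shape is not None and len(source_space.grid_shape) == 3:
        return GridAdjacency(source_space.grid_shape)
    return voxel_adjacency(source_space.voxel_coords_mm, source_space.spacing_mm)


def _test_summary(res, lag_grid=None) -> dict:
    out = {
        "t_max": None if np.isnan(res.t_max) else float(res.t_max),
        "p_min": float(res.p_map.min()),
        "n_significant": int(res.sig_mask.sum()),
        "significant": bool(res.sig_mask.any()),
        "n_permutations": res.n_permutations,
    }
    if lag_grid is not None:
        out["sig_lag_ranges_ms"] = res.sig_ranges(lag_grid)
    return out


def _analyze_conditions(
    cohort: SyntheticCohort,
    config: RunConfig,
    pred_labels: tuple[str, ...],
    conditions: list[str],
    report: RunReport,
) -> dict:
    """Shared engine: batched fits, nulls, accuracies, amplitude tests, peaks.

    All ``conditions`` must be driven by the same predictor set
    (``pred_labels``); subjects × conditions are fitted in one batch per
    variant.  Returns per-condition intermediate arrays for scenario-specific
    post-processing.
    """
    config.validate()
    basis = config.basis()
    n_sub = cohort.n_subjects
    n_vox = cohort.source_space.n_voxels
    lag_grid = basis.lag_grid_ms
    adjacency_vox = _adjacency_for(cohort.source_space)

    pred_values = np.stack([cohort.predictors[k].values for k in pred_labels])
    Y = np.stack([_stack_responses(cohort, c) for c in conditions])  # (C,S,V,3,T)
    n_cond = len(conditions)
    t = Y.shape[-1]
    Y_flat = Y.reshape(n_cond * n_sub * n_vox * 3, t)

    t0 = time.time()
    true_fit, null_fits = _fit_variants(
        pred_values, Y_flat, basis, config, n_cond * n_sub, n_vox
    )
    report.timings_s["fits"] = round(time.time() - t0, 2)

    amp_true = true_fit.amplitudes().reshape(n_cond, n_sub, n_vox, len(pred_labels), -1)
    amp_null = np.mean(
        [nf.amplitudes() for nf in null_fits], axis=0
    ).reshape(amp_true.shape)
    corrected = amp_true - amp_null

    if config.compute_accuracy:
        t0 = time.time()
        Y_resh = Y.reshape(n_cond * n_sub, n_vox, 3, t)
        acc_true = true_fit.cv_accuracy(Y_resh, config.rate).reshape(
            n_cond, n_sub, n_vox
        )
        acc_null = np.mean(
            [nf.cv_accuracy(Y_resh, config.rate) for nf in null_fits], axis=0
        ).reshape(n_cond, n_sub, n_vox)
        report.timings_s["accuracy"] = round(time.time() - t0, 2)

        smooth = lambda m: smooth_accuracy(
            AccuracyMap(m), cohort.source_space, config.smoothing_sd_mm
        ).values
        acc_true_sm = np.stack([[smooth(a) for a in cond] for cond in acc_true])
        acc_null_sm = np.stack([[smooth(a) for a in cond] for cond in acc_null])

    t0 = time.time()
    rows = []
    for ci, cond in enumerate(conditions):
        if config.compute_accuracy:
            report.accuracy_summary[cond] = {
                "mean": float(acc_true[ci].mean()),
                "sd": float(acc_true[ci].std()),
                "null_mean": float(acc_null[ci].mean()),
                "null_sd": float(acc_null[ci].std()),
            }
            res = permutation_test(
                acc_true_sm[ci],
                acc_null_sm[ci],
                adjacency_vox,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=_derived_seed(config.seed, f"acc:{cond}"),
            )
            report.accuracy_tests[cond] = _test_summary(res)
        for pi, plabel in enumerate(pred_labels):
            vm_true = amp_true[ci, :, :, pi].mean(axis=1)   # (S, L)
            vm_null = amp_null[ci, :, :, pi].mean(axis=1)
            res_amp = permutation_test(
                vm_true,
                vm_null,
                GridAdjacency((lag_grid.size,)),
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=_derived_seed(config.seed, f"amp:{cond}:{plabel}"),
            )
            report.amplitude_tests[f"{cond}:{plabel}"] = _test_summary(
                res_amp, lag_grid
            )
            vm_corr = corrected[ci, :, :, pi].mean(axis=1)
            peaks, lats = extract_peaks(vm_corr, lag_grid, config.peak_window_ms)
            for s in range(n_sub):
                rows.append(
                    {
                        "subject": s,
                        "condition": cond,
                        "predictor": plabel,
                        "peak_amplitude": peaks[s],
                        "peak_latency_ms": lats[s],
                    }
                )
    report.timings_s["stats"] = round(time.time() - t0, 2)
    report.peak_table = pd.DataFrame(rows)
    return {
        "corrected": corrected,
        "amp_true": amp_true,
        "amp_null": amp_null,
        "lag_grid": lag_grid,
        "conditions": conditions,
        "pred_labels": pred_labels,
    }


def run_single_speaker(cohort: SyntheticCohort, config: RunConfig) -> RunReport:
    """Two-predictor (carrier + envelope) analysis, one run per speaker."""
    if cohort.scenario != "single_speaker":
        raise ValueError("cohort was not generated for the single-speaker scenario")
    report = RunReport(
        "single_speaker",
        dataclasses.asdict(config),
        config.config_hash,
        config.seed,
        cohort.n_subjects,
    )
    tables = []
    for speaker in ("male", "female"):
        sub_report = _analyze_conditions(
            cohort,
            config,
            (f"{speaker}_carrier", f"{speaker}_envelope"),
            [speaker],
            report,
        )
        tables.append(report.peak_table)
    report.peak_table = pd.concat(tables, ignore_index=True)
    return report


def run_cocktail_party(cohort: SyntheticCohort, config: RunConfig) -> RunReport:
    """Four-predictor analysis plus the attended-vs-ignored peak comparison.

    Male-speech kernels from the attend-male condition are the attended TRFs;
    the same predictors fitted in the attend-female condition give the ignored
    TRFs.  Corrected 20–50 ms peaks are compared attended vs. ignored with a
    two-sided Wilcoxon signed-rank test, separately for the envelope and
    carrier predictors.
    """
    if cohort.scenario != "cocktail_party":
        raise ValueError("cohort was not generated for the cocktail-party scenario")
    report = RunReport(
        "cocktail_party",
        dataclasses.asdict(config),
        config.config_hash,
        config.seed,
        cohort.n_subjects,
    )
    out = _analyze_conditions(
        cohort, config, COCKTAIL_LABELS, ["attend_male", "attend_female"], report
    )
    table = report.peak_table
    for kind, plabel in (("envelope", "male_envelope"), ("carrier", "male_carrier")):
        att = table.query("condition == 'attend_male' and predictor == @plabel")
        ign = table.query("condition == 'attend_female' and predictor == @plabel")
        att = att.sort_values("subject")["peak_amplitude"].to_numpy()
        ign = ign.sort_values("subject")["peak_amplitude"].to_numpy()
        res = compare_peaks_wilcoxon(att, ign)
        report.wilcoxon[kind] = {
            "W": None if np.isnan(res.w) else res.w,
            "p": None if np.isnan(res.p) else res.p,
            "n_used": res.n_used,
            "no_test": res.no_test,
        }
    return report
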