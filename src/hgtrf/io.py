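"""Serialized forms: WAV stimuli, array+JSON-sidecar intermediates, TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .predictors import Predictor
from .synth import SourceRecording, SourceSpace, SyntheticStimulus

__all__ = [
    "write_wav",
    "read_wav",
    "save_array",
    "load_array",
    "save_recording",
    "load_recording",
    "save_predictor",
    "load_predictor",
    "save_accuracy_tsv",
    "save_stat_result",
    "save_peak_table",
]


def write_wav(path, stimulus, rate: float | None = None) -> None:
    """16-bit PCM WAV, peak-scaled to 90% full range."""
    if isinstance(stimulus, SyntheticStimulus):
        wave, rate = stimulus.waveform, stimulus.spec.audio_rate
    else:
        wave = np.asarray(stimulus, dtype=np.float64)
        if rate is None:
            raise ValueError("raw waveforms need a rate")
    peak = np.max(np.abs(wave)) or 1.0
    pcm = np.round(wave / peak * 0.9 * 32767).astype(np.int16)
    wavfile.write(str(path), int(rate), pcm)


def read_wav(path) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return np.asarray(data, dtype=np.float64), int(rate)


def save_array(path_base, array: np.ndarray, meta: dict) -> None:
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), np.asarray(array))
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_array(path_base) -> tuple[np.ndarray, dict]:
    base = Path(path_base)
    arr = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return arr, meta


def save_recording(path_base, rec: SourceRecording) -> None:
    meta = {
        "rate": rec.rate,
        "voxel_coords_mm": rec.source_space.voxel_coords_mm.tolist(),
        "spacing_mm": rec.source_space.spacing_mm,
        "grid_shape": list(rec.source_space.grid_shape or []),
        "condition_labels": rec.condition_labels,
    }
    save_array(path_base, rec.data, meta)


def load_recording(path_base) -> SourceRecording:
    data, meta = load_array(path_base)
    space = SourceSpace(
        np.asarray(meta["voxel_coords_mm"]),
        meta["spacing_mm"],
        tuple(meta["grid_shape"]) or None,
    )
    return SourceRecording(data, meta["rate"], space, meta.get("condition_labels", {}))


def save_predictor(path_base, pred: Predictor) -> None:
    meta = {
        "rate": pred.rate,
        "kind": pred.kind,
        "source_label": pred.source_label,
        "degenerate": pred.degenerate,
        "block_lengths": list(pred.block_lengths),
    }
    save_array(path_base, pred.values, meta)


def load_predictor(path_base) -> Predictor:
    values, meta = load_array(path_base)
    return Predictor(
        values,
        meta["rate"],
        meta["kind"],
        meta.get("source_label", ""),
        meta.get("degenerate", False),
        tuple(meta.get("block_lengths", [])),
    )


def save_accuracy_tsv(path, values: np.ndarray, source_space: SourceSpace) -> None:
    coords = source_space.voxel_coords_mm
    df = pd.DataFrame(
        {
            "voxel_id": np.arange(len(values)),
            "x_mm": coords[:, 0],
            "y_mm": coords[:, 1],
            "z_mm": coords[:, 2],
            "accuracy": values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def save_stat_result(path_base, result, element_ids=None) -> None:
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    t = result.t_map.ravel()
    if element_ids is None:
        element_ids = np.arange(t.size)
    pd.DataFrame(
        {
            "element_id": element_ids,
            "t": t,
            "tfce": result.tfce_map.ravel(),
            "p": result.p_map.ravel(),
            "significant": result.sig_mask.ravel().astype(int),
        }
    ).to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    summary = {
        "t_max": None if np.isnan(result.t_max) else result.t_max,
        "n_permutations": result.n_permutations,
        "alpha": result.alpha,
        "p_min": float(np.min(result.p_map)),
        "n_significant": int(result.sig_mask.sum()),
    }
    base.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def save_peak_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
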