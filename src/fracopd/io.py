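"""Record I/O: CSV and EDF readers, channel mapping, resampling."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .record import MultichannelRecord, PRESETS

logger = logging.getLogger(__name__)

__all__ = ["read_record", "resample_record", "read_manifest"]


def _repair_nonfinite(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Linear interpolation over non-finite samples, per channel."""
    n_bad = int((~np.isfinite(data)).sum())
    if n_bad == 0:
        return data, 0
    out = data.copy()
    for i in range(out.shape[0]):
        row = out[i]
        bad = ~np.isfinite(row)
        if bad.all():
            raise ValueError(f"channel {i} has no finite samples")
        if bad.any():
            idx = np.arange(row.size)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    return out, n_bad


def _canonicalize(
    frame_channels: list[str],
    data: np.ndarray,
    preset: str,
    mapping: dict[str, str] | None,
) -> tuple[list[str], np.ndarray]:
    want = list(PRESETS[preset])
    have = {c: i for i, c in enumerate(frame_channels)}
    if mapping:
        for canonical, actual in mapping.items():
            if actual in have:
                have[canonical] = have[actual]
    rows = []
    for ch in want:
        if ch not in have:
            raise KeyError(
                f"missing channel {ch!r} for preset {preset!r}; "
                f"available: {sorted(frame_channels)}"
            )
        rows.append(have[ch])
    return want, data[rows]


def read_record(
    path: str | Path,
    preset: str = "nox12",
    mapping: dict[str, str] | None = None,
    record_id: str | None = None,
    patient_id: str = "unknown",
    institution: str = "unknown",
    stage: int | None = None,
) -> MultichannelRecord:
    """Read one recording from CSV (samples x channels) or EDF.

    Channels are reordered to the preset's canonical roster; `mapping`
    translates canonical names to file-specific labels. Non-finite
    samples are repaired by linear interpolation (logged).
    """
    path = Path(path)
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as e:  # pragma: no cover
            raise ImportError("EDF reading requires mne") from e
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = list(raw.ch_names)
        data = raw.get_data()
    else:
        frame = pd.read_csv(path)
        channels = list(frame.columns)
        data = frame.to_numpy(dtype=float).T
    channels, data = _canonicalize(channels, data, preset, mapping)
    data, n_repaired = _repair_nonfinite(data)
    if n_repaired:
        logger.info("repaired %d non-finite samples in %s", n_repaired, path.name)
    return MultichannelRecord(
        record_id=record_id or path.stem,
        patient_id=patient_id,
        institution=institution,
        stage=stage,
        channels=channels,
        data=data,
        sampling_note="nominal",
    )


def resample_record(record: MultichannelRecord, target_len: int = 6000) -> MultichannelRecord:
    """Resample every channel to exactly `target_len` samples.

    Uses polyphase filtering; idempotent when the record already has the
    target length. Constant channels stay constant.
    """
    T = record.n_samples
    if T == target_len:
        return record
    if T < target_len:
        raise ValueError(
            f"record has {T} samples < target {target_len}; pad upstream if intended"
        )
    from math import gcd

    g = gcd(target_len, T)
    up, down = target_len // g, T // g
    if max(up, down) > 1000:
        # awkward ratio: fall back to linear interpolation
        t_old = np.linspace(0.0, 1.0, T)
        t_new = np.linspace(0.0, 1.0, target_len)
        data = np.stack([np.interp(t_new, t_old, ch) for ch in record.data])
    else:
        data = sp_signal.resample_poly(record.data, up, down, axis=1, padtype="line")
        data = data[:, :target_len]
    return MultichannelRecord(
        record_id=record.record_id,
        patient_id=record.patient_id,
        institution=record.institution,
        stage=record.stage,
        channels=list(record.channels),
        data=data,
        sampling_note="resampled",
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (record_id, patient_id, institution, stage, path)."""
    manifest = pd.read_csv(path)
    required = {"record_id", "patient_id", "institution", "stage", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest
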