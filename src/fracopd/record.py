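"""Core record container and channel presets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# channel roster of a NOX-T3-style 12-channel polygraph
NOX12_CHANNELS = (
    "Thorax",
    "Abdomen",
    "SpO2",
    "SpO2 B-B",
    "Pulse",
    "Plethysmograph",
    "Nasal Pressure",
    "RIP Sum",
    "Activity",
    "Position",
    "Flow",
    "Resp Rate",
)

# 6-channel portable (Porti-style) roster
PORTI6_CHANNELS = (
    "Thorax",
    "Abdomen",
    "SpO2",
    "Pulse",
    "Plethysmograph",
    "Nasal Pressure",
)

PRESETS = {"nox12": NOX12_CHANNELS, "porti6": PORTI6_CHANNELS}


@dataclass
class MultichannelRecord:
    """One labeled multichannel physiological recording.

    `data` is channels x samples; `stage` is the COPD stage 0 (healthy)
    through 4 (very severe), or None when unknown (inference-only runs).
    """

    record_id: str
    patient_id: str
    institution: str
    stage: int | None
    channels: list[str]
    data: np.ndarray
    sampling_note: str = "nominal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels, n_samples); got {self.data.shape} "
                f"for {len(self.channels)} channels"
            )
        if self.stage is not None and not 0 <= int(self.stage) <= 4:
            raise ValueError(f"stage must be in 0..4 or None, got {self.stage}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
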