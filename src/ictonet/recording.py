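"""Container types for annotated multichannel peri-ictal recordings.

A :class:`Recording` holds an ``(n_channels, n_samples)`` signal matrix in
microvolt-like units together with its sampling rate and, optionally, the
peri-ictal annotations (pre-ictal start, seizure onset/offset, post-ictal
end) that drive segmentation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

EPOCH_LABELS = ("preictal", "ictal", "postictal")


@dataclass(frozen=True)
class EpochAnnotation:
    """Boundaries (seconds) of one peri-ictal epoch: pre-ictal, ictal, post-ictal."""

    preictal_start_s: float
    seizure_onset_s: float
    seizure_offset_s: float
    postictal_end_s: float

    def __post_init__(self) -> None:
        ts = (
            self.preictal_start_s,
            self.seizure_onset_s,
            self.seizure_offset_s,
            self.postictal_end_s,
        )
        if not all(b > a for a, b in zip(ts, ts[1:])):
            raise InvalidInputError(
                "annotation boundaries must be strictly increasing: "
                f"{ts}"
            )

    def epoch_bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "preictal": (self.preictal_start_s, self.seizure_onset_s),
            "ictal": (self.seizure_onset_s, self.seizure_offset_s),
            "postictal": (self.seizure_offset_s, self.postictal_end_s),
        }

    def to_dict(self) -> dict[str, float]:
        return {
            "preictal_start_s": self.preictal_start_s,
            "seizure_onset_s": self.seizure_onset_s,
            "seizure_offset_s": self.seizure_offset_s,
            "postictal_end_s": self.postictal_end_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpochAnnotation":
        return cls(
            preictal_start_s=float(d["preictal_start_s"]),
            seizure_onset_s=float(d["seizure_onset_s"]),
            seizure_offset_s=float(d["seizure_offset_s"]),
            postictal_end_s=float(d["postictal_end_s"]),
        )


@dataclass
class Recording:
    """Multichannel recording: ``data[channel, sample]`` at sampling rate ``fs``."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    annotations: EpochAnnotation | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise InvalidInputError("channel_labels length must match channel count")
        if self.annotations is not None:
            if not (
                0.0 <= self.annotations.preictal_start_s
                and self.annotations.postictal_end_s <= self.duration_s + 1e-9
            ):
                raise InvalidInputError(
                    "annotation boundaries must lie within the recording"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with new samples (annotations carried over)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)
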