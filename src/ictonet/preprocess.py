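"""Turn annotated recordings into the segment/subsegment ensembles used for FC.

The protocol: down-sample to 512 Hz, re-reference each sample against the
cross-channel median, band-pass 0.5-120 Hz and notch 48-52 Hz (zero-phase),
cut each peri-ictal epoch into 8 s segments separated by 1 s gaps, and split
every segment into 10 subsegments of 2 s laid out with minimal overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import InvalidInputError, InvalidParameterError, UpsamplingRefusedError
from .recording import Recording

SEGMENT_LEN_S = 8.0
SEGMENT_GAP_S = 1.0
SUBSEGMENT_LEN_S = 2.0
N_SUBSEGMENTS = 10


@dataclass
class Segment:
    """An 8 s window of a recording, labelled by the peri-ictal epoch it lies in."""

    start_s: float
    end_s: float
    epoch_label: str
    data: np.ndarray  # (n_channels, n_seg_samples)
    fs: float

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class SubsegmentEnsemble:
    """2 s subsegments of one segment: 10 originals and 10x10 = 100 surrogates."""

    original: list[np.ndarray]
    surrogate: list[np.ndarray]
    parent: Segment

    def __post_init__(self) -> None:
        if len(self.original) != N_SUBSEGMENTS:
            raise InvalidInputError(
                f"expected {N_SUBSEGMENTS} original subsegments, got {len(self.original)}"
            )


def resample_recording(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased down-sampling to ``target_fs``; annotations (in seconds) unchanged."""
    if target_fs <= 0:
        raise InvalidParameterError(f"target_fs must be positive, got {target_fs}")
    if target_fs > rec.fs:
        raise UpsamplingRefusedError(
            f"refusing to upsample from {rec.fs} Hz to {target_fs} Hz"
        )
    if target_fs == rec.fs:
        return rec.with_data(rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.with_data(out, fs=target_fs)


def rereference_median(
    rec: Recording, exclude_channels: Sequence[int] = ()
) -> Recording:
    """Subtract the per-sample median across channels from every channel.

    ``exclude_channels`` are left out of the median computation (e.g. channels
    marked as artifactual by inspection) but are still re-referenced.
    """
    if rec.n_channels < 2:
        raise InvalidInputError("median re-referencing requires >= 2 channels")
    include = np.setdiff1d(np.arange(rec.n_channels), np.asarray(exclude_channels, int))
    if include.size < 2:
        raise InvalidInputError("fewer than 2 channels left for the median reference")
    ref = np.median(rec.data[include], axis=0)
    return rec.with_data(rec.data - ref[None, :])


def bandpass_notch_filter(
    rec: Recording,
    band: tuple[float, float] = (0.5, 120.0),
    notch: tuple[float, float] = (48.0, 52.0),
) -> Recording:
    """Zero-phase Butterworth band-pass followed by band-stop (notch).

    4th-order band-pass and 2nd-order band-stop, each applied forward-backward
    (``sosfiltfilt``) so that zero-lag correlations downstream are not biased
    by filter phase.
    """
    nyq = rec.fs / 2.0
    low, high = band
    if not (0.0 < low < high < nyq):
        raise InvalidParameterError(
            f"band edges must satisfy 0 < {low} < {high} < Nyquist ({nyq})"
        )
    nlow, nhigh = notch
    if not (low <= nlow < nhigh <= high):
        raise InvalidParameterError("notch interval must lie inside the pass band")
    sos_bp = signal.butter(4, [low, high], btype="bandpass", output="sos", fs=rec.fs)
    sos_bs = signal.butter(2, [nlow, nhigh], btype="bandstop", output="sos", fs=rec.fs)
    out = signal.sosfiltfilt(sos_bp, rec.data, axis=1)
    out = signal.sosfiltfilt(sos_bs, out, axis=1)
    return rec.with_data(out)


def segment_peri_ictal(rec: Recording) -> list[Segment]:
    """Cut each epoch independently into 8 s segments with 1 s gaps.

    Windows start every ``SEGMENT_LEN_S + SEGMENT_GAP_S`` = 9 s from the epoch
    start; a window that would cross the epoch boundary is dropped, so every
    segment carries a single epoch label.
    """
    if rec.annotations is None:
        raise InvalidInputError("recording has no peri-ictal annotations")
    stride = SEGMENT_LEN_S + SEGMENT_GAP_S
    n_seg_samples = int(round(SEGMENT_LEN_S * rec.fs))
    segments: list[Segment] = []
    for label, (t0, t1) in rec.annotations.epoch_bounds().items():
        if t1 - t0 < SEGMENT_LEN_S:
            warnings.warn(
                f"epoch '{label}' ({t1 - t0:.1f} s) shorter than one segment; skipped",
                stacklevel=2,
            )
            continue
        start = t0
        while start + SEGMENT_LEN_S <= t1 + 1e-9:
            i0 = int(round(start * rec.fs))
            seg = Segment(
                start_s=start,
                end_s=start + SEGMENT_LEN_S,
                epoch_label=label,
                data=rec.data[:, i0 : i0 + n_seg_samples].copy(),
                fs=rec.fs,
            )
            if seg.data.shape[1] == n_seg_samples:
                segments.append(seg)
            start += stride
    return segments


def subsegment_starts(fs: float) -> np.ndarray:
    """Sample indices of the 10 subsegment starts, evenly spaced over [0, 6] s."""
    spacing = (SEGMENT_LEN_S - SUBSEGMENT_LEN_S) / (N_SUBSEGMENTS - 1)
    return np.array(
        [int(round(i * spacing * fs)) for i in range(N_SUBSEGMENTS)], dtype=int
    )


def make_subsegments(
    seg: Segment, surrogates: list[np.ndarray]
) -> SubsegmentEnsemble:
    """Cut a segment (and its surrogate realizations) into the 2 s subsegment grid.

    The same 10 start positions are applied to the original data and to every
    surrogate matrix, giving 10 original and ``10 x len(surrogates)``
    surrogate subsegments (100 with the standard 10 surrogates).
    """
    n_sub = int(round(SUBSEGMENT_LEN_S * seg.fs))
    for sur in surrogates:
        if sur.shape != seg.data.shape:
            raise InvalidInputError(
                f"surrogate shape {sur.shape} != segment shape {seg.data.shape}"
            )
    starts = subsegment_starts(seg.fs)
    original = [seg.data[:, s : s + n_sub].copy() for s in starts]
    surrogate = [sur[:, s : s + n_sub].copy() for sur in surrogates for s in starts]
    return SubsegmentEnsemble(original=original, surrogate=surrogate, parent=seg)


def preprocess_recording(
    rec: Recording,
    target_fs: float = 512.0,
    band: tuple[float, float] = (0.5, 120.0),
    notch: tuple[float, float] = (48.0, 52.0),
    exclude_channels: Sequence[int] = (),
) -> Recording:
    """Standard chain: down-sample, median re-reference, band-pass + notch."""
    rec = resample_recording(rec, min(target_fs, rec.fs))
    rec = rereference_median(rec, exclude_channels)
    return bandpass_notch_filter(rec, band, notch)
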