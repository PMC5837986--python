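"""Readers and writers: plain-matrix recordings, EDF, FC matrices, reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fc import FCNetwork
from .recording import EpochAnnotation, Recording


def write_matrix_recording(path, rec: Recording) -> None:
    """Plain-text fixture format: one header line of channel labels, then
    tab-separated samples (one row per time point)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6g", delimiter="\t")


def read_matrix_recording(path, fs: float, annotations: EpochAnnotation | None = None) -> Recording:
    path = Path(path)
    with path.open() as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != len(labels):
        raise InvalidInputError("column count does not match the header labels")
    return Recording(data=data.T, fs=fs, channel_labels=labels, annotations=annotations)


def read_edf_recording(path, annotations: EpochAnnotation | None = None) -> Recording:
    """Read a European Data Format recording (requires the ``edf`` extra)."""
    import mne  # noqa: deferred heavy import

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=annotations,
    )


def write_annotations(path, ann: EpochAnnotation) -> None:
    Path(path).write_text(json.dumps(ann.to_dict(), indent=2))


def read_annotations(path) -> EpochAnnotation:
    return EpochAnnotation.from_dict(json.loads(Path(path).read_text()))


def write_fc(path, fc: FCNetwork, sidecar: dict | None = None) -> None:
    """FC matrix as an N x N TSV with a JSON sidecar of inference metadata."""
    path = Path(path)
    np.savetxt(path, fc.weights, fmt="%.8g", delimiter="\t")
    meta = {"measure": fc.measure, **fc.meta, **(sidecar or {})}
    if fc.segment is not None:
        meta["segment_window_s"] = [fc.segment.start_s, fc.segment.end_s]
        meta["epoch_label"] = fc.segment.epoch_label
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=_jsonify))


def read_fc(path) -> tuple[np.ndarray, dict]:
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return w, meta


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "engel_class": r.engel_class,
            "elevated_epoch1": r.elevated_flags[0],
            "elevated_epoch2": r.elevated_flags[1],
            "elevated_ictal": r.elevated_ictal,
            "outcome_good": r.outcome_good,
            "delta_bni": r.delta_bni,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify))
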