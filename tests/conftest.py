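"""Shared fixtures: small synthetic recordings and a cached tiny pipeline run."""

import numpy as np
import pytest

from ictonet import EpochAnnotation, Recording, Segment, SyntheticSpec, generate_cohort
from ictonet.pipeline import RunConfig, run_subject


def make_white_recording(
    n_channels: int = 4,
    fs: float = 512.0,
    pre_s: float = 20.0,
    ictal_s: float = 10.0,
    post_s: float = 20.0,
    seed: int = 0,
) -> Recording:
    """Independent white-noise channels with valid peri-ictal annotations."""
    rng = np.random.default_rng(seed)
    total = pre_s + ictal_s + post_s
    data = rng.standard_normal((n_channels, int(round(total * fs))))
    ann = EpochAnnotation(
        preictal_start_s=0.0,
        seizure_onset_s=pre_s,
        seizure_offset_s=pre_s + ictal_s,
        postictal_end_s=total,
    )
    return Recording(data=data, fs=fs, annotations=ann)


def make_segment(data: np.ndarray, fs: float = 512.0, label: str = "ictal") -> Segment:
    """Wrap an (n_channels, 8 s * fs) array as a Segment."""
    return Segment(start_s=0.0, end_s=data.shape[1] / fs, epoch_label=label,
                   data=np.asarray(data, float), fs=fs)


#: problem sizes for desk-scale end-to-end runs (small cohorts, short epochs)
TINY_SPEC = dict(n_subjects=2, n_channels=8, n_core=3, pre_s=27.0, post_s=27.0,
                 ictal_range_s=(27.0, 32.0), seed=5)
TINY_CONFIG = dict(profile="test", seed=3, n_k=7)


@pytest.fixture(scope="session")
def tiny_subject_run():
    """One responder subject analysed end to end (shared across test modules)."""
    cohort = generate_cohort(SyntheticSpec(**TINY_SPEC))
    subject = cohort[0]
    assert subject.ground_truth.responder
    config = RunConfig(**TINY_CONFIG)
    result = run_subject(
        config,
        subject.recordings,
        subject.ground_truth.resection_mask,
        subject_id=subject.ground_truth.subject_id,
        engel_class=subject.ground_truth.engel_class,
    )
    return config, subject, result
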