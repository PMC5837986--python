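"""End-to-end orchestration: preprocess -> FC -> BNI -> cohort statistics.

``run_subject`` takes a subject's two annotated peri-ictal recordings and a
resection mask and produces the normalized BNI timecourses, the per-epoch
elevated-ictal flags and the virtual-resection DeltaBNI. ``run_cohort``
aggregates subjects into the group epoch comparison, the elevated-vs-outcome
permutation test and the DeltaBNI ROC analyses. All randomness derives from
the master seed in the config, so reruns are reproducible.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import cohort_stats as cs
from .errors import CalibrationError, IctonetError, InvalidParameterError, StageError
from .fc import infer_fc
from .ictogenicity import (
    BNITimecourse,
    ThetaParams,
    bni_curve,
    bni_integral,
    calibrate_reference_coupling,
    default_k_grid,
    delta_bni,
    normalize_timecourse,
    select_k_interval,
)
from .preprocess import preprocess_recording, segment_peri_ictal
from .recording import Recording
from .synthetic import SubjectData

logger = logging.getLogger("ictonet")

#: simulation steps per profile: the full protocol vs a desk-scale run
PROFILE_STEPS = {"full": 4_000_000, "test": 200_000}
PROFILE_NK = {"full": 21, "test": 11}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    profile: str = "test"
    measure: str = "pearson"
    alpha: float = 0.05
    seed: int = 0
    n_surrogates: int = 10
    target_fs: float = 512.0
    band: tuple[float, float] = (0.5, 120.0)
    notch: tuple[float, float] = (48.0, 52.0)
    i0: float = -1.2
    noise_sd: float = 0.6
    dt: float = 0.01
    n_steps: int | None = None
    n_k: int | None = None
    k_max: float = 512.0
    n_realizations_curve: int = 1
    n_realizations_calib: int = 3
    h2_bins: int = 10
    bni_pre_target: float = 0.5
    bni_pre_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.profile not in PROFILE_STEPS:
            raise InvalidParameterError(f"unknown profile {self.profile!r}")
        if self.n_steps is None:
            self.n_steps = PROFILE_STEPS[self.profile]
        if self.n_k is None:
            self.n_k = PROFILE_NK[self.profile]

    def theta_params(self, seed: int = 0) -> ThetaParams:
        return ThetaParams(
            i0=self.i0, noise_sd=self.noise_sd, dt=self.dt,
            n_steps=self.n_steps, seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("band", "notch"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SubjectResult:
    record: cs.CohortRecord
    timecourses: list[BNITimecourse]
    k_interval: tuple[float, float]
    epoch_pvalues: list[float]
    k_ref: float | None = None
    calibration_achieved: float | None = None
    details: dict = field(default_factory=dict)


def _subject_seed(config: RunConfig, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, zlib.crc32(subject_id.encode())])


def run_subject(
    config: RunConfig,
    recordings: Sequence[Recording],
    resection_mask: Sequence[int],
    subject_id: str = "sub00",
    engel_class: str = "I",
) -> SubjectResult:
    """Analyse one subject's two peri-ictal epochs end to end."""
    if len(recordings) != 2:
        raise StageError("input", "expected exactly two peri-ictal recordings")
    ss = _subject_seed(config, subject_id)
    seed_fc, seed_bni, seed_resect = ss.spawn(3)
    k_grid = default_k_grid(config.k_max, config.n_k)

    epochs: list[dict] = []
    all_curves = []
    for e, rec in enumerate(recordings):
        try:
            pre = preprocess_recording(
                rec, target_fs=config.target_fs, band=config.band, notch=config.notch
            )
            segments = segment_peri_ictal(pre)
        except IctonetError as err:
            raise StageError("preprocess", str(err)) from err
        if not segments:
            raise StageError("preprocess", f"epoch {e}: no segments produced")
        fcs = []
        fc_seeds = seed_fc.spawn(len(recordings))[e].spawn(len(segments))
        for seg, child in zip(segments, fc_seeds):
            try:
                fcs.append(
                    infer_fc(
                        seg,
                        n_surrogates=config.n_surrogates,
                        measure=config.measure,
                        alpha=config.alpha,
                        seed=child,
                        n_bins=config.h2_bins,
                    )
                )
            except IctonetError as err:
                raise StageError("fc_inference", str(err)) from err
        curves = []
        curve_seeds = seed_bni.spawn(len(recordings))[e].spawn(len(segments))
        for fc_net, child in zip(fcs, curve_seeds):
            try:
                curves.append(
                    bni_curve(
                        fc_net.weights,
                        config.theta_params(),
                        k_grid,
                        seed=child.generate_state(1)[0] % (2**31),
                        n_realizations=config.n_realizations_curve,
                    )
                )
            except IctonetError as err:
                raise StageError("ictogenicity", str(err)) from err
        epochs.append({"segments": segments, "fcs": fcs, "curves": curves})
        all_curves.extend(curves)

    try:
        k1, k2 = select_k_interval(all_curves)
    except IctonetError as err:
        raise StageError("ictogenicity", str(err)) from err

    timecourses, flags, pvals = [], [], []
    for e, ep in enumerate(epochs):
        values = [bni_integral(c, k1, k2) for c in ep["curves"]]
        tc = BNITimecourse(
            times=np.array([s.midpoint_s for s in ep["segments"]]),
            values=np.array(values),
            labels=[s.epoch_label for s in ep["segments"]],
        )
        try:
            tc = normalize_timecourse(tc)
        except IctonetError as err:
            raise StageError("ictogenicity", str(err)) from err
        timecourses.append(tc)
        flag, p = cs.elevated_ictal_test(
            tc.epoch_values("preictal"), tc.epoch_values("ictal"), config.alpha
        )
        flags.append(flag)
        pvals.append(p)

    # DeltaBNI on the FC averaged over first-half ictal segments of both epochs
    first_half = []
    for ep in epochs:
        ictal = [
            (s, f)
            for s, f in zip(ep["segments"], ep["fcs"])
            if s.epoch_label == "ictal"
        ]
        if not ictal:
            continue
        onset = min(s.start_s for s, _ in ictal)
        offset = max(s.end_s for s, _ in ictal)
        mid = onset + (offset - onset) / 2.0
        chosen = [f for s, f in ictal if s.midpoint_s <= mid] or [ictal[0][1]]
        first_half.extend(f.weights for f in chosen)
    k_ref = achieved = delta = None
    if first_half:
        mean_fc = np.mean(first_half, axis=0)
        params = config.theta_params()
        try:
            calib = calibrate_reference_coupling(
                mean_fc,
                params,
                target=config.bni_pre_target,
                tol=config.bni_pre_tol,
                k_max=config.k_max,
                n_realizations=config.n_realizations_calib,
                seed=seed_resect.generate_state(1)[0] % (2**31),
            )
            k_ref, achieved = calib.k_ref, calib.achieved
            res = delta_bni(
                mean_fc,
                resection_mask,
                params,
                k_ref,
                seed=seed_resect.generate_state(2)[1] % (2**31),
                n_realizations=config.n_realizations_calib,
            )
            delta = res.delta_bni
        except CalibrationError as err:
            warnings.warn(
                f"{subject_id}: DeltaBNI skipped ({err})", stacklevel=2
            )

    record = cs.CohortRecord(
        subject_id=subject_id,
        engel_class=engel_class,
        elevated_flags=(bool(flags[0]), bool(flags[1])),
        delta_bni=delta,
    )
    return SubjectResult(
        record=record,
        timecourses=timecourses,
        k_interval=(k1, k2),
        epoch_pvalues=pvals,
        k_ref=k_ref,
        calibration_achieved=achieved,
    )


def run_cohort(
    config: RunConfig, subjects: Sequence[SubjectData], n_perm: int = 10_000
) -> dict:
    """Run every subject and assemble the cohort statistics report."""
    results: list[SubjectResult] = []
    for sub in subjects:
        gt = sub.ground_truth
        logger.info("running subject %s", gt.subject_id)
        results.append(
            run_subject(
                config,
                sub.recordings,
                gt.resection_mask,
                subject_id=gt.subject_id,
                engel_class=gt.engel_class,
            )
        )
    return summarize_cohort(config, results, n_perm=n_perm)


def summarize_cohort(
    config: RunConfig, results: Sequence[SubjectResult], n_perm: int = 10_000
) -> dict:
    records = [r.record for r in results]
    report: dict = {
        "config": {"profile": config.profile, "measure": config.measure,
                   "alpha": config.alpha, "seed": config.seed},
        "subjects": [
            {
                "subject_id": r.record.subject_id,
                "engel_class": r.record.engel_class,
                "elevated_flags": list(r.record.elevated_flags),
                "elevated_ictal": r.record.elevated_ictal,
                "epoch_pvalues": r.epoch_pvalues,
                "delta_bni": r.record.delta_bni,
                "k_interval": list(r.k_interval),
                "k_ref": r.k_ref,
                "bni_pre_achieved": r.calibration_achieved,
            }
            for r in results
        ],
    }

    pooled = {"preictal": [], "ictal": [], "postictal": []}
    for r in results:
        for tc in r.timecourses:
            for label in pooled:
                pooled[label].extend(tc.epoch_values(label).tolist())
    try:
        h, p = cs.kruskal_wallis_epochs(
            pooled["preictal"], pooled["ictal"], pooled["postictal"]
        )
        report["group_epochs"] = {"kruskal_h": h, "p": p}
    except IctonetError as err:
        warnings.warn(f"group epoch comparison skipped: {err}", stacklevel=2)
        report["group_epochs"] = None
    report["group_timecourse"] = _aligned_timecourse(results)

    try:
        chi2, p, table = cs.permutation_chi_square(
            records, n_perm=n_perm, seed=config.seed
        )
        report["elevated_vs_outcome"] = {
            "chi_square": chi2, "p": p, "table": table.tolist(),
        }
    except IctonetError as err:
        warnings.warn(f"contingency statistics skipped: {err}", stacklevel=2)
        report["elevated_vs_outcome"] = None

    report["outcome_prediction"] = _auc_block(records)
    return report


def _auc_block(records: list[cs.CohortRecord]) -> dict:
    block: dict = {}
    groups = {
        "elevated": [r for r in records if r.elevated_ictal and r.delta_bni is not None],
        "inconsistent": [
            r for r in records if not r.elevated_ictal and r.delta_bni is not None
        ],
    }
    dists = {}
    for name, grp in groups.items():
        scores = np.array([r.delta_bni for r in grp])
        labels = np.array([r.outcome_good for r in grp])
        if len(grp) < 2 or labels.all() or not labels.any():
            warnings.warn(f"AUC skipped for group '{name}' (need both outcomes)",
                          stacklevel=2)
            block[name] = None
            continue
        entry = {"n": len(grp), "auc": cs.roc_auc(scores, labels)}
        try:
            dists[name] = cs.half_split_aucs(scores, labels)
            entry["n_half_splits"] = int(dists[name].size)
        except IctonetError:
            pass
        block[name] = entry
    if len(dists) == 2:
        da, db = dists["elevated"], dists["inconsistent"]
        from .fc import mannwhitney_u

        _, p = mannwhitney_u(da, db, alternative="two-sided")
        block["half_split_comparison_p"] = float(p)
    return block


def _aligned_timecourse(results: Sequence[SubjectResult]) -> dict | None:
    """Cohort mean +/- s.e. of normalized BNI at aligned peri-ictal positions."""
    pre_n = min(
        tc.epoch_values("preictal").size for r in results for tc in r.timecourses
    )
    post_n = min(
        tc.epoch_values("postictal").size for r in results for tc in r.timecourses
    )
    if pre_n == 0 or post_n == 0:
        return None
    rows = []
    for r in results:
        for tc in r.timecourses:
            pre = tc.epoch_values("preictal")[-pre_n:]  # aligned to seizure onset
            ict = tc.epoch_values("ictal")
            post = tc.epoch_values("postictal")[:post_n]
            rows.append(np.concatenate([pre, ict, post]))
    arr = np.vstack(rows)
    return {
        "labels": ["preictal"] * pre_n + ["ictal"] * 10 + ["postictal"] * post_n,
        "mean": arr.mean(axis=0).tolist(),
        "sem": (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])).tolist(),
        "n_traces": int(arr.shape[0]),
    }
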