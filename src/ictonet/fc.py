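"""Surrogate-corrected functional connectivity from subsegment ensembles.

For each 8 s segment, pairwise associations (zero-lag Pearson magnitude or
the nonlinear h^2 index) are computed on 10 original 2 s subsegments and on
100 subsegments cut from 10 channel-wise IAAFT surrogates. A one-sided
Mann-Whitney U test per channel pair (original associations stochastically
larger than surrogate associations), Holm-corrected across all pairs, gives
the significance mask s. The surrogate-corrected weights are then

    C_ij = max(0, (rho0_ij - rhosurr_ij) / (1 - rhosurr_ij)) * s_ij   (Pearson)
    H_ij = h2_ij * s_ij                                               (h^2)

where rho0 / rhosurr are the per-pair medians of the original / surrogate
association ensembles. IAAFT surrogates preserve each channel's amplitude
distribution exactly and its power spectrum approximately while destroying
cross-channel coupling, so they provide the null for the U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateSignalError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .preprocess import Segment, SubsegmentEnsemble, make_subsegments

Measure = Literal["pearson", "h2"]

# exact U distribution is cheap up to this combined sample size; above it the
# normal approximation with tie correction is standard
_EXACT_U_MAX = 25


# ---------------------------------------------------------------------------
# IAAFT surrogates
# ---------------------------------------------------------------------------

def iaaft_surrogates(
    x: np.ndarray,
    n_surrogates: int,
    seed: int | np.random.Generator,
    max_iter: int = 100,
) -> list[np.ndarray]:
    """Iterated amplitude-adjusted Fourier-transform surrogates of a 1-D signal.

    Each iteration enforces the original amplitude spectrum (Fourier step)
    and then the original value multiset (rank-ordering step). A surrogate
    stops iterating when its rank ordering no longer changes, when its
    spectrum discrepancy stops improving (broadband signals plateau without
    ever freezing their ordering), or after ``max_iter`` rounds. The rank
    step runs last, so every surrogate's sorted values equal the original's
    bit-exactly.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 64:
        raise InvalidInputError(f"need >= 64 samples for IAAFT, got {x.size}")
    if n_surrogates < 1:
        raise InvalidParameterError("n_surrogates must be >= 1")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("cannot build surrogates of a constant signal")
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    n = x.size
    # all surrogates iterate together (rows of y); rows freeze once converged
    y = np.stack([rng.permutation(x) for _ in range(n_surrogates)])
    prev_order = None
    prev_err = None
    active = np.ones(n_surrogates, dtype=bool)
    cols = np.arange(n)
    amp_norm = np.linalg.norm(target_amp)
    for _ in range(max_iter):
        spec = np.fft.rfft(y[active], axis=1)
        # enforce target amplitudes, keep phases
        mag = np.abs(spec)
        err = np.linalg.norm(mag - target_amp, axis=1) / amp_norm
        np.maximum(mag, 1e-300, out=mag)
        z = np.fft.irfft(spec / mag * target_amp, n=n, axis=1)
        order = np.argsort(z, axis=1)
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.broadcast_to(cols, order.shape), axis=1)
        y[active] = sorted_x[ranks]
        done = np.zeros(err.shape, dtype=bool)
        if prev_order is not None and prev_order.shape == order.shape:
            done |= np.all(order == prev_order, axis=1)
        if prev_err is not None and prev_err.shape == err.shape:
            done |= prev_err - err < 1e-2 * err  # spectrum discrepancy stalled
        if done.any():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            if not active.any():
                break
            prev_order = order[~done]
            prev_err = err[~done]
        else:
            prev_order = order
            prev_err = err
    return [y[k] for k in range(n_surrogates)]


def channelwise_surrogates(
    data: np.ndarray, n_surrogates: int, seed: int | np.random.SeedSequence
) -> list[np.ndarray]:
    """``n_surrogates`` multichannel surrogate matrices, each channel randomized
    independently (univariate IAAFT), which destroys all cross-channel coupling."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(data.shape[0])
    per_channel = [
        iaaft_surrogates(data[c], n_surrogates, np.random.default_rng(children[c]))
        for c in range(data.shape[0])
    ]
    return [
        np.vstack([per_channel[c][k] for c in range(data.shape[0])])
        for k in range(n_surrogates)
    ]


# ---------------------------------------------------------------------------
# association measures
# ---------------------------------------------------------------------------

def pearson_zero_lag(x: np.ndarray, y: np.ndarray) -> float:
    """Magnitude of the sample Pearson coefficient at lag zero, in [0, 1]."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 2:
        raise InvalidInputError("inputs must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return min(abs(r), 1.0)


def _h2_directed(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Variance of y explained by a piecewise-linear curve in x (h^2, one way)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    edges = np.array_split(np.arange(x.size), n_bins)
    bx = np.array([xs[idx].mean() for idx in edges])
    by = np.array([ys[idx].mean() for idx in edges])
    fx = np.interp(x, bx, by)
    sse0 = float(np.sum((y - y.mean()) ** 2))
    if sse0 == 0.0:
        return 0.0
    ssef = float(np.sum((y - fx) ** 2))
    return float(np.clip(1.0 - ssef / sse0, 0.0, 1.0))


def h2_association(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Nonlinear h^2 index, symmetrized as max over both regression directions.

    h^2 = 1 - SSE_f / SSE_0 where f is the piecewise-linear curve through the
    per-bin means of the response over ``n_bins`` equal-count bins of the
    predictor. Captures monotone and non-monotone (e.g. quadratic)
    dependencies that zero-lag Pearson misses.
    """
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 10 * n_bins:
        raise InvalidInputError(f"need equal lengths >= {10 * n_bins}")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("h2 undefined for constant predictor")
    fwd = _h2_directed(x, y, n_bins)
    rev = _h2_directed(y, x, n_bins) if np.ptp(y) > 0 else 0.0
    return max(fwd, rev)


# ---------------------------------------------------------------------------
# ensembles, significance, corrected matrices
# ---------------------------------------------------------------------------

@dataclass
class AssociationSample:
    """Original vs surrogate association ensembles for one channel pair."""

    pair: tuple[int, int]
    rho0_values: np.ndarray  # 10 values from original subsegments
    rhosurr_values: np.ndarray  # 100 values from surrogate subsegments
    measure: Measure = "pearson"


@dataclass
class FCNetwork:
    """Symmetric surrogate-corrected association matrix for one segment."""

    weights: np.ndarray
    measure: Measure
    significance_mask: np.ndarray
    segment: Segment | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise InvalidInputError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidInputError("weights must have zero diagonal")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise InvalidInputError("weights must lie in [0, 1]")
        if np.any((w > 0) & (self.significance_mask == 0)):
            raise InvalidInputError("positive weight on a non-significant pair")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _abs_corr_matrix(sub: np.ndarray) -> np.ndarray:
    """|Pearson| matrix across channels of one subsegment; NaN on constant rows."""
    sd = sub.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub)
    r = np.abs(r)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


def build_association_samples(
    ens: SubsegmentEnsemble, measure: Measure = "pearson", n_bins: int = 10
) -> list[AssociationSample]:
    """Per-pair association ensembles from the original and surrogate subsegments."""
    n_ch = ens.parent.n_channels
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    if measure == "pearson":
        orig = np.stack([_abs_corr_matrix(s) for s in ens.original])
        surr = np.stack([_abs_corr_matrix(s) for s in ens.surrogate])
        return [
            AssociationSample(p, orig[:, p[0], p[1]], surr[:, p[0], p[1]], measure)
            for p in pairs
        ]
    if measure != "h2":
        raise InvalidParameterError(f"unknown measure {measure!r}")

    def h2_safe(x: np.ndarray, y: np.ndarray) -> float:
        try:
            return h2_association(x, y, n_bins)
        except DegenerateSignalError:
            return np.nan

    samples = []
    for i, j in pairs:
        r0 = np.array([h2_safe(s[i], s[j]) for s in ens.original])
        rs = np.array([h2_safe(s[i], s[j]) for s in ens.surrogate])
        samples.append(AssociationSample((i, j), r0, rs, measure))
    return samples


def surrogate_significance(
    samples: list[AssociationSample], alpha: float = 0.05, n_channels: int | None = None
) -> np.ndarray:
    """Holm-corrected one-sided U tests: which pairs exceed their surrogate null.

    Per pair the alternative is that original associations are stochastically
    larger than surrogate associations (only an excess of association over
    the coupling-destroying null is evidence of a functional connection).
    Returns the binary mask s as an ``N x N`` symmetric matrix.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if n_channels is None:
        n_channels = max(max(s.pair) for s in samples) + 1
    expected = n_channels * (n_channels - 1) // 2
    if len(samples) != expected or len({s.pair for s in samples}) != expected:
        raise InvalidInputError(
            f"need one sample per unordered pair ({expected}), got {len(samples)}"
        )
    pvals = np.ones(len(samples))
    testable = np.zeros(len(samples), bool)
    for k, s in enumerate(samples):
        r0 = np.asarray(s.rho0_values, float)
        rs = np.asarray(s.rhosurr_values, float)
        r0, rs = r0[np.isfinite(r0)], rs[np.isfinite(rs)]
        if r0.size < 3 or rs.size < 3:
            continue  # degenerate pair: excluded from testing, stays non-significant
        pvals[k] = mannwhitney_u(r0, rs, alternative="greater")[1]
        testable[k] = True
    reject = np.zeros(len(samples), bool)
    if testable.any():
        reject[testable] = multipletests(pvals[testable], alpha=alpha, method="holm")[0]
    s_mat = np.zeros((n_channels, n_channels), dtype=int)
    for k, samp in enumerate(samples):
        if reject[k]:
            i, j = samp.pair
            s_mat[i, j] = s_mat[j, i] = 1
    return s_mat


def mannwhitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U of x vs y: exact for small samples, otherwise normal
    approximation with mid-ranks and tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    method = "exact" if (x.size + y.size) <= _EXACT_U_MAX and not _has_ties(x, y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    allv = np.concatenate([x, y])
    return np.unique(allv).size < allv.size


def corrected_fc(
    samples: list[AssociationSample],
    s_mask: np.ndarray,
    measure: Measure = "pearson",
    segment: Segment | None = None,
    meta: dict | None = None,
) -> FCNetwork:
    """Surrogate-corrected FC matrix from per-pair ensembles and the mask s.

    Per-pair scalars rho0 and rhosurr are the medians of the 10 original and
    100 surrogate association values (robust summaries matching the
    rank-based test). Negative corrected values are clipped to zero: the
    weights feed a model where coupling is nonnegative.
    """
    n = s_mask.shape[0]
    w = np.zeros((n, n))
    for samp in samples:
        i, j = samp.pair
        if not s_mask[i, j]:
            continue
        r0 = np.nanmedian(samp.rho0_values)
        rs = np.nanmedian(samp.rhosurr_values)
        if not np.isfinite(r0) or not np.isfinite(rs):
            continue
        if measure == "pearson":
            if rs >= 1.0:
                continue  # division-degenerate pair: weight left at 0
            val = (r0 - rs) / (1.0 - rs)
        else:
            val = r0
        w[i, j] = w[j, i] = float(np.clip(val, 0.0, 1.0))
    return FCNetwork(
        weights=w,
        measure=measure,
        significance_mask=np.asarray(s_mask, int),
        segment=segment,
        meta=meta or {},
    )


def infer_fc(
    seg: Segment,
    n_surrogates: int = 10,
    measure: Measure = "pearson",
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    n_bins: int = 10,
) -> FCNetwork:
    """Full FC inference for one segment: surrogates, ensembles, test, correction."""
    surr = channelwise_surrogates(seg.data, n_surrogates, seed)
    ens = make_subsegments(seg, surr)
    samples = build_association_samples(ens, measure, n_bins)
    s_mask = surrogate_significance(samples, alpha, seg.n_channels)
    meta = {"alpha": alpha, "n_surrogates": n_surrogates, "measure": measure}
    return corrected_fc(samples, s_mask, measure, segment=seg, meta=meta)
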