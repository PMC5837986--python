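"""Brain network ictogenicity (BNI) from theta-neuron dynamics on FC networks.

Each network node is a theta neuron,

    dtheta_j/dt = (1 - cos theta_j) + (1 + cos theta_j) * I_j(t),
    I_j(t) = I0_j + xi_j(t) + (K / N) * sum_{i != j} a_ij (1 - cos(theta_i - theta_i^s)),

with Gaussian noise xi_j, global coupling K, FC weights a_ij and the stable
fixed point theta_i^s = -arccos((1 + I0)/(1 - I0)) of the uncoupled
noise-free node. For I0 < 0 the node is excitable (stable rest state); at
I0 = 0 a SNIC bifurcation occurs, and for I0 > 0 the node spikes
periodically with period pi / sqrt(I0). Noise drives escapes over the
saddle; coupling recruits neighbours, so strongly connected networks spend
more time spiking.

BNI*(K) is the average fraction of (post-burn-in) time the nodes spend in
the seizure state, where a node is in the seizure state at time t iff it
spiked within the trailing window w. To remove the arbitrary choice of one
K, BNI is the integral of BNI*(K) over a fixed interval [K1, K2] chosen so
that BNI* sweeps its full range. Virtual resection removes node rows and
columns and reports the relative drop DeltaBNI = (BNI_pre - BNI_post)/BNI_pre
from a reference coupling calibrated so that BNI_pre = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import (
    CalibrationError,
    DegenerateTimecourseError,
    GridExhaustedError,
    InvalidInputError,
    InvalidParameterError,
    InvalidResectionError,
    NoFixedPointError,
)

#: default seizure-state window: three spiking periods at I0 = 0.5
DEFAULT_WINDOW = 3.0 * math.pi / math.sqrt(0.5)


@dataclass(frozen=True)
class ThetaParams:
    """Parameters of the stochastic theta-network simulation.

    ``i0`` is the per-node excitability (scalar = homogeneous): negative
    values give an excitable node with a stable rest state, nonnegative
    values intrinsic spiking. ``noise_sd`` is the standard deviation
    of the Gaussian input noise, entering with Euler-Maruyama sqrt(dt)
    scaling. ``n_steps`` defaults to the full protocol length; analysis
    profiles shorten it for desk-scale runs.
    """

    i0: float | np.ndarray = -1.2
    noise_sd: float = 0.6
    dt: float = 0.01
    n_steps: int = 4_000_000
    seed: int = 0
    burn_frac: float = 0.1
    window: float = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(np.asarray(self.i0, float))):
            raise InvalidParameterError("i0 must be finite")
        if self.dt <= 0 or self.n_steps < 1 or self.noise_sd < 0:
            raise InvalidParameterError("dt > 0, n_steps >= 1, noise_sd >= 0 required")
        if not 0 <= self.burn_frac < 1:
            raise InvalidParameterError("burn_frac must lie in [0, 1)")

    def i0_vector(self, n: int) -> np.ndarray:
        v = np.asarray(self.i0, float)
        return np.full(n, float(v)) if v.ndim == 0 else v.astype(float)


def theta_steady_state(i0: float | np.ndarray) -> float | np.ndarray:
    """Stable rest phase of the uncoupled noise-free theta node.

    Solves (1 - cos t) + (1 + cos t) I0 = 0 on the stable branch:
    theta_s = -arccos((1 + I0)/(1 - I0)). Only defined for I0 < 0; at I0 >= 0
    the fixed point has vanished in the SNIC bifurcation.
    """
    arr = np.asarray(i0, float)
    if np.any(arr >= 0):
        raise NoFixedPointError("no fixed point for i0 >= 0 (beyond the SNIC)")
    out = -np.arccos((1.0 + arr) / (1.0 - arr))
    return float(out) if np.ndim(i0) == 0 else out


# linear-interpolated trig tables on (-pi, pi]; interpolation error ~3e-8,
# negligible against the Euler-Maruyama discretization error
_TRIG_M = 8192
_TRIG_GRID = np.linspace(-np.pi, np.pi, _TRIG_M + 1)
_COS_TAB = np.cos(_TRIG_GRID)
_SIN_TAB = np.sin(_TRIG_GRID)


@njit(cache=True, fastmath=True)
def _theta_kernel(indptr, indices, wdata, i0, theta0, theta_s, n_nodes, k_over_n,
                  noise_sd, dt, n_steps, seed, cap,
                  cos_tab, sin_tab):  # pragma: no cover - numba
    np.random.seed(seed)
    theta = theta0.copy()
    cos_s = np.cos(theta_s)
    sin_s = np.sin(theta_s)
    x = np.empty(n_nodes)
    cos_buf = np.empty(n_nodes)
    spike_t = np.empty(cap, np.int64)
    spike_n = np.empty(cap, np.int64)
    m = 0
    sqdt = np.sqrt(dt)
    two_pi = 2.0 * np.pi
    n_tab = cos_tab.size - 1
    scale = n_tab / two_pi
    for t in range(n_steps):
        for i in range(n_nodes):
            u = (theta[i] + np.pi) * scale
            k = int(u)
            if k >= n_tab:
                k = n_tab - 1
            f = u - k
            ci = cos_tab[k] * (1.0 - f) + cos_tab[k + 1] * f
            si = sin_tab[k] * (1.0 - f) + sin_tab[k + 1] * f
            cos_buf[i] = ci
            # 1 - cos(theta_i - theta_s_i) via the angle-difference identity
            x[i] = 1.0 - (ci * cos_s[i] + si * sin_s[i])
        for j in range(n_nodes):
            c = 0.0
            for p in range(indptr[j], indptr[j + 1]):
                c += wdata[p] * x[indices[p]]
            cj = cos_buf[j]
            drift = (1.0 - cj) + (1.0 + cj) * (i0[j] + k_over_n * c)
            th = theta[j] + dt * drift \
                + (1.0 + cj) * noise_sd * sqdt * np.random.randn()
            if th > np.pi:
                th -= two_pi
                if m < cap:
                    spike_t[m] = t
                    spike_n[m] = j
                    m += 1
            elif th < -np.pi:
                th += two_pi
            theta[j] = th
    return spike_t[:m], spike_n[:m]


def _validate_weights(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] == 0:
        raise InvalidInputError("weights must be a nonempty square matrix")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("weights must be finite")
    if a.min() < 0 or np.any(np.diag(a) != 0):
        raise InvalidInputError("weights must be nonnegative with zero diagonal")
    return a


def simulate_theta_network(
    a: np.ndarray, params: ThetaParams, k: float, seed: int | None = None
) -> list[np.ndarray]:
    """Euler-Maruyama simulation; returns per-node spike times (model units).

    A spike is an upward crossing of theta = pi; phases are wrapped to
    (-pi, pi]. Excitable nodes (i0 < 0) start at their rest state theta_s;
    intrinsically spiking nodes (i0 >= 0) have no rest state and start just
    past the wrap point with theta_s conventionally 0 in the coupling term.
    Deterministic for a fixed seed.
    """
    a = _validate_weights(a)
    n = a.shape[0]
    i0 = params.i0_vector(n)
    theta_s = np.zeros(n)
    rest = i0 < 0
    if rest.any():
        theta_s[rest] = np.asarray(theta_steady_state(i0[rest]), float)
    theta0 = np.where(rest, theta_s, -np.pi + 1e-9)
    from scipy.sparse import csr_matrix

    csr = csr_matrix(a)
    horizon = params.n_steps * params.dt
    # spike-count bound from the saturated firing rate sqrt(I_max)/pi
    i_max = float(i0.max() + (k / n) * max(csr.sum(axis=1).max(), 0.0) * 2.0)
    rate = math.sqrt(max(i_max, 1.0)) / math.pi
    cap = int(min(n * params.n_steps, 2.0 * n * horizon * rate + 10_000))
    seed_u32 = np.uint32(
        np.random.SeedSequence(params.seed if seed is None else seed).generate_state(1)[0]
    )
    st, sn = _theta_kernel(
        csr.indptr.astype(np.int64),
        csr.indices.astype(np.int64),
        csr.data.astype(np.float64),
        i0,
        theta0,
        theta_s,
        n,
        k / n,
        params.noise_sd,
        params.dt,
        params.n_steps,
        seed_u32,
        cap,
        _COS_TAB,
        _SIN_TAB,
    )
    times = st * params.dt
    return [times[sn == j] for j in range(n)]


def seizure_fraction(
    spike_trains: list[np.ndarray],
    horizon: float,
    window: float = DEFAULT_WINDOW,
    t_start: float = 0.0,
) -> float:
    """BNI*: mean over nodes of the fraction of [t_start, t_start + horizon]
    during which the node has spiked within the trailing window."""
    if horizon <= 0 or window <= 0:
        raise InvalidParameterError("horizon and window must be positive")
    t_end = t_start + horizon
    total = 0.0
    for times in spike_trains:
        times = np.asarray(times, float)
        times = times[(times + window > t_start) & (times < t_end)]
        if times.size == 0:
            continue
        # union of sorted intervals [t, t+window] clipped to [t_start, t_end]
        lo = np.maximum(
            np.maximum(times, t_start),
            np.concatenate(([t_start], times[:-1] + window)),
        )
        hi = np.minimum(times + window, t_end)
        total += float(np.clip(hi - lo, 0.0, None).sum()) / horizon
    return total / len(spike_trains) if spike_trains else 0.0


def bni_star(
    a: np.ndarray,
    params: ThetaParams,
    k: float,
    seed: int | None = None,
    n_realizations: int = 1,
) -> float:
    """BNI* at one coupling value, averaged over noise realizations."""
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    horizon = params.n_steps * params.dt * (1.0 - params.burn_frac)
    t_start = params.n_steps * params.dt * params.burn_frac
    vals = []
    for child in ss.spawn(n_realizations):
        trains = simulate_theta_network(a, params, k, seed=child.generate_state(1)[0] % (2**31))
        vals.append(seizure_fraction(trains, horizon, params.window, t_start))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# BNI curves and the K-integrated BNI
# ---------------------------------------------------------------------------

@dataclass
class BNICurve:
    """BNI*(K) sampled on an increasing coupling grid."""

    k_grid: np.ndarray
    values: np.ndarray
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        self.k_grid = np.asarray(self.k_grid, float)
        self.values = np.asarray(self.values, float)
        if self.k_grid.size < 2 or np.any(np.diff(self.k_grid) <= 0):
            raise InvalidParameterError("k_grid must be increasing with >= 2 points")
        if self.values.shape != self.k_grid.shape:
            raise InvalidInputError("values must match k_grid")


def default_k_grid(k_max: float = 512.0, n_k: int = 21, k_min: float = 1.0) -> np.ndarray:
    """Coupling grid: 0 plus a geometric ladder up to ``k_max``.

    Geometric spacing resolves the transition region of BNI*(K) at any weight
    scale the FC matrices happen to have, while keeping the point count small.
    """
    return np.concatenate([[0.0], np.geomspace(k_min, k_max, n_k - 1)])


def bni_curve(
    a: np.ndarray,
    params: ThetaParams,
    k_grid: np.ndarray,
    seed: int | None = None,
    n_realizations: int = 1,
) -> BNICurve:
    """Evaluate BNI* on a coupling grid with a fresh noise stream per K."""
    k_grid = np.asarray(k_grid, float)
    if k_grid.size < 2 or np.any(np.diff(k_grid) <= 0):
        raise InvalidParameterError("k_grid must be increasing with >= 2 points")
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    children = ss.spawn(k_grid.size)
    vals = [
        bni_star(a, params, float(k), seed=child.generate_state(1)[0] % (2**31),
                 n_realizations=n_realizations)
        for k, child in zip(k_grid, children)
    ]
    return BNICurve(k_grid=k_grid, values=np.array(vals))


def select_k_interval(
    curves: list[BNICurve], threshold: float = 0.95, margin: float = 1.2
) -> tuple[float, float]:
    """Fixed integration interval [K1, K2] shared by all of a subject's segments.

    K1 = 0. K2 is the largest per-curve saturation coupling (smallest grid
    value with BNI* >= threshold), extended by the margin. Curves that never
    reach the threshold on the grid have BNI* ceilings below it (e.g.
    isolated nodes stay quiescent at any K) and contribute the grid maximum;
    if no curve saturates at all, the scan was too narrow.
    """
    if not curves:
        raise InvalidInputError("need at least one curve")
    k_sats = []
    any_saturated = False
    for c in curves:
        idx = np.flatnonzero(c.values >= threshold)
        if idx.size:
            k_sats.append(c.k_grid[idx[0]])
            any_saturated = True
        else:
            k_sats.append(c.k_grid[-1])
    if not any_saturated:
        raise GridExhaustedError(
            "no BNI* curve reaches the saturation threshold; widen the K scan"
        )
    return 0.0, float(margin * max(k_sats))


def bni_integral(curve: BNICurve, k1: float | None = None, k2: float | None = None) -> float:
    """Trapezoidal integral of BNI* over [K1, K2].

    Beyond the scanned grid the curve is extended at its final (saturated)
    value; interior bounds are linearly interpolated onto the grid.
    """
    k1 = curve.k1 if k1 is None else k1
    k2 = curve.k2 if k2 is None else k2
    if k1 is None or k2 is None or k2 <= k1:
        raise InvalidParameterError("require valid bounds with k2 > k1")
    if k1 < curve.k_grid[0] - 1e-12:
        raise InvalidParameterError("k1 below the scanned grid")
    inner = curve.k_grid[(curve.k_grid > k1) & (curve.k_grid < k2)]
    ks = np.concatenate([[k1], inner, [k2]])
    vals = np.interp(ks, curve.k_grid, curve.values)  # right side: last value
    return float(np.trapezoid(vals, ks))


# ---------------------------------------------------------------------------
# timecourses
# ---------------------------------------------------------------------------

N_ICTAL_POINTS = 10


@dataclass
class BNITimecourse:
    """Per-segment BNI values over one peri-ictal epoch (pre, ictal, post)."""

    times: np.ndarray
    values: np.ndarray
    labels: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if not (self.times.size == self.values.size == len(self.labels)):
            raise InvalidInputError("times, values and labels must align")

    def epoch_values(self, label: str) -> np.ndarray:
        mask = np.array([lb == label for lb in self.labels])
        return self.values[mask]


def normalize_timecourse(tc: BNITimecourse) -> BNITimecourse:
    """Normalize by the epoch maximum and resample the ictal run to 10 points.

    Division by the maximum over the whole peri-ictal epoch (pre + ictal +
    post) makes subjects comparable; linear interpolation of the ictal values
    onto 10 equally spaced normalized-time points makes seizure durations
    comparable. Pre- and post-ictal runs keep their lengths.
    """
    ictal_idx = np.array([lb == "ictal" for lb in tc.labels])
    if not ictal_idx.any():
        raise DegenerateTimecourseError("timecourse has no ictal values")
    vmax = tc.values.max()
    if vmax <= 0:
        raise DegenerateTimecourseError("cannot normalize: maximum BNI is zero")
    vals = tc.values / vmax
    it = tc.times[ictal_idx]
    iv = vals[ictal_idx]
    if iv.size == 1:
        new_it = np.full(N_ICTAL_POINTS, it[0])
        new_iv = np.full(N_ICTAL_POINTS, iv[0])
    else:
        pos = np.linspace(0.0, 1.0, iv.size)
        new_pos = np.linspace(0.0, 1.0, N_ICTAL_POINTS)
        new_iv = np.interp(new_pos, pos, iv)
        new_it = np.interp(new_pos, pos, it)
    pre = ~ictal_idx & np.array([t < it[0] for t in tc.times])
    post = ~ictal_idx & ~pre
    times = np.concatenate([tc.times[pre], new_it, tc.times[post]])
    values = np.concatenate([vals[pre], new_iv, vals[post]])
    labels = (
        [lb for lb, m in zip(tc.labels, pre) if m]
        + ["ictal"] * N_ICTAL_POINTS
        + [lb for lb, m in zip(tc.labels, post) if m]
    )
    return BNITimecourse(times=times, values=values, labels=labels, normalized=True)


# ---------------------------------------------------------------------------
# calibration and virtual resection
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    k_ref: float
    achieved: float
    history: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class ResectionResult:
    """Virtual resection of node set ``removed_nodes`` at the reference coupling."""

    removed_nodes: tuple[int, ...]
    bni_pre: float
    bni_post: float

    @property
    def delta_bni(self) -> float:
        return (self.bni_pre - self.bni_post) / self.bni_pre


def calibrate_reference_coupling(
    a: np.ndarray,
    params: ThetaParams,
    target: float = 0.5,
    tol: float = 0.05,
    k_max: float = 512.0,
    n_realizations: int = 3,
    seed: int | None = None,
    max_iter: int = 40,
    min_bracket_frac: float = 0.005,
) -> CalibrationResult:
    """Bisection on K until BNI*(K) hits the reference level (default 0.5).

    Each evaluation averages ``n_realizations`` fresh noise realizations; the
    bracket is expanded geometrically if the scan maximum does not reach the
    target. The bracket is narrowed to ``min_bracket_frac`` of its initial
    width even if an early evaluation already lies within ``tol`` — the
    transition of BNI*(K) is steep, so a coarse bracket midpoint can sit a
    noise-width away from the true crossing. Raises
    :class:`CalibrationError` when the target cannot be bracketed (e.g. an
    all-silent network).
    """
    a = _validate_weights(a)
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    seeds = iter(ss.spawn(max_iter + 16))

    def f(k: float) -> float:
        return bni_star(
            a, params, k, seed=next(seeds).generate_state(1)[0] % (2**31),
            n_realizations=n_realizations,
        )

    history: list[tuple[float, float]] = []
    lo, f_lo = 0.0, f(0.0)
    history.append((lo, f_lo))
    if f_lo >= target + tol:
        raise CalibrationError("baseline BNI* already above target; cannot bracket")
    hi = k_max
    f_hi = f(hi)
    history.append((hi, f_hi))
    expansions = 0
    while f_hi < target and expansions < 5:
        hi *= 2.0
        f_hi = f(hi)
        history.append((hi, f_hi))
        expansions += 1
    if f_hi < target:
        raise CalibrationError(
            f"BNI* reaches only {f_hi:.3f} < target {target} up to K = {hi}"
        )
    best = min(history, key=lambda kv: abs(kv[1] - target))
    min_bracket = min_bracket_frac * hi
    for _ in range(max_iter):
        if hi - lo <= min_bracket and abs(best[1] - target) <= tol:
            return CalibrationResult(k_ref=best[0], achieved=best[1], history=history)
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        history.append((mid, f_mid))
        if abs(f_mid - target) < abs(best[1] - target):
            best = (mid, f_mid)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - target) <= 2 * tol:
        return CalibrationResult(k_ref=best[0], achieved=best[1], history=history)
    raise CalibrationError(
        f"bisection did not reach |BNI* - {target}| <= {tol}; best {best}"
    )


def delta_bni(
    a: np.ndarray,
    removed_nodes,
    params: ThetaParams,
    k_ref: float,
    seed: int | None = None,
    n_realizations: int = 3,
) -> ResectionResult:
    """Relative BNI drop after deleting ``removed_nodes`` from the network.

    The reduced network keeps the same ThetaParams and reference coupling;
    the 1/N prefactor uses the reduced node count (N is defined as the size
    of the simulated network). An empty resection returns DeltaBNI of the
    unmodified network (identically ~0 up to noise).
    """
    a = _validate_weights(a)
    n = a.shape[0]
    removed = tuple(sorted(set(int(i) for i in removed_nodes)))
    if any(i < 0 or i >= n for i in removed):
        raise InvalidResectionError("resected node index out of range")
    if len(removed) >= n:
        raise InvalidResectionError("cannot resect every node")
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    s_pre, s_post = (c.generate_state(1)[0] % (2**31) for c in ss.spawn(2))
    i0 = params.i0_vector(n)
    bni_pre = bni_star(a, replace(params, i0=i0), k_ref, seed=s_pre,
                       n_realizations=n_realizations)
    keep = np.setdiff1d(np.arange(n), removed)
    a_post = a[np.ix_(keep, keep)]
    bni_post = bni_star(a_post, replace(params, i0=i0[keep]), k_ref, seed=s_post,
                        n_realizations=n_realizations)
    if bni_pre <= 0:
        raise CalibrationError("reference BNI is zero; run calibration first")
    return ResectionResult(removed_nodes=removed, bni_pre=bni_pre, bni_post=bni_post)
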