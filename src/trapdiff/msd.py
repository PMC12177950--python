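"""Mean-squared-displacement estimators and mobility-state analysis.

All estimators act on :class:`~trapdiff.trajectories.Trajectory` objects
with contiguous frames. The anomalous-diffusion law fitted throughout is

    <r^2(tau)> = 4 * D_A * tau**alpha,

with the apparent diffusion coefficient ``D_A`` in um^2/s and the
dimensionless exponent ``alpha`` (alpha < 1 indicates subdiffusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .trajectories import Trajectory, TrajectorySet

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "MobilityTrace",
    "DwellSet",
    "LogNormalTrapFit",
    "JumpDistanceDistribution",
    "msd_time_averaged",
    "msd_curve",
    "ensemble_msd",
    "fit_anomalous",
    "temporal_msd",
    "temporal_diffusion",
    "temporal_weights",
    "mobility_states",
    "dwell_times",
    "fit_lognormal",
    "jump_distances",
    "fit_two_component_jumps",
    "STATIONARY_THRESHOLD",
    "DEFAULT_WINDOW",
]

#: Mobile/stationary classification threshold on D_A,temp, um^2/s.
STATIONARY_THRESHOLD = 0.031

#: Default temporal window T (frames) for D_A,temp.
DEFAULT_WINDOW = 16


@dataclass(frozen=True)
class MSDCurve:
    """Lag time vs mean squared displacement.

    ``lags`` are tau = n*Delta-t in seconds, ``msd`` in um^2, ``n_obs``
    the number of displacement pairs (or contributing tracks) per lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, float)
        msd = np.asarray(self.msd, float)
        n_obs = np.asarray(self.n_obs, np.int64)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_obs", n_obs)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("msd must be non-negative")
        if np.any(n_obs < 1):
            raise ValueError("each reported lag needs at least one observation")


@dataclass(frozen=True)
class DiffusionFit:
    """Power-law fit <r^2> = 4 D_A tau^alpha of an MSD curve."""

    D_A: float
    alpha: float
    fit_range: tuple[int, int]
    residual: float


@dataclass(frozen=True)
class MobilityTrace:
    """Per-frame temporal diffusion coefficient and mobile/stationary labels."""

    window: int
    d_temp: np.ndarray
    states: np.ndarray  # bool: True = stationary
    threshold: float

    def __post_init__(self):
        if len(self.d_temp) != len(self.states):
            raise ValueError("d_temp and states must have equal length")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class DwellSet:
    """Durations of stationary segments; ``censored`` marks segments
    touching a trajectory end (their true duration is a lower bound)."""

    durations: np.ndarray
    censored: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.durations, float)
        c = np.asarray(self.censored, bool)
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "censored", c)
        if np.any(d <= 0):
            raise ValueError("dwell durations must be positive")
        if len(d) != len(c):
            raise ValueError("durations and censored flags must align")

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]

    def extend(self, other: "DwellSet") -> "DwellSet":
        return DwellSet(
            np.concatenate([self.durations, other.durations]),
            np.concatenate([self.censored, other.censored]),
        )


@dataclass(frozen=True)
class LogNormalTrapFit:
    """Log-normal trap-time model psi(tau_t | mu, sigma) with reference tau0.

    The density is (tau0 / (tau_t * sigma * sqrt(2 pi)))
    * exp(-(ln(tau_t/tau0) - mu)^2 / (2 sigma^2)); equivalently
    ln(tau_t/tau0) ~ Normal(mu, sigma^2).
    """

    mu: float
    sigma: float
    tau0: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not self.tau0 > 0:
            raise ValueError("tau0 must be positive")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self.tau0 * np.exp(rng.normal(self.mu, self.sigma, size=size))

    @property
    def median(self) -> float:
        return self.tau0 * np.exp(self.mu)

    @property
    def mean(self) -> float:
        return self.tau0 * np.exp(self.mu + 0.5 * self.sigma**2)


@dataclass(frozen=True)
class JumpDistanceDistribution:
    """Pooled jump lengths |r(i+n) - r(i)| at one lag, plus optional fit."""

    lag: float
    distances: np.ndarray
    fit: dict | None = None

    def __post_init__(self):
        d = np.asarray(self.distances, float)
        object.__setattr__(self, "distances", d)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# time-averaged MSD

def _require_contiguous(traj: Trajectory) -> None:
    if not traj.is_contiguous:
        raise ValueError(
            f"track {traj.track_id}: frames have gaps; MSD estimators require "
            "contiguous tracks (reject or split upstream)"
        )


def msd_time_averaged(traj: Trajectory, n: int) -> float:
    """Time-averaged MSD of one trajectory at lag ``n`` frames.

    Returns (1/(l-n)) * sum_{i=1..l-n} |r(i+n) - r(i)|^2 in um^2, the
    average over all displacement pairs separated by n frames.
    """
    _require_contiguous(traj)
    l = len(traj)
    if not 1 <= n < l:
        raise ValueError(f"lag n={n} must satisfy 1 <= n < trajectory length {l}")
    dx = traj.x[n:] - traj.x[:-n]
    dy = traj.y[n:] - traj.y[:-n]
    return float(np.mean(dx * dx + dy * dy))


def msd_curve(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory at all lags 1..max_lag."""
    _require_contiguous(traj)
    l = len(traj)
    if max_lag is None:
        max_lag = l - 1
    max_lag = min(max_lag, l - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.array([msd_time_averaged(traj, int(n)) for n in lags])
    return MSDCurve(lags * traj.frame_time, msd, l - lags)


def ensemble_msd(tset: TrajectorySet, max_lag: int) -> MSDCurve:
    """Ensemble average of per-trajectory time-averaged MSDs.

    Per lag n the unweighted mean of ``msd_time_averaged`` over all
    trajectories with length l > n; lags with no contributing
    trajectory are omitted.
    """
    if len(tset) == 0:
        raise ValueError("ensemble_msd needs a non-empty trajectory set")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for traj in tset:
        _require_contiguous(traj)
        l = len(traj)
        top = min(max_lag, l - 1)
        for n in range(1, top + 1):
            sums[n - 1] += msd_time_averaged(traj, n)
            counts[n - 1] += 1
    keep = counts > 0
    lags = np.arange(1, max_lag + 1)[keep] * tset.frame_time
    return MSDCurve(lags, sums[keep] / counts[keep], counts[keep])


def fit_anomalous(curve: MSDCurve, fit_range: tuple[int, int] | None = None) -> DiffusionFit:
    """Fit <r^2(tau)> = 4 D_A tau^alpha by least squares in log-log space.

    ``fit_range`` is a half-open (start, stop) index range into the
    curve's lags; default uses the first min(10, len) lags. The slope of
    log msd vs log tau is alpha and the intercept is log(4 D_A).
    """
    if fit_range is None:
        fit_range = (0, min(10, len(curve.lags)))
    lo, hi = fit_range
    taus = curve.lags[lo:hi]
    msds = curve.msd[lo:hi]
    if len(taus) < 2:
        raise ValueError("fit_anomalous needs at least two lags in range")
    if np.any(msds <= 0):
        raise ValueError("msd must be positive over the fit range (log undefined)")
    lt, lm = np.log(taus), np.log(msds)
    alpha, intercept = np.polyfit(lt, lm, 1)
    resid = float(np.sum((lm - (alpha * lt + intercept)) ** 2))
    return DiffusionFit(
        D_A=float(np.exp(intercept) / 4.0),
        alpha=float(alpha),
        fit_range=(lo, hi),
        residual=resid,
    )


# ---------------------------------------------------------------------------
# temporal (windowed) MSD and the variance-weighted diffusion coefficient

def temporal_msd(traj: Trajectory, k: int, T: int, n: int) -> float:
    """Windowed MSD at lag n*Delta-t over the T-frame window starting at
    array index ``k`` (0-based): (1/(T-n)) sum_{i=0..T-n-1}
    |r(k+i+n) - r(k+i)|^2."""
    _require_contiguous(traj)
    l = len(traj)
    if not 1 <= n < T:
        raise ValueError("lag n must satisfy 1 <= n < T")
    if not 0 <= k <= l - T:
        raise ValueError(f"window [{k}, {k + T - 1}] outside trajectory of length {l}")
    x = traj.x[k : k + T]
    y = traj.y[k : k + T]
    dx = x[n:] - x[:-n]
    dy = y[n:] - y[:-n]
    return float(np.mean(dx * dx + dy * dy))


def temporal_weights(T: int) -> np.ndarray:
    """Relative-variance weights w(j) for lags j = 1..T-1, normalized to 1.

    The unnormalized weight is the reciprocal relative variance of the
    windowed MSD at lag j, w(j) = (T - j + 1) / (j (2 j^2 + 1)); short
    lags, which average many nearly independent pairs, dominate.
    Normalization makes the weighted estimator a convex combination of
    per-lag unbiased estimates of D, hence itself unbiased for Brownian
    input.
    """
    j = np.arange(1, T, dtype=float)
    w = (T - j + 1) / (j * (2 * j**2 + 1))
    return w / w.sum()


def temporal_diffusion(traj: Trajectory, k: int, T: int = DEFAULT_WINDOW) -> float:
    """Variance-weighted temporal diffusion coefficient D_A,temp (um^2/s)
    over the T-frame window starting at array index ``k``:
    sum_j w(j) * msd_temp(j Delta-t) / (4 j Delta-t)."""
    if T < 2:
        raise ValueError("window T must be >= 2")
    w = temporal_weights(T)
    dt = traj.frame_time
    est = 0.0
    for j in range(1, T):
        est += w[j - 1] * temporal_msd(traj, k, T, j) / (4.0 * j * dt)
    return est


def mobility_states(
    traj: Trajectory,
    threshold: float = STATIONARY_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> MobilityTrace:
    """Classify each frame mobile/stationary from windowed D_A,temp.

    A centered sliding window of ``window`` frames is evaluated per
    frame (clamped to full windows near the ends); the frame is labeled
    stationary when D_A,temp < threshold (default 0.031 um^2/s).
    """
    _require_contiguous(traj)
    l = len(traj)
    if l < window:
        raise ValueError(f"trajectory length {l} shorter than window {window}")
    half = window // 2
    starts = np.clip(np.arange(l) - half, 0, l - window)
    # windows repeat near the ends; evaluate each distinct start once
    cache: dict[int, float] = {}
    d_temp = np.empty(l)
    for i, s in enumerate(starts):
        s = int(s)
        if s not in cache:
            cache[s] = temporal_diffusion(traj, s, window)
        d_temp[i] = cache[s]
    states = d_temp < threshold
    return MobilityTrace(window=window, d_temp=d_temp, states=states,
                         threshold=threshold)


def dwell_times(trace: MobilityTrace, frame_time: float) -> DwellSet:
    """Stationary dwell durations from a mobility trace.

    Maximal runs of stationary frames are converted to durations
    (run length x Delta-t); runs touching either end of the trace are
    flagged censored.
    """
    s = np.asarray(trace.states, bool)
    if not s.any():
        return DwellSet(np.empty(0), np.empty(0, bool))
    padded = np.concatenate([[False], s, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    durations = (ends - starts) * frame_time
    censored = (starts == 0) | (ends == len(s))
    return DwellSet(durations, censored)


def fit_lognormal(dwells: DwellSet, tau0: float = 1.0) -> LogNormalTrapFit:
    """Maximum-likelihood log-normal fit to uncensored dwell durations.

    For the density psi(tau_t | mu, sigma) the MLE is the sample mean
    and standard deviation of ln(tau_t / tau0).
    """
    d = dwells.uncensored
    if len(d) < 10:
        raise ValueError(
            f"fit_lognormal needs >= 10 uncensored dwells, got {len(d)}"
        )
    logs = np.log(d / tau0)
    return LogNormalTrapFit(mu=float(np.mean(logs)),
                            sigma=float(np.std(logs)), tau0=tau0)


# ---------------------------------------------------------------------------
# jump-distance distributions

def jump_distances(tset: TrajectorySet, n: int) -> JumpDistanceDistribution:
    """Pool jump lengths |r(i+n) - r(i)| across all trajectories at lag
    tau = n * Delta-t."""
    if n < 1:
        raise ValueError("lag multiplier n must be >= 1")
    chunks = []
    for traj in tset:
        if len(traj) > n:
            _require_contiguous(traj)
            dx = traj.x[n:] - traj.x[:-n]
            dy = traj.y[n:] - traj.y[:-n]
            chunks.append(np.hypot(dx, dy))
    if not chunks:
        raise ValueError(f"no trajectory longer than lag n={n}")
    return JumpDistanceDistribution(lag=n * tset.frame_time,
                                    distances=np.concatenate(chunks))


def _rayleigh_logpdf(r: np.ndarray, s2: float) -> np.ndarray:
    # 2D jump-length density r/s^2 exp(-r^2 / (2 s^2)) with scale^2 = s2
    return np.log(r) - np.log(s2) - r * r / (2.0 * s2)


class JumpFitError(RuntimeError):
    """Mixture fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate):
        super().__init__(message)
        self.last_iterate = last_iterate


def fit_two_component_jumps(dist: JumpDistanceDistribution,
                            sigma_loc_max: float = 0.15) -> dict:
    """Fit a two-component Rayleigh mixture to a jump-distance sample.

    Model: with probability ``stationary_fraction`` a jump is drawn from
    the stationary component, pure localization noise with scale^2 =
    2 sigma_loc^2 (lag-independent: apparent stationary jumps reflect
    position uncertainty, not motion); otherwise from the mobile
    component with scale^2 = 2 sigma_loc^2 + 2 D_mobile tau. Maximum
    likelihood via Nelder-Mead on transformed parameters.

    ``sigma_loc_max`` bounds the stationary scale to the localization
    regime (default 0.15 um, just above the ~0.1 um practical resolution
    of the imaging model); without the bound the stationary component
    can absorb a purely mobile population and the mixture fraction
    becomes unidentifiable.

    Returns dict with keys ``stationary_fraction``, ``sigma_loc`` (um),
    ``D_mobile`` (um^2/s), ``loglik`` and ``converged``.
    """
    r = dist.distances[dist.distances > 0]
    if len(r) < 100:
        raise ValueError("fit_two_component_jumps needs >= 100 positive distances")
    tau = dist.lag

    def unpack(theta):
        f = 1.0 / (1.0 + np.exp(-theta[0]))
        sigma_loc = sigma_loc_max / (1.0 + np.exp(-theta[1]))
        d_mob = np.exp(theta[2])
        return f, sigma_loc, d_mob

    def nll(theta):
        f, sigma_loc, d_mob = unpack(theta)
        s2_stat = 2.0 * sigma_loc**2
        s2_mob = s2_stat + 2.0 * d_mob * tau
        lp_stat = _rayleigh_logpdf(r, s2_stat) + np.log(f + 1e-300)
        lp_mob = _rayleigh_logpdf(r, s2_mob) + np.log(1.0 - f + 1e-300)
        m = np.maximum(lp_stat, lp_mob)
        return -np.sum(m + np.log(np.exp(lp_stat - m) + np.exp(lp_mob - m)))

    # moment-flavored starting point: small jumps -> localization noise,
    # large jumps -> mobile scale
    q25, q75 = np.quantile(r, [0.25, 0.75])
    sigma0 = np.clip(q25 / np.sqrt(2.0), 0.05 * sigma_loc_max,
                     0.95 * sigma_loc_max)
    d0 = max((q75**2 / 2.0 - 2.0 * sigma0**2) / (2.0 * tau), 1e-6)
    best = None
    for f0 in (0.2, 0.5, 0.8):
        theta0 = np.array([
            np.log(f0 / (1 - f0)),
            np.log(sigma0 / (sigma_loc_max - sigma0)),
            np.log(d0),
        ])
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise JumpFitError("two-component jump fit did not converge",
                           last_iterate=best.x if best is not None else None)
    f, sigma_loc, d_mob = unpack(best.x)
    return {
        "stationary_fraction": float(f),
        "sigma_loc": float(sigma_loc),
        "D_mobile": float(d_mob),
        "loglik": float(-best.fun),
        "converged": bool(best.success),
    }
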