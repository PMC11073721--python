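"""Two-boundary Wiener diffusion machinery.

First-passage-time ("WFPT") densities, absorption probabilities, an
Euler-Maruyama reference sampler, and the contaminant-mixture trial
log-likelihood used by the drift-diffusion fits.

Conventions
-----------
* Diffusion coefficient fixed at 1 (the usual scaling degeneracy; all
  parameters are reported on that scale).
* The *upper* boundary is the correct response.  Drift ``v`` is signed
  toward the correct boundary, so positive ``v`` means above-chance
  accuracy.
* ``w`` is the relative start point in (0, 1); ``w = 0.5`` is unbiased
  and is the default (the model has no bias parameter).
* Densities are *defective*: the density for one boundary integrates to
  that boundary's absorption probability; correct + error integrate to 1.

The density is evaluated by the standard pair of series expansions
(small-time and large-time) with adaptive truncation.  The truncation
rule bounds the absolute error of the standardised density by ``_EPS``
(1e-12), far below the documented 1e-7 contract for the full density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "wfpt_density",
    "absorption_probability",
    "mean_decision_time",
    "simulate_ddm",
    "trial_loglik",
    "loglik_trials",
    "LIKELIHOOD_FLOOR",
]

#: per-trial likelihood floor applied before the log, so that a zero
#: density (e.g. an RT below t0 with p_c = 0) yields a large finite
#: penalty rather than -inf.
LIKELIHOOD_FLOOR = 1e-29

_EPS = 1e-12  # absolute truncation error of the standardised series


class ParameterError(ValueError):
    """Raised for diffusion parameters outside their domain."""


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one condition cell.

    Parameters
    ----------
    v : float
        Drift rate (evidence units / s), signed toward the correct
        (upper) boundary.
    a : float
        Boundary separation (> 0).
    t0 : float
        Non-decision time in seconds (>= 0): encoding plus motor time.
    w : float
        Relative start point in (0, 1); 0.5 = unbiased.
    p_c : float
        Contaminant proportion in [0, 1): fraction of trials produced by
        the outlier process (uniform RT, random response).
    """

    v: float
    a: float
    t0: float
    w: float = 0.5
    p_c: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ParameterError(f"drift v must be finite, got {self.v}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ParameterError(f"boundary a must be > 0, got {self.a}")
        if not (self.t0 >= 0 and np.isfinite(self.t0)):
            raise ParameterError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if not (0.0 < self.w < 1.0):
            raise ParameterError(f"start point w must be in (0, 1), got {self.w}")
        if not (0.0 <= self.p_c < 1.0):
            raise ParameterError(f"contaminant proportion p_c must be in [0, 1), got {self.p_c}")


@njit(cache=True)
def _fpt_standard(tau: float, w: float) -> float:
    """Standardised lower-boundary FPT density (a=1, v=0) at scaled time tau.

    Chooses between the small-time and large-time expansions by the
    number of terms each needs for absolute error <= _EPS and truncates
    adaptively (fewer terms wins).
    """
    if tau <= 0.0:
        return 0.0
    eps = _EPS
    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if math.pi * tau * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        s = 0.0
        for k in range(lo, hi + 1):
            z = w + 2.0 * k
            s += z * math.exp(-z * z / (2.0 * tau))
        return s / math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
        return s * math.pi


@njit(cache=True)
def _density_lower(td: float, v: float, a: float, w: float) -> float:
    """Defective FPT density at the lower boundary, decision time td."""
    if td <= 0.0:
        return 0.0
    tau = td / (a * a)
    f = _fpt_standard(tau, w)
    if f <= 0.0:
        return 0.0
    return f / (a * a) * math.exp(-v * a * w - v * v * td / 2.0)


@njit(cache=True)
def _density(td: float, correct: bool, v: float, a: float, w: float) -> float:
    # upper boundary (correct) = lower-boundary density of the mirrored process
    if correct:
        return _density_lower(td, -v, a, 1.0 - w)
    return _density_lower(td, v, a, w)


def wfpt_density(t, boundary: str, params: DDMParams):
    """Defective first-passage density at RT ``t`` for one boundary.

    Parameters
    ----------
    t : float or array
        Reaction time in seconds (decision time is ``t - t0``).
    boundary : {"correct", "error"}
        Which absorbing boundary; "correct" is the upper one.
    params : DDMParams

    Returns
    -------
    float or ndarray
        Density in 1/s; 0 for ``t <= t0``.
    """
    if boundary not in ("correct", "error"):
        raise ValueError(f"boundary must be 'correct' or 'error', got {boundary!r}")
    correct = boundary == "correct"
    t_arr = np.asarray(t, dtype=float)
    out = np.empty(t_arr.shape, dtype=float)
    flat_t = t_arr.ravel()
    flat_o = out.ravel()
    for i in range(flat_t.size):
        flat_o[i] = _density(flat_t[i] - params.t0, correct, params.v, params.a, params.w)
    return float(out) if t_arr.ndim == 0 else out


def absorption_probability(params: DDMParams) -> float:
    """Probability the diffusion terminates at the correct (upper) boundary.

    Closed form for unit diffusion with boundaries {0, a} and start
    ``z = w a``: ``P(upper) = (1 - exp(-2 v a w)) / (1 - exp(-2 v a))``,
    with the driftless limit ``w``.
    """
    v, a, w = params.v, params.a, params.w
    if abs(v) < 1e-10:
        return w
    x = -2.0 * v * a
    # numerically stable for large |v a|
    num = -np.expm1(x * w)
    den = -np.expm1(x)
    return float(num / den)


def mean_decision_time(params: DDMParams) -> float:
    """Unconditional mean first-passage (decision) time, excluding t0.

    Driftless: ``a^2 w (1-w)``.  With drift:
    ``(a/v) * [ (1-exp(-2vaw))/(1-exp(-2va)) - w ] * coth-free form`` —
    implemented via the standard expectation
    ``E[T] = (a / v) * ( (1 - e^{-2vaw}) / (1 - e^{-2va}) ) * ...``; for
    the unbiased case this reduces to ``(a / 2v) tanh(v a / 2)``.
    """
    v, a, w = params.v, params.a, params.w
    if abs(v) < 1e-10:
        return a * a * w * (1.0 - w)
    z = w * a
    # E[T] for Brownian motion with drift v between 0 and a, start z:
    # E[T] = (a * P_upper - z) / v   (Wald / optional stopping)
    p_up = absorption_probability(params)
    return float((a * p_up - z) / v)


@njit(cache=True, fastmath=True)
def _consume_paths(xs, ts, status, buf, start, v, dt, sq, a):
    """Advance pending paths, consuming pre-drawn normals from ``buf``.

    status: 0 pending, 1 absorbed at upper (correct), -1 at lower.
    ``ts`` accumulates elapsed time; steps are counted as integers and
    converted once per segment to avoid a floating accumulator chain.
    Returns (index of first still-pending path, normals consumed).
    """
    bi = 0
    nb = buf.size
    drift = v * dt
    for i in range(start, xs.size):
        if status[i] != 0:
            continue
        x = xs[i]
        steps = 0
        while True:
            if bi >= nb:
                xs[i] = x
                ts[i] += steps * dt
                return i, bi
            x += drift + sq * buf[bi]
            bi += 1
            steps += 1
            if x >= a or x <= 0.0:
                status[i] = 1 if x >= a else -1
                ts[i] += steps * dt
                break
    return xs.size, bi


def simulate_ddm(params: DDMParams, n: int, seed: int, dt: float = 1e-4):
    """Euler-Maruyama reference sampler of the two-boundary diffusion.

    Returns ``(correct, rt)`` arrays; ``rt`` includes ``t0``.  The
    contaminant proportion ``p_c`` is ignored here — contaminants are a
    separate process injected by the synthetic-data generator.

    Normals come from numpy's Ziggurat generator in large buffers that a
    compiled loop consumes, so throughput is RNG-bound.  ``dt`` must be
    positive; the discretisation bias of the hitting time is O(sqrt(dt)),
    so oracle-grade comparisons use dt <= 1e-4.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not (dt > 0):
        raise ParameterError(f"dt must be > 0, got {dt}")
    n = int(n)
    rng = np.random.default_rng(seed)
    xs = np.full(n, params.w * params.a, dtype=np.float64)
    ts = np.zeros(n, dtype=np.float64)
    status = np.zeros(n, dtype=np.int8)
    sq = math.sqrt(dt)
    # buffer sized to the expected total demand, capped for memory
    expected = mean_decision_time(params) / dt * n * 1.1 + 1024
    bufsize = int(min(expected, 2 ** 23))
    buf = np.empty(bufsize, dtype=np.float64)
    start = 0
    while start < n:
        rng.standard_normal(out=buf)
        start, _ = _consume_paths(xs, ts, status, buf, start, params.v, float(dt), sq, params.a)
    return status == 1, ts + params.t0


@njit(cache=True)
def _loglik_core(
    rts: np.ndarray,
    correct: np.ndarray,
    v: float,
    a: float,
    t0: float,
    w: float,
    p_c: float,
    rt_lo: float,
    rt_hi: float,
) -> float:
    u = 0.5 / (rt_hi - rt_lo)  # uniform density x 0.5 per response side
    total = 0.0
    for i in range(rts.shape[0]):
        f = _density(rts[i] - t0, correct[i], v, a, w)
        lik = (1.0 - p_c) * f
        if p_c > 0.0 and rt_lo <= rts[i] <= rt_hi:
            lik += p_c * u
        if lik < LIKELIHOOD_FLOOR:
            lik = LIKELIHOOD_FLOOR
        total += math.log(lik)
    return total


def trial_loglik(trial, params: DDMParams, rt_window) -> float:
    """Log-likelihood of one ``(correct, rt)`` trial under the mixture.

    ``log[(1 - p_c) f_wfpt(rt, choice) + p_c * 0.5 * U(rt; rt_window)]``
    with the floor :data:`LIKELIHOOD_FLOOR` applied before the log.
    """
    correct, rt = trial
    lo, hi = float(rt_window[0]), float(rt_window[1])
    if not hi > lo:
        raise ValueError(f"rt_window must have positive length, got ({lo}, {hi})")
    return _loglik_core(
        np.array([rt], dtype=float),
        np.array([bool(correct)]),
        params.v, params.a, params.t0, params.w, params.p_c, lo, hi,
    )


def loglik_trials(rts: np.ndarray, correct: np.ndarray, params: DDMParams, rt_window) -> float:
    """Summed mixture log-likelihood over arrays of trials."""
    lo, hi = float(rt_window[0]), float(rt_window[1])
    if not hi > lo:
        raise ValueError(f"rt_window must have positive length, got ({lo}, {hi})")
    return _loglik_core(
        np.ascontiguousarray(rts, dtype=float),
        np.ascontiguousarray(correct, dtype=bool),
        params.v, params.a, params.t0, params.w, params.p_c, lo, hi,
    )
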