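"""Birth-death kinetics of DNA-bound sliding clamps.

During chromosomal replication new clamps are loaded onto freshly primed
Okazaki fragments at an effectively constant rate ``k_p`` (primer formation is
rate limiting, so every new primer consumes one clamp), while each DNA-bound
clamp is unloaded independently with time constant ``t_unload``.  The bound
count ``N(t)`` is therefore an immigration-death chain with constant birth
rate ``k_p`` and per-capita death rate ``1/t_unload``.  At steady state the
total unloading flux ``N/t_unload`` balances the loading flux, giving a
Poisson-distributed plateau with mean ``k_p * t_unload`` and an effective
per-clamp loading interval ``t_unload / N_ss``.

Loading is switched off at the replication time ``t_rep`` (termination), after
which the bound population decays exponentially with the same ``t_unload``.

Two samplers are provided: the fixed time-step scheme (per-step event
probabilities ``dt*k_p`` and ``N*dt/t_unload``) and an exact event-driven
(Gillespie) sampler used as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "ClampTrajectory",
    "EffectiveLoading",
    "steady_state_mean",
    "effective_loading_time",
    "mean_trajectory",
    "simulate_fixed_dt",
    "simulate_exact",
    "sample_counts_fixed_dt",
    "sample_counts_exact",
    "sample_at",
]

#: step-probability validity bound for the fixed-dt scheme
_MAX_STEP_PROB = 0.1


class ParameterError(ValueError):
    """Invalid kinetic parameter or argument."""


@dataclass(frozen=True)
class KineticParams:
    """Rate parameters of the clamp loading/unloading chain.

    Parameters
    ----------
    k_p : float
        Effective loading (primer-formation) rate, events/s.
    t_unload : float
        Per-clamp unloading time constant, s.
    t_rep : float
        Replication duration, s.  Loading stops at ``t_rep``.
    dt : float, optional
        Fixed simulation step, s.  Defaults to ``min(1/k_p, t_unload)/1000``.
    n_init : int
        Bound count at t=0 (default 0: replication starts with no clamps
        loaded).
    """

    k_p: float
    t_unload: float
    t_rep: float
    dt: float | None = None
    n_init: int = 0

    def __post_init__(self) -> None:
        if not (self.k_p >= 0 and math.isfinite(self.k_p)):
            raise ParameterError(f"k_p must be finite and >= 0, got {self.k_p}")
        if not (self.t_unload > 0):
            raise ParameterError(f"t_unload must be > 0, got {self.t_unload}")
        if not (self.t_rep > 0):
            raise ParameterError(f"t_rep must be > 0, got {self.t_rep}")
        if not (isinstance(self.n_init, (int, np.integer)) and self.n_init >= 0):
            raise ParameterError(f"n_init must be a non-negative integer, got {self.n_init}")
        if self.dt is None:
            base = min(1.0 / self.k_p, self.t_unload) if self.k_p > 0 else self.t_unload
            object.__setattr__(self, "dt", base / 1000.0)
        if not (self.dt > 0):
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        self._validate_dt()

    def _validate_dt(self) -> None:
        # refuse (not clip) steps that violate the per-step probability bound
        # for any count the chain can plausibly reach
        if self.dt * self.k_p >= _MAX_STEP_PROB:
            raise ParameterError(
                f"dt*k_p = {self.dt * self.k_p:.3g} violates the step-probability "
                f"bound {_MAX_STEP_PROB}; choose a smaller dt"
            )
        if self.dt * self.reachable_max / self.t_unload >= _MAX_STEP_PROB:
            raise ParameterError(
                f"dt*N_max/t_unload = {self.dt * self.reachable_max / self.t_unload:.3g} "
                f"violates the step-probability bound {_MAX_STEP_PROB}; choose a smaller dt"
            )

    @property
    def reachable_max(self) -> int:
        """Conservative upper bound on counts the chain will visit (mean + 6 sd)."""
        mean = self.k_p * self.t_unload
        return int(self.n_init + math.ceil(mean + 6.0 * math.sqrt(mean) + 10.0))


@dataclass(frozen=True)
class ClampTrajectory:
    """A single realisation of the bound-clamp count over time."""

    times: np.ndarray
    counts: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts)
        if t.shape != c.shape:
            raise ParameterError("times and counts must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(c < 0):
            raise ParameterError("counts must be non-negative")


@dataclass(frozen=True)
class EffectiveLoading:
    """Steady-state balance: one clamp loaded every ``t_load_eff`` seconds."""

    t_load_eff: float
    n_ss: float


def steady_state_mean(params: KineticParams) -> float:
    """Stationary mean bound count, ``k_p * t_unload``."""
    return params.k_p * params.t_unload


def effective_loading_time(n_ss: float, t_unload: float) -> EffectiveLoading:
    """Effective per-clamp loading interval from the steady-state balance.

    At plateau the total unloading rate ``n_ss / t_unload`` equals the loading
    rate ``1 / t_load_eff``, hence ``t_load_eff = t_unload / n_ss``.
    """
    if not (n_ss > 0):
        raise ParameterError(f"n_ss must be > 0, got {n_ss}")
    if not (t_unload > 0):
        raise ParameterError(f"t_unload must be > 0, got {t_unload}")
    return EffectiveLoading(t_load_eff=t_unload / n_ss, n_ss=n_ss)


def mean_trajectory(params: KineticParams, t: float | np.ndarray) -> float | np.ndarray:
    """Analytic mean bound count at time(s) ``t``.

    For ``t <= t_rep`` the immigration-death mean is
    ``k_p*t_unload*(1 - exp(-t/t_unload)) + n_init*exp(-t/t_unload)``;
    after termination the value at ``t_rep`` decays as
    ``exp(-(t - t_rep)/t_unload)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("t must be >= 0")
    tau = params.t_unload
    n_ss = params.k_p * tau

    def rising(tt):
        return n_ss * (1.0 - np.exp(-tt / tau)) + params.n_init * np.exp(-tt / tau)

    # clamp the decay exponent at 0 so the unused branch cannot overflow
    decay_exponent = -np.maximum(t_arr - params.t_rep, 0.0)
    out = np.where(
        t_arr <= params.t_rep,
        rising(np.minimum(t_arr, params.t_rep)),
        rising(params.t_rep) * np.exp(decay_exponent / tau),
    )
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def _fixed_dt_counts(
    params: KineticParams, duration: float, rng: np.random.Generator, n_rep: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised fixed-dt chain: returns (times, counts[n_steps+1, n_rep])."""
    dt = params.dt
    n_steps = int(math.ceil(duration / dt))
    times = np.arange(n_steps + 1) * dt
    counts = np.empty((n_steps + 1, n_rep), dtype=np.int32)
    n = np.full(n_rep, params.n_init, dtype=np.int32)
    counts[0] = n
    p_birth = dt * params.k_p
    death_scale = dt / params.t_unload
    for i in range(n_steps):
        t_now = times[i]
        # two independent uniforms per step: a birth and a death may both fire
        u = rng.random((2, n_rep))
        birth = (u[0] < p_birth) & (t_now <= params.t_rep)
        death = u[1] < n * death_scale
        n = n + birth.astype(np.int32) - death.astype(np.int32)
        counts[i + 1] = n
    return times, counts


def simulate_fixed_dt(params: KineticParams, duration: float, seed: int) -> ClampTrajectory:
    """Fixed time-step Monte Carlo realisation of the chain.

    Per step of length ``dt``: increment with probability ``dt*k_p`` while the
    elapsed time is within the replication period, decrement with probability
    ``count*dt/t_unload``.  The two events are drawn from independent uniforms,
    so both may fire in one step (net change 0).
    """
    if not (duration > 0):
        raise ParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    times, counts = _fixed_dt_counts(params, duration, rng, 1)
    return ClampTrajectory(times=times, counts=counts[:, 0], seed=seed)


def simulate_exact(params: KineticParams, duration: float, seed: int) -> ClampTrajectory:
    """Event-driven (exact) realisation of the same chain.

    Samples inter-event times from the total propensity
    ``k_p*[t <= t_rep] + n/t_unload``; used as the oracle for the fixed-dt
    scheme.  The returned times are the event times prefixed with 0 and
    suffixed with ``duration``.
    """
    if not (duration > 0):
        raise ParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t = 0.0
    n = int(params.n_init)
    times = [0.0]
    counts = [n]
    while True:
        loading = params.k_p if t <= params.t_rep else 0.0
        rate = loading + n / params.t_unload
        if rate == 0.0:
            if t <= params.t_rep < duration and params.k_p > 0:
                # nothing can happen until loading resumes? (loading active
                # region is [0, t_rep]; rate 0 here means k_p == 0 too)
                pass
            break
        dt_next = rng.exponential(1.0 / rate)
        # a waiting interval that straddles t_rep must be re-drawn with the
        # post-termination propensity for the remainder
        if t <= params.t_rep < t + dt_next and loading > 0.0:
            # advance to t_rep and restart the clock (memorylessness)
            t = np.nextafter(params.t_rep, np.inf)
            continue
        t = t + dt_next
        if t >= duration:
            break
        if rng.random() < loading / rate:
            n += 1
        else:
            n -= 1
        times.append(t)
        counts.append(n)
    times.append(duration)
    counts.append(n)
    return ClampTrajectory(
        times=np.asarray(times), counts=np.asarray(counts, dtype=np.int32), seed=seed
    )


def sample_at(traj: ClampTrajectory, times: np.ndarray) -> np.ndarray:
    """Evaluate a (step-function) trajectory at arbitrary times."""
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(traj.times, times, side="right") - 1
    idx = np.clip(idx, 0, len(traj.counts) - 1)
    return np.asarray(traj.counts)[idx]


def sample_counts_fixed_dt(
    params: KineticParams, duration: float, n_rep: int, seed: int
) -> np.ndarray:
    """Final counts at ``duration`` for ``n_rep`` independent fixed-dt chains."""
    rng = np.random.default_rng(seed)
    _, counts = _fixed_dt_counts(params, duration, rng, n_rep)
    return counts[-1]


def sample_counts_exact(
    params: KineticParams, duration: float, n_rep: int, seed: int
) -> np.ndarray:
    """Final counts at ``duration`` for ``n_rep`` independent exact chains.

    Vectorised across replicates (one propensity draw per pending event), so
    large ensembles are cheap; marginally identical to ``simulate_exact``.
    """
    rng = np.random.default_rng(seed)
    t = np.zeros(n_rep)
    n = np.full(n_rep, params.n_init, dtype=np.int64)
    active = np.ones(n_rep, dtype=bool)
    while np.any(active):
        loading = np.where(t <= params.t_rep, params.k_p, 0.0)
        rate = loading + n / params.t_unload
        dead = active & (rate == 0.0)
        if np.any(dead):
            # absorbed at 0 with no loading: state frozen to the horizon
            active = active & ~dead
            t = np.where(dead, duration, t)
            if not np.any(active):
                break
        with np.errstate(divide="ignore"):
            wait = rng.exponential(1.0, n_rep) / np.where(rate > 0, rate, np.inf)
        t_new = t + wait
        # redraw (via memorylessness) any waiting interval straddling t_rep
        straddle = active & (t <= params.t_rep) & (t_new > params.t_rep) & (loading > 0)
        finish = active & (t_new >= duration) & ~straddle
        fire = active & ~straddle & ~finish
        u = rng.random(n_rep)
        birth = fire & (u < np.where(rate > 0, loading / np.where(rate > 0, rate, 1.0), 0.0))
        death = fire & ~birth
        n[birth] += 1
        n[death] -= 1
        t = np.where(straddle, np.nextafter(params.t_rep, np.inf), t_new)
        t = np.where(~active, duration, t)
        active = active & ~finish
    return n.astype(np.int32)
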