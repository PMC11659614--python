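"""Synthetic inputs with known ground truth.

Three generators feed the empirical-style pipeline:

* state-dependent Ornstein–Uhlenbeck (OU) recordings, whose autocorrelation
  decay constant switches with the behavioral state — ground truth for
  timescale-recovery tests;
* wheel-velocity traces built from rest/run/rest bouts, shaped to exercise
  the duration rules of the behavioral segmentation heuristic;
* DTI-like random connectomes: nonnegative, zero-diagonal, heavy-tailed
  weights, optionally symmetric.

All generators take explicit integer seeds; none touches global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import Recording

__all__ = [
    "OUSpec",
    "BoutSpec",
    "ConnectomeSpec",
    "gen_ou_series",
    "gen_state_recording",
    "gen_wheel_velocity",
    "gen_connectome",
]


@dataclass(frozen=True)
class OUSpec:
    """Parameters of a discretely sampled OU process.

    ``tau_true`` is the autocorrelation decay constant in seconds; ``sigma``
    the stationary standard deviation; ``fs`` the sampling rate in Hz.
    """

    tau_true: float
    sigma: float = 1.0
    fs: float = 20.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise ValueError(f"tau_true must be > 0, got {self.tau_true}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def n_samples(self) -> int:
        n = int(round(self.duration * self.fs))
        if n <= 0:
            raise ValueError("duration * fs must be a positive sample count")
        return n

    @property
    def phi(self) -> float:
        """Exact AR(1) coefficient exp(-1/(fs*tau))."""
        return float(np.exp(-1.0 / (self.fs * self.tau_true)))


@dataclass(frozen=True)
class BoutSpec:
    """One rest/run/rest epoch of a wheel-velocity trace (durations in s)."""

    pre_rest: float
    run_duration: float
    post_rest: float
    run_speed: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pre_rest, self.run_duration, self.post_rest) < 0:
            raise ValueError("bout durations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ConnectomeSpec:
    """Random stand-in for an averaged DTI connectivity matrix."""

    n_regions: int = 360
    density: float = 1.0
    weight_law: str = "lognormal"
    scale: float = 1.0  # lognormal sigma or exponential scale
    symmetric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0.0 < self.density <= 1.0:
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.weight_law not in ("lognormal", "exponential"):
            raise ValueError(f"unknown weight_law {self.weight_law!r}")


def _ou_samples(n: int, phi: float, sigma: float, rng: np.random.Generator,
                x0: float | None = None) -> np.ndarray:
    """Exact AR(1) recursion x[t+1] = phi*x[t] + eps, stationary SD sigma."""
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - phi * phi), size=n)
    if x0 is None:
        x0 = rng.normal(0.0, sigma)
    # lfilter runs the recursion in C; zi carries the initial condition
    out, _ = signal.lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def gen_ou_series(spec: OUSpec) -> np.ndarray:
    """Generate one OU series with autocorrelation exp(-lag/tau_true).

    Uses the exact AR(1) discretization: phi = exp(-dt/tau), innovation
    variance sigma^2 (1 - phi^2), so the stationary SD is exactly ``sigma``
    and the lag-1 autocorrelation exactly ``phi``.
    """
    rng = np.random.default_rng(spec.seed)
    return _ou_samples(spec.n_samples, spec.phi, spec.sigma, rng)


def gen_state_recording(
    schedule: list[tuple[str, float]],
    tau_by_state: dict[str, float | np.ndarray],
    n_channels: int,
    fs: float = 20.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> Recording:
    """Multichannel OU recording whose timescale switches with state.

    ``schedule`` is a list of (state, duration_s) entries; ``tau_by_state``
    maps each state to a decay constant in seconds — either a scalar shared
    by all channels or an array of per-channel values. Channels evolve
    continuously across state boundaries (the last sample of one segment
    seeds the next), only the AR(1) coefficient switches. The returned
    recording carries per-sample state labels aligned exactly with the
    schedule.
    """
    if n_channels <= 0:
        raise ValueError(f"n_channels must be positive, got {n_channels}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not schedule:
        raise ValueError("schedule is empty")
    for state, _ in schedule:
        if state not in tau_by_state:
            raise KeyError(f"state {state!r} missing from tau_by_state")

    taus = {}
    for state, tau in tau_by_state.items():
        tau = np.broadcast_to(np.asarray(tau, dtype=float), (n_channels,))
        if np.any(tau <= 0):
            raise ValueError(f"tau for state {state!r} must be > 0")
        taus[state] = tau

    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    label_chunks: list[np.ndarray] = []
    x_last = rng.normal(0.0, sigma, size=n_channels)
    for state, dur_s in schedule:
        n = int(round(dur_s * fs))
        if n <= 0:
            raise ValueError(f"segment ({state!r}, {dur_s}) has no samples")
        phi = np.exp(-1.0 / (fs * taus[state]))
        seg = np.empty((n, n_channels))
        for c in range(n_channels):
            seg[:, c] = _ou_samples(n, float(phi[c]), sigma, rng, x0=x_last[c])
        x_last = seg[-1]
        chunks.append(seg)
        label_chunks.append(np.full(n, state, dtype=object))
    return Recording(
        data=np.concatenate(chunks, axis=0),
        fs=fs,
        labels=np.concatenate(label_chunks),
    )


def gen_wheel_velocity(
    bouts: list[BoutSpec], fs: float = 20.0, seed: int = 0
) -> np.ndarray:
    """Concatenate rest/run/rest epochs into a wheel-velocity trace.

    Rest epochs are zero-mean Gaussian noise at ``noise_sd``; run epochs are
    ``run_speed`` plus the same noise, so the mean absolute velocity during
    running equals ``run_speed`` when the noise is small.
    """
    if not bouts:
        raise ValueError("bouts list is empty")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    for bout in bouts:
        for dur, base in (
            (bout.pre_rest, 0.0),
            (bout.run_duration, bout.run_speed),
            (bout.post_rest, 0.0),
        ):
            n = int(round(dur * fs))
            if n == 0:
                continue
            parts.append(base + rng.normal(0.0, bout.noise_sd, size=n))
    return np.concatenate(parts) if parts else np.empty(0)


def gen_connectome(spec: ConnectomeSpec) -> np.ndarray:
    """Draw a DTI-like random coupling matrix.

    Nonnegative heavy-tailed weights (lognormal or exponential) on a random
    off-diagonal support at the requested density; diagonal zero. With
    ``symmetric=True`` the upper triangle is drawn and mirrored.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions

    def draw(size: int) -> np.ndarray:
        if spec.weight_law == "lognormal":
            return rng.lognormal(mean=0.0, sigma=spec.scale, size=size)
        return rng.exponential(scale=spec.scale, size=size)

    W = np.zeros((n, n))
    if spec.symmetric:
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < spec.density
        vals = np.zeros(iu.size)
        vals[keep] = draw(int(keep.sum()))
        W[iu, ju] = vals
        W[ju, iu] = vals
    else:
        off = ~np.eye(n, dtype=bool)
        m = int(off.sum())
        keep = rng.random(m) < spec.density
        vals = np.zeros(m)
        vals[keep] = draw(int(keep.sum()))
        W[off] = vals
    return W
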