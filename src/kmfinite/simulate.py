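"""Euler-Maruyama simulation of jump-diffusion processes.

The process is

    dX_t = a(X_t) dt + b(X_t) dW(t) + xi dJ(t),

with drift a (default mean-reverting linear, a(x) = -a*x), constant or
state-dependent diffusion b, a Poisson process J with rate lambda, and
Gaussian jump amplitudes xi ~ N(0, s) (s is the amplitude *variance*).
With lambda = 0 or s = 0 this is the Ornstein-Uhlenbeck process, the pure
diffusion benchmark.  The simulator is the synthetic-data source for the
estimation pipeline, and closed-form OU transition moments are provided as
a testing oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "JumpDiffusionSpec",
    "TimeSeries",
    "simulate",
    "ou_conditional_moments",
    "write_series",
    "read_series",
    "SeriesParseError",
]


@dataclass
class JumpDiffusionSpec:
    """Parameters of the jump-diffusion SDE.

    a : mean-reverting strength of the default linear drift -a*x (1/time)
    b : diffusion amplitude (state units / sqrt(time)); constant or callable
    lam : Poisson jump rate (1/time)
    s : variance of the Gaussian jump amplitude (state units squared)
    dt : sampling interval (time)
    x0 : initial state
    seed : integer seed; spawns independent sub-streams for the Brownian,
        Poisson, and amplitude draws so trajectories are reproducible
        independently of draw interleaving
    drift : optional callable a(x) overriding the linear default
    refine : integrate at dt/refine and keep every refine-th point
    """

    a: float = 1.0
    b: float | Callable[[np.ndarray], np.ndarray] = 0.5
    lam: float = 0.0
    s: float = 0.0
    dt: float = 0.01
    x0: float = 0.0
    seed: int = 0
    drift: Callable[[float], float] | None = None
    refine: int = 1

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.lam < 0 or self.s < 0:
            raise ValueError("jump rate and jump variance must be non-negative")
        if not callable(self.b) and self.b < 0:
            raise ValueError("diffusion amplitude must be non-negative")
        if self.refine < 1 or not isinstance(self.refine, int):
            raise ValueError("refine must be a positive integer")


@dataclass
class TimeSeries:
    """A uniformly sampled scalar series with provenance metadata."""

    values: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a time series needs at least two samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size


def _jump_increments(n: int, lam: float, s: float, dt: float, rng_counts, rng_amp):
    """Compound-Poisson increments: K ~ Poisson(lam*dt) jumps per step, each
    N(0, s); their sum is N(0, K*s) given K."""
    if lam == 0.0 or s == 0.0:
        # draw nothing: keeps the diffusion stream identical with/without jumps
        return 0.0, 0
    counts = rng_counts.poisson(lam * dt, size=n)
    amp = rng_amp.standard_normal(n) * np.sqrt(s * counts)
    return amp, int(counts.sum())


def simulate(spec: JumpDiffusionSpec, n_steps: int) -> TimeSeries:
    """Integrate the SDE with the Euler-Maruyama scheme.

    Returns n_steps + 1 samples starting at x0.  Per integration step,

        X_{k+1} = X_k + a(X_k) dt + b(X_k) sqrt(dt) G_k + sum_i xi_i,

    with G_k standard normal and the jump sum a compound-Poisson increment.
    """
    spec.validate()
    if not isinstance(n_steps, int) or n_steps < 1:
        raise ValueError(f"n_steps must be a positive integer, got {n_steps!r}")
    n_fine = n_steps * spec.refine
    dt = spec.dt / spec.refine
    ss = np.random.SeedSequence(spec.seed)
    rng_gauss, rng_pois, rng_amp = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3))

    gauss = rng_gauss.standard_normal(n_fine)
    jumps, n_jumps = _jump_increments(n_fine, spec.lam, spec.s, dt, rng_pois, rng_amp)

    linear = spec.drift is None and not callable(spec.b)
    if linear:
        # X_{k+1} = c X_k + w_k is a first-order linear recursion: solve it
        # vectorised with an IIR filter instead of a Python loop.
        c = 1.0 - spec.a * dt
        w = spec.b * math.sqrt(dt) * gauss + jumps
        x = np.empty(n_fine + 1)
        x[0] = spec.x0
        x[1:], _ = lfilter([1.0], [1.0, -c], w, zi=np.array([c * spec.x0]))
    else:
        drift = spec.drift if spec.drift is not None else (lambda y: -spec.a * y)
        bfun = spec.b if callable(spec.b) else (lambda y: spec.b)
        sqdt = math.sqrt(dt)
        jump_arr = jumps if np.ndim(jumps) else np.zeros(n_fine)
        x = np.empty(n_fine + 1)
        x[0] = spec.x0
        xi = spec.x0
        for k in range(n_fine):
            xi = xi + drift(xi) * dt + bfun(xi) * sqdt * gauss[k] + jump_arr[k]
            x[k + 1] = xi

    values = x[:: spec.refine]
    meta = {
        "a": spec.a,
        "b": spec.b if not callable(spec.b) else "callable",
        "lam": spec.lam,
        "s": spec.s,
        "x0": spec.x0,
        "seed": spec.seed,
        "refine": spec.refine,
        "n_jumps": n_jumps,
    }
    return TimeSeries(values, spec.dt, meta)


def ou_conditional_moments(x0: float, a: float, b: float, tau: float):
    """Exact transition moments of the OU process dX = -aX dt + b dW.

    X_{t+tau} | X_t = x0 is Gaussian with mean x0 e^{-a tau} and variance
    v = b^2 (1 - e^{-2 a tau}) / (2a); returns the raw increment moments
    (M1, M2, M3, M4) of X_{t+tau} - x0.
    """
    if a <= 0:
        raise ValueError(f"mean reversion a must be positive, got {a}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    m1 = x0 * (math.exp(-a * tau) - 1.0)
    v = b**2 * (1.0 - math.exp(-2.0 * a * tau)) / (2.0 * a)
    m2 = m1**2 + v
    m3 = m1**3 + 3.0 * m1 * v
    m4 = m1**4 + 6.0 * m1**2 * v + 3.0 * v**2
    return m1, m2, m3, m4


# --------------------------------------------------------------------------
# series file format: '# dt=...', '# seed=...', then one value per line
# --------------------------------------------------------------------------

class SeriesParseError(ValueError):
    """Malformed series file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_series(series: TimeSeries, path) -> None:
    """Plain-text serialisation, lossless for double precision."""
    with open(path, "w") as fh:
        fh.write(f"# dt={series.dt!r}\n")
        if "seed" in series.meta:
            fh.write(f"# seed={series.meta['seed']}\n")
        for key in sorted(series.meta):
            if key in ("seed",):
                continue
            fh.write(f"# {key}={series.meta[key]}\n")
        for v in series.values:
            fh.write(format(v, ".17g") + "\n")


def read_series(path) -> TimeSeries:
    dt = None
    meta: dict = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise SeriesParseError(f"malformed header {line!r}", lineno)
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                if key == "dt":
                    try:
                        dt = float(val)
                    except ValueError:
                        raise SeriesParseError(f"bad dt value {val!r}", lineno) from None
                else:
                    meta[key] = _coerce(val)
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise SeriesParseError(f"bad numeric value {line!r}", lineno) from None
    if dt is None:
        raise SeriesParseError("missing required header '# dt=<float>'", 0)
    return TimeSeries(np.asarray(values), dt, meta)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val
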