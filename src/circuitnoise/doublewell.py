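"""One-dimensional double-well benchmark systems.

Overdamped Langevin dynamics dx = -V'(x) dt + D sqrt(dt) eta on four
quartic double-well variants that decouple the two notions every sampling
scheme must distinguish — basin width (how many trajectories fall in) and
well depth (how hard noise-driven escape is):

``a``  symmetric:        V = x^4/4 - x^2/2                (equal basins, equal depth)
``b``  tilted symmetric: V = x^4/4 - x^2/2 - 0.1 x        (equal basins, right deeper)
``c``  stretched:        V = u^4/4 - u^2/2, u = x/0.5 (x<0) or x/1.5 (x>=0)
                         (left basin narrow, equal depths)
``d``  stretched+tilt:   V_c + 0.15 x                     (left basin narrow, left deeper)

The stretched variants reuse the symmetric quartic under a piecewise
linear coordinate change, which moves the minima to -0.5 and +1.5 while
keeping both depths at -1/4; the tilt then trades depth between the
wells without moving the saddle far from 0.  Positions are unconstrained
(no nonnegativity clamp — these are abstract coordinates, not expression
levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .simulate import SimulationConfig, Trajectory, _record_steps

#: benchmark noise amplitudes; effective temperatures D^2/2 of 0.5, 0.1
#: and 0.01 against well depths of ~0.25, giving free inter-well hopping,
#: occasional hopping, and complete trapping respectively
NOISE_LEVELS = {"high": 1.0, "intermediate": 0.45, "low": 0.14}

_LEFT_W = 0.5
_RIGHT_W = 1.5
_TILT_B = 0.1   # tilt of variant b (right well deeper, equal basins)
_TILT_D = 0.15  # tilt of variant d (narrow left well deeper)


def _v_sym(x):
    return x**4 / 4.0 - x**2 / 2.0


def _vp_sym(x):
    return x**3 - x


def _u(x):
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, x / _LEFT_W, x / _RIGHT_W)


def _dudx(x):
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, 1.0 / _LEFT_W, 1.0 / _RIGHT_W)


@dataclass(frozen=True)
class DoubleWell:
    """A double-well potential with its sampling domain and landmarks."""

    name: str
    potential: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    minima: tuple[float, float]  # (left, right), refined numerically
    saddle: float

    @property
    def depths(self) -> tuple[float, float]:
        """Potential values at the two minima (left, right)."""
        return (float(self.potential(self.minima[0])), float(self.potential(self.minima[1])))

    @property
    def deeper_side(self) -> str:
        dl, dr = self.depths
        if math.isclose(dl, dr, abs_tol=1e-9):
            return "equal"
        return "left" if dl < dr else "right"

    def basin_widths(self) -> tuple[float, float]:
        """Widths of the two basins within the sampling domain, split at
        the saddle; MIC occupancy under a uniform initial condition is
        proportional to these."""
        lo, hi = self.domain
        return (self.saddle - lo, hi - self.saddle)

    def side(self, x) -> np.ndarray:
        """0 for the left basin, 1 for the right (split at the saddle)."""
        return (np.asarray(x, dtype=float) > self.saddle).astype(int)


def _refine(grad, lo, hi) -> float:
    return float(brentq(grad, lo, hi, xtol=1e-12))


def _build_variants() -> dict[str, DoubleWell]:
    variants: dict[str, DoubleWell] = {}

    variants["a"] = DoubleWell(
        "a", _v_sym, _vp_sym, domain=(-2.0, 2.0), minima=(-1.0, 1.0), saddle=0.0
    )

    def v_b(x):
        return _v_sym(np.asarray(x, dtype=float)) - _TILT_B * np.asarray(x, dtype=float)

    def vp_b(x):
        return _vp_sym(np.asarray(x, dtype=float)) - _TILT_B

    variants["b"] = DoubleWell(
        "b", v_b, vp_b, domain=(-2.0, 2.0),
        minima=(_refine(vp_b, -1.5, -0.5), _refine(vp_b, 0.5, 1.5)),
        saddle=_refine(vp_b, -0.5, 0.5),
    )

    def v_c(x):
        return _v_sym(_u(x))

    def vp_c(x):
        return _vp_sym(_u(x)) * _dudx(x)

    variants["c"] = DoubleWell(
        "c", v_c, vp_c, domain=(-1.0, 2.0), minima=(-_LEFT_W, _RIGHT_W), saddle=0.0
    )

    def v_d(x):
        return v_c(x) + _TILT_D * np.asarray(x, dtype=float)

    def vp_d(x):
        return vp_c(x) + _TILT_D

    variants["d"] = DoubleWell(
        "d", v_d, vp_d, domain=(-1.0, 2.0),
        minima=(_refine(vp_d, -0.9, -0.1), _refine(vp_d, 0.6, 1.9)),
        saddle=_refine(vp_d, -0.05, 0.6),
    )
    return variants


DOUBLE_WELLS: dict[str, DoubleWell] = _build_variants()
VARIANT_NAMES = tuple(DOUBLE_WELLS)


def get_variant(name: str | DoubleWell) -> DoubleWell:
    if isinstance(name, DoubleWell):
        return name
    key = str(name).lower()
    if key not in DOUBLE_WELLS:
        raise ValueError(f"unknown double-well variant {name!r}; choose from {VARIANT_NAMES}")
    return DOUBLE_WELLS[key]


def particle_step(
    well: DoubleWell,
    x: np.ndarray,
    dt: float,
    noise: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Euler--Maruyama step for an array of particles."""
    x = np.asarray(x, dtype=float)
    x_new = x - well.grad(x) * dt
    if noise > 0:
        if rng is None:
            raise ValueError("a random generator is required when noise > 0")
        x_new = x_new + noise * math.sqrt(dt) * rng.standard_normal(x.shape)
    return x_new


def particles_simulate(
    well: DoubleWell,
    x0: np.ndarray,
    *,
    dt: float = 0.02,
    t_max: float = 10.0,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    record_times: Sequence[float] | None = None,
):
    """Integrate many independent particles; returns the terminal positions
    or ``(times, snapshots)`` when ``record_times`` is given."""
    x = np.array(x0, dtype=float)
    n_steps = int(round(t_max / dt))
    recording = record_times is not None
    if recording:
        rec = _record_steps(record_times, dt, n_steps)
        snaps = np.empty((len(record_times), *x.shape))
    for step in range(1, n_steps + 1):
        x = particle_step(well, x, dt, noise, rng)
        if recording and step in rec:
            snaps[rec[step]] = x
    if recording:
        return np.asarray(record_times, dtype=float), snaps
    return x


def sample_domain(well: DoubleWell, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial positions over the variant's sampling domain."""
    return rng.uniform(*well.domain, size=n)


def double_well_simulate(variant: str | DoubleWell, config: SimulationConfig,
                         x0: float | None = None) -> Trajectory:
    """Single-particle trajectory on a double-well variant.

    The initial position defaults to a uniform draw over the variant's
    domain.  Records at ``config.record_times`` (terminal point only by
    default).
    """
    well = get_variant(variant)
    rng = np.random.default_rng(config.seed)
    start = rng.uniform(*well.domain) if x0 is None else float(x0)
    n_steps = int(round(config.t_max / config.dt))
    record_times = config.record_times or (n_steps * config.dt,)
    times, snaps = particles_simulate(
        well,
        np.array([start]),
        dt=config.dt,
        t_max=config.t_max,
        noise=config.noise,
        rng=rng,
        record_times=record_times,
    )
    return Trajectory(times, snaps[:, :, None][:, 0, :], ("x",))
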