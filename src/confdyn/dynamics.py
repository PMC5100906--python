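"""Desk-scale sampling: overdamped Langevin dynamics and exact Boltzmann samplers.

These stand in for production all-atom MD: they sample low-dimensional
collective-variable spaces on analytic potentials so the biasing and
free-energy machinery can be verified against known truth.  The
integrator is overdamped (Brownian): x ← x − (∇V/γ)·dt + √(2·kB·T·dt/γ)·ξ,
which samples the Boltzmann distribution of V at temperature T for small
enough dt.  Every stochastic operation takes an explicit seed and is
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import KB
from .synthetic import PotentialModel

__all__ = ["LangevinSpec", "SampleTrack", "BiasSource", "langevin_run",
           "boltzmann_sampler"]


class BiasSource(Protocol):
    """Anything evaluable to a bias energy and gradient at a CV point."""

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]: ...


@dataclass(frozen=True)
class LangevinSpec:
    """Integration conditions for an overdamped Langevin run.

    ``friction`` is the drag coefficient γ; the diffusion constant is
    kB·T/γ.  Identical seeds give identical trajectories.
    """

    time_step: float = 0.01          # ps
    friction: float = 1.0
    temperature: float = 300.0       # K
    seed: int = 0
    n_steps: int = 10_000
    stride: int = 10
    x0: float | Sequence[float] = 0.0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time step must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.friction <= 0:
            raise ValueError("friction must be positive")


@dataclass
class SampleTrack:
    """Time-ordered positions, instantaneous bias energies and CV traces."""

    times: np.ndarray
    positions: np.ndarray
    bias_energy: np.ndarray
    cv_traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or \
           len(self.times) != len(self.bias_energy):
            raise ValueError("track arrays must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def write_text(self, destination) -> None:
        header = "time " + " ".join(
            f"x{d}" for d in range(self.positions.shape[1])
        ) + " bias " + " ".join(self.cv_traces)
        data = np.column_stack(
            [self.times, self.positions, self.bias_energy]
            + [self.cv_traces[k] for k in self.cv_traces]
        )
        np.savetxt(destination, data, header=header)


def langevin_run(
    potential: PotentialModel,
    biases: Sequence[BiasSource],
    spec: LangevinSpec,
    cv_funcs: dict[str, Callable[[np.ndarray], float]] | None = None,
) -> SampleTrack:
    """Overdamped Langevin sampling of ``potential`` plus bias sources.

    Gaussian noise has standard deviation √(2·kB·T·dt/γ) per coordinate;
    at T = 0 a start at a potential minimum stays there.  A non-finite
    force aborts with the offending step index.
    """
    rng = np.random.default_rng(spec.seed)
    dim = potential.dimension
    x = np.atleast_1d(np.asarray(spec.x0, dtype=float)).copy()
    if x.shape != (dim,):
        raise ValueError(f"x0 must have dimension {dim}")
    mobility = spec.time_step / spec.friction
    noise_scale = np.sqrt(2.0 * KB * spec.temperature * spec.time_step / spec.friction)
    n_out = spec.n_steps // spec.stride
    times = np.empty(n_out)
    positions = np.empty((n_out, dim))
    bias_out = np.empty(n_out)
    cv_funcs = cv_funcs or {}
    traces = {name: np.empty(n_out) for name in cv_funcs}
    out = 0
    for step in range(1, spec.n_steps + 1):
        grad = np.atleast_1d(np.asarray(potential.gradient(x), dtype=float))
        e_bias = 0.0
        for bias in biases:
            eb, gb = bias.energy_gradient(x)
            e_bias += eb
            grad = grad + np.atleast_1d(gb)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite force at step {step}, x={x}")
        x = x - mobility * grad + noise_scale * rng.standard_normal(dim)
        if step % spec.stride == 0:
            times[out] = step * spec.time_step
            positions[out] = x
            bias_out[out] = e_bias
            for name, fn in cv_funcs.items():
                traces[name][out] = fn(x)
            out += 1
    return SampleTrack(times=times, positions=positions, bias_energy=bias_out,
                       cv_traces=traces)


def boltzmann_sampler(
    potential: PotentialModel,
    bias: BiasSource | None,
    temperature: float,
    n: int,
    seed: int,
    domain: tuple[float, float] | None = None,
    grid_points: int = 4001,
) -> np.ndarray:
    """Exact i.i.d. samples from exp(−(V + bias)/kB·T) on a bounded domain.

    1-D only: inverse-CDF sampling on a dense grid (trapezoidal CDF), which
    is deterministic under the seed and free of Markov-chain correlation —
    the oracle sampler for umbrella/WHAM verification.
    """
    if potential.dimension != 1:
        raise ValueError("exact sampler implemented for 1-D potentials")
    if domain is None:
        domain = potential.domain
    if domain is None:
        raise ValueError("a bounded domain is required")
    beta = 1.0 / (KB * temperature)
    grid = np.linspace(domain[0], domain[1], grid_points)
    energy = np.asarray(potential.energy(grid), dtype=float)
    if bias is not None:
        extra = np.array([bias.energy_gradient(np.atleast_1d(g))[0] for g in grid])
        energy = energy + extra
    log_w = -beta * (energy - energy.min())
    density = np.exp(log_w)
    cdf = cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return np.interp(u, cdf, grid)
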