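"""Toy samplers that validate the Gaussian restraints statistically.

Two samplers are provided:

* an internal-coordinate Metropolis chain on a single bend or dihedral
  angle, whose histogram must converge to the Boltzmann density
  exp(-V/kT) of the restraint (no Jacobian — the angle itself is the
  sampled variable); and
* an overdamped (first-order) Langevin integrator on a Cartesian bead
  chain under restraint plus harmonic-bond forces, for generating small
  demonstration trajectories.

Energies are in kJ/mol; kB = 0.0083145 kJ/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import BeadChain
from .restraints import RestraintSpec, cartesian_forces, restraint_energy

__all__ = [
    "KB",
    "SamplerConfig",
    "SampleSet",
    "IntegrationError",
    "boltzmann_density",
    "boltzmann_cdf",
    "metropolis_sample",
    "brownian_dynamics",
]

KB = 0.0083145  # kJ/mol/K


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """Common sampler settings.

    ``step_size`` is the half-width of the uniform Metropolis proposal in
    degrees, or the time step in ps for Brownian dynamics.
    """

    temperature: float = 310.0  # K
    n_steps: int = 100_000
    step_size: float = 2.0
    seed: int = 0
    burn_in: int = 1000
    thinning: int = 1

    def __post_init__(self) -> None:
        if not (self.n_steps > self.burn_in >= 0):
            raise ValueError("need n_steps > burn_in >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class SampleSet:
    values: np.ndarray
    config: SamplerConfig
    acceptance_rate: float


def _domain(spec: RestraintSpec) -> tuple[float, float]:
    return (0.0, 180.0) if spec.kind == "bend" else (-180.0, 180.0)


def boltzmann_density(
    spec: RestraintSpec, temperature: float, grid: np.ndarray
) -> np.ndarray:
    """Normalized Boltzmann density exp(-V/kT) on ``grid`` (trapezoidal norm)."""
    grid = np.asarray(grid, dtype=float)
    v = np.array([restraint_energy(x, spec) for x in grid])
    p = np.exp(-(v - v.min()) / (KB * temperature))
    z = np.trapezoid(p, grid)
    return p / z


def boltzmann_cdf(
    spec: RestraintSpec, temperature: float, grid: np.ndarray
) -> np.ndarray:
    """Cumulative form of :func:`boltzmann_density` on the same grid."""
    from scipy.integrate import cumulative_trapezoid

    grid = np.asarray(grid, dtype=float)
    pdf = boltzmann_density(spec, temperature, grid)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    return cdf / cdf[-1]


def metropolis_sample(spec: RestraintSpec, config: SamplerConfig) -> SampleSet:
    """Metropolis chain on the scalar restraint coordinate.

    Uniform symmetric proposals of half-width ``step_size``; bend proposals
    outside (0, 180) are rejected, dihedral proposals wrap periodically
    into (-180, 180].  Deterministic for a given seed.
    """
    if config.temperature == 0:
        raise ValueError("Metropolis sampling requires a positive temperature")
    lo, hi = _domain(spec)
    periodic = spec.kind == "dihedral"
    beta = 1.0 / (KB * config.temperature)
    k = spec.depth_k
    sigma = spec.width_sigma
    centers = spec.centers

    def energy(x: float) -> float:
        e = 0.0
        for c in centers:
            arg = (x - c) * (x - c) / sigma
            if arg < 700.0:
                e -= k * math.exp(-arg)
        return e

    rng = np.random.default_rng(config.seed)
    # draw all randomness up front; the loop is then pure scalar arithmetic
    props = rng.uniform(-config.step_size, config.step_size, size=config.n_steps)
    logu = np.log(rng.random(size=config.n_steps))

    x = spec.center_deg
    e = energy(x)
    kept: list[float] = []
    accepted = 0
    burn, thin = config.burn_in, config.thinning
    for t in range(config.n_steps):
        xp = x + props[t]
        if periodic:
            if xp > 180.0:
                xp -= 360.0
            elif xp <= -180.0:
                xp += 360.0
            inside = True
        else:
            inside = lo < xp < hi
        if inside:
            ep = energy(xp)
            if -beta * (ep - e) >= logu[t]:
                x, e = xp, ep
                accepted += 1
        if t >= burn and (t - burn) % thin == 0:
            kept.append(x)
    return SampleSet(
        values=np.asarray(kept),
        config=config,
        acceptance_rate=accepted / config.n_steps,
    )


def brownian_dynamics(
    chain: BeadChain,
    specs: list[RestraintSpec],
    bonds: list[tuple[int, int, float, float]],
    config: SamplerConfig,
    mobility: float = 0.01,
    force_limit: float = 1e5,
) -> list[BeadChain]:
    """Overdamped Langevin trajectory of a bead chain.

    Position update per step of length dt = ``step_size`` (ps):

        r += mobility * F * dt + sqrt(2 * mobility * kB * T * dt) * xi

    with ``mobility`` in nm^2 / (kJ/mol * ps) and xi standard normal.
    ``bonds`` are harmonic terms ``(i, j, r0_nm, k_bond)`` with k_bond in
    kJ/mol/nm^2.  Frames are emitted every ``thinning`` steps after
    ``burn_in``.  Bitwise reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    pos = chain.backbone_positions.copy()
    n = chain.n_residues
    dt = config.step_size
    noise_scale = math.sqrt(2.0 * mobility * KB * config.temperature * dt)
    frames: list[BeadChain] = []
    for step in range(config.n_steps):
        f = np.zeros((n, 3))
        work = BeadChain(chain.residue_ids, chain.residue_names, pos)
        for spec in specs:
            f += cartesian_forces(work, spec).cartesian_forces
        for i, j, r0, kb_ in bonds:
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            if r <= 0:
                raise IntegrationError(f"bond {i}-{j} collapsed at step {step}")
            fb = kb_ * (r - r0) * d / r
            f[i] += fb
            f[j] -= fb
        fmax = np.abs(f).max()
        if fmax > force_limit:
            raise IntegrationError(
                f"force blow-up (|F|={fmax:.3g} kJ/mol/nm) at step {step}"
            )
        pos = pos + mobility * f * dt + noise_scale * rng.standard_normal((n, 3))
        if step >= config.burn_in and (step - config.burn_in) % config.thinning == 0:
            frames.append(BeadChain(chain.residue_ids, chain.residue_names, pos.copy()))
    return frames
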