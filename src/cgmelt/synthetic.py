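"""Synthetic multi-temperature peptide-membrane campaigns with known truth.

The generator models membrane *occupancy*, not physics: each residue is a
two-state (bound/unbound) Markov chain whose stationary bound probability

    p_r(T) = w_r / (1 + exp((T - Tm) / s))

decays sigmoidally with temperature around a true melting temperature Tm
with steepness s, scaled by a per-residue affinity weight w_r in [0, 1].
Frames are rendered as 3-D coordinates over a planar phosphate grid so that
running the contact pipeline on the rendered frames recovers the generated
state matrix exactly: bound residues sit below the contact threshold,
unbound residues above it, with truncated Gaussian jitter that respects the
separation.

Temporal correlation is controlled by the total relaxation rate
k_on + k_off_base (per frame): each frame the state refreshes from the
stationary Bernoulli with that probability and persists otherwise, which
keeps the stationary distribution exact at every temperature.

The construct fixtures carry the nine alpha-synuclein N-terminal (and
C-terminal control) sequences used by the melting-curve assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .contacts import DEFAULT_THRESHOLD_NM, LabeledFrame

__all__ = [
    "BindingModelParams",
    "ConstructFixture",
    "CampaignResult",
    "DEFAULT_TEMPERATURE_LADDER",
    "default_residue_weights",
    "uniform_residue_weights",
    "bound_probability",
    "simulate_state_chain",
    "simulate_state_matrix",
    "render_frames",
    "generate_campaign",
    "construct_fixtures",
]

# 310 K to 450 K in 10 K steps: the 15-rung ladder of the melting assay
DEFAULT_TEMPERATURE_LADDER: tuple[float, ...] = tuple(float(t) for t in range(310, 451, 10))


def default_residue_weights(n_residues: int = 30) -> np.ndarray:
    """Extended-like affinity profile: N-terminal dominance.

    The first seven residues bind at full weight; the remainder decay
    linearly (0.95 -> 0.24), giving a mean plateau of about 0.69 for a
    30-residue chain — the shape seen for extended-disordered anchoring,
    where only the initial stretch makes strong contacts.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    head = min(7, n_residues)
    w = np.ones(n_residues)
    if n_residues > head:
        w[head:] = np.linspace(0.95, 0.24, n_residues - head)
    return w


def uniform_residue_weights(n_residues: int = 30) -> np.ndarray:
    """Helical-like profile: uniform full-weight binding along the sequence."""
    return np.ones(max(n_residues, 1))


@dataclass(frozen=True)
class BindingModelParams:
    """Ground truth of the synthetic two-state binding model.

    ``k_on`` and ``k_off_base`` (per frame) set the total relaxation rate of
    the Markov chain; their sum is the per-frame probability that a
    residue's state re-equilibrates, so correlation time is
    1 / (k_on + k_off_base) frames.
    """

    tm_true: float = 380.0  # K
    steepness: float = 10.0  # K
    per_residue_weight: tuple[float, ...] = tuple(default_residue_weights(30))
    k_on: float = 0.05
    k_off_base: float = 0.05
    bound_distance_mean: float = 0.5  # nm, < threshold
    unbound_distance_mean: float = 1.6  # nm, > threshold
    distance_jitter: float = 0.12  # nm, 1-sigma before truncation
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.per_residue_weight, float)
        if np.any((w < 0) | (w > 1)):
            raise ValueError("per-residue weights must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not (0.0 < self.bound_distance_mean < DEFAULT_THRESHOLD_NM < self.unbound_distance_mean):
            raise ValueError(
                "need 0 < bound_distance_mean < threshold (1 nm) < unbound_distance_mean"
            )
        rate = self.k_on + self.k_off_base
        if not (0.0 < rate <= 1.0):
            raise ValueError("k_on + k_off_base must lie in (0, 1]")
        if self.distance_jitter <= 0:
            raise ValueError("distance_jitter must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.per_residue_weight)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.per_residue_weight, float)


@dataclass(frozen=True)
class ConstructFixture:
    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


# Deletion/mutation series of the 30-residue alpha-synuclein N-terminal
# anchor, plus the C-terminal control region (residues 111-140).
_CONSTRUCTS: tuple[tuple[str, str], ...] = (
    ("WT", "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2", "MVFMKGLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2-3", "MFMKGLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2-4", "MMKGLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2-5", "MKGLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2-7", "MLSKAKEGVVAAAEKTKQGVAEAA"),
    ("Del 2-11", "MKEGVVAAAEKTKQGVAEAA"),
    ("CT", "GILEDMPVDPDNEAYEMPSEEGYQDYEPEA"),
    ("F4A", "MDVAMKGLSKAKEGVVAAAEKTKQGVAEAA"),
)


def construct_fixtures() -> list[ConstructFixture]:
    """The nine assay constructs (wild type, N-terminal deletions, the
    C-terminal control and the F4A point mutant)."""
    return [ConstructFixture(n, s) for n, s in _CONSTRUCTS]


def bound_probability(temperature: float, residue: int, params: BindingModelParams) -> float:
    """Stationary bound probability of residue ``residue`` (0-based) at ``temperature``."""
    w = params.weights[residue]
    p = w / (1.0 + np.exp((temperature - params.tm_true) / params.steepness))
    return float(np.clip(p, 0.0, 1.0))


def _refresh_chain(p: float, rate: float, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary two-state chain: refresh from Bernoulli(p) with prob ``rate``."""
    if p <= 0.0:
        return np.zeros(n_frames, dtype=np.uint8)
    if p >= 1.0:
        return np.ones(n_frames, dtype=np.uint8)
    draws = (rng.random(n_frames) < p).astype(np.uint8)
    refresh = rng.random(n_frames) < rate
    refresh[0] = True  # initial state drawn from the stationary law
    idx = np.where(refresh, np.arange(n_frames), -1)
    idx = np.maximum.accumulate(idx)
    return draws[idx]


def simulate_state_chain(
    params: BindingModelParams,
    temperature: float,
    residue: int,
    n_frames: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Binary bound/unbound trajectory of one residue.

    The chain is stationary with bound fraction exactly
    :func:`bound_probability`; target probabilities of 0 or 1 yield
    absorbing all-zero / all-one chains.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = bound_probability(temperature, residue, params)
    return _refresh_chain(p, params.k_on + params.k_off_base, n_frames, rng)


def simulate_state_matrix(
    params: BindingModelParams,
    temperature: float,
    n_frames: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """(n_residues, n_frames) state matrix; residues evolve independently."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.stack(
        [
            simulate_state_chain(params, temperature, r, n_frames, rng)
            for r in range(params.n_residues)
        ]
    )


@dataclass(frozen=True)
class FrameGeometry:
    """Layout of the rendered system (nm).

    Phosphates form a planar grid at z = 0 spanning the box; each residue's
    (x, y) sits on a grid node so its minimum phosphate distance equals its
    own height |z| exactly, which makes the state -> frames -> contacts
    round trip bit-exact.
    """

    box: tuple[float, float, float] = (5.6, 5.6, 14.0)
    grid_spacing: float = 0.7
    threshold: float = DEFAULT_THRESHOLD_NM
    separation_margin: float = 0.05  # nm kept clear on both sides of threshold


def _phosphate_grid(geom: FrameGeometry) -> np.ndarray:
    nx = int(round(geom.box[0] / geom.grid_spacing))
    ny = int(round(geom.box[1] / geom.grid_spacing))
    xs = np.arange(nx) * geom.grid_spacing
    ys = np.arange(ny) * geom.grid_spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])


def _truncated_heights(
    mean: float, lo: float, hi: float, jitter: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    a, b = (lo - mean) / jitter, (hi - mean) / jitter
    return truncnorm.rvs(a, b, loc=mean, scale=jitter, size=size, random_state=rng)


def render_frames(
    states: np.ndarray,
    params: BindingModelParams,
    geometry: FrameGeometry | None = None,
    seed: int | np.random.Generator = 0,
) -> list[LabeledFrame]:
    """Render a (n_residues, n_frames) state matrix as coordinate frames.

    Bound residues are placed at heights drawn from a Gaussian around
    ``bound_distance_mean`` truncated below threshold - margin; unbound
    residues around ``unbound_distance_mean`` truncated above
    threshold + margin.  Raises if the requested means sit inside the
    exclusion band, which would break the bound/unbound separation.
    """
    geom = geometry or FrameGeometry()
    states = np.asarray(states)
    n_res, n_frames = states.shape
    lo_cut = geom.threshold - geom.separation_margin
    hi_cut = geom.threshold + geom.separation_margin
    if not (params.bound_distance_mean < lo_cut and params.unbound_distance_mean > hi_cut):
        raise ValueError(
            "distance means too close to the contact threshold for the "
            f"separation margin {geom.separation_margin} nm"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phosphates = _phosphate_grid(geom)
    box = np.asarray(geom.box, float)

    nx = int(round(geom.box[0] / geom.grid_spacing))
    ny = int(round(geom.box[1] / geom.grid_spacing))
    cols = np.arange(n_res) % nx
    rows = (np.arange(n_res) // nx) % ny
    xy = np.column_stack([cols * geom.grid_spacing, rows * geom.grid_spacing])

    z = np.empty((n_res, n_frames))
    bound = states.astype(bool)
    z_lo = 0.05  # keep beads off the phosphate plane itself
    n_b = int(bound.sum())
    n_u = bound.size - n_b
    if n_b:
        z[bound] = _truncated_heights(
            params.bound_distance_mean, z_lo, lo_cut, params.distance_jitter, n_b, rng
        )
    if n_u:
        # upper truncation keeps unbound beads inside the box half-height
        z_hi = min(box[2] / 2.0 - 0.1, params.unbound_distance_mean + 4 * params.distance_jitter)
        z[~bound] = _truncated_heights(
            params.unbound_distance_mean, hi_cut, z_hi, params.distance_jitter, n_u, rng
        )
    frames = []
    for f in range(n_frames):
        coords = np.column_stack([xy[:, 0], xy[:, 1], z[:, f]])
        frames.append(LabeledFrame(coords, phosphates, box))
    return frames


@dataclass
class CampaignResult:
    """One synthetic multi-temperature campaign plus its ground truth."""

    frames_by_temperature: dict[float, list[LabeledFrame]]
    params: BindingModelParams
    temperatures: tuple[float, ...]
    seed: int

    def ground_truth(self) -> dict:
        return {
            "tm_true": self.params.tm_true,
            "steepness": self.params.steepness,
            "per_residue_weight": list(self.params.weights),
            "k_on": self.params.k_on,
            "k_off_base": self.params.k_off_base,
            "seed": self.seed,
        }


def generate_campaign(
    params: BindingModelParams,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURE_LADDER,
    n_frames: int = 1000,
    seed: int | None = None,
    geometry: FrameGeometry | None = None,
) -> CampaignResult:
    """Full synthetic campaign: one rendered frame set per temperature.

    Every temperature draws from an independent stream spawned
    deterministically from ``seed`` (default: ``params.seed``), so the
    whole campaign is reproducible from one integer and rungs are
    statistically independent.
    """
    if len(temperatures) < 2:
        raise ValueError("need at least two temperatures")
    if seed is None:
        seed = params.seed
    streams = np.random.SeedSequence(seed).spawn(len(temperatures))
    out: dict[float, list[LabeledFrame]] = {}
    for t, ss in zip(temperatures, streams):
        chain_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        states = simulate_state_matrix(params, float(t), n_frames, chain_rng)
        out[float(t)] = render_frames(states, params, geometry, render_rng)
    return CampaignResult(
        frames_by_temperature=out,
        params=params,
        temperatures=tuple(float(t) for t in temperatures),
        seed=int(seed),
    )
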