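"""Gaussian conformational restraints on bend and dihedral angles.

The restraint on an internal coordinate x (bend angle theta or dihedral
phi, both in degrees) is an inverted Gaussian well

    V(x) = -K * sum_c exp(-(x - c)**2 / sigma)

summed over the well center and, for dihedrals, its two periodic images at
center +/- 360 degrees (which keep the energy continuous across the
atan2 branch cut at +/-180).  K is the well depth in kJ/mol; sigma is the
width parameter and, by convention, is the plain printed scalar dividing a
squared-degree quantity (effective 1-sigma width ~ sqrt(sigma/2) deg).

Cartesian forces follow by the chain rule, F = -dV/dx * dx/dr, with the
degree <-> radian conversion carried entirely by the geometric gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BeadChain,
    bend_angle_gradient,
    dihedral_angle_gradient,
)

__all__ = [
    "RestraintSpec",
    "EnergyForceResult",
    "HELICAL_BEND_CENTER",
    "EXTENDED_BEND_CENTER",
    "HELICAL_DIHEDRAL_CENTER",
    "EXTENDED_DIHEDRAL_CENTER",
    "DEFAULT_SIGMA",
    "DEFAULT_DEPTH_K",
    "restraint_energy",
    "restraint_internal_gradient",
    "cartesian_forces",
    "build_conformation_restraints",
    "export_tabulated_potentials",
    "parse_tabulated_potential",
    "serialize_restraints",
]

# Restraint centers for the two conformational basins, in degrees.
HELICAL_BEND_CENTER = 96.0
EXTENDED_BEND_CENTER = 124.0
HELICAL_DIHEDRAL_CENTER = 60.0
EXTENDED_DIHEDRAL_CENTER = 100.0

DEFAULT_SIGMA = 14.0
DEFAULT_DEPTH_K = 50.0  # kJ/mol; well depth, configurable everywhere


@dataclass(frozen=True)
class RestraintSpec:
    """One Gaussian well on a bend or dihedral angle.

    Parameters
    ----------
    kind
        ``"bend"`` (3 beads) or ``"dihedral"`` (4 beads).
    bead_indices
        0-based indices into a :class:`~cgmelt.geometry.BeadChain`.
    center_deg
        Well center in degrees.
    width_sigma
        Width parameter; divides the squared degree deviation as printed.
    depth_k
        Well depth in kJ/mol.
    periodic_images
        Extra centers in degrees; empty for bends, ``(c-360, c+360)``
        for dihedrals.
    """

    kind: str
    bead_indices: tuple[int, ...]
    center_deg: float
    width_sigma: float = DEFAULT_SIGMA
    depth_k: float = DEFAULT_DEPTH_K
    periodic_images: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("bend", "dihedral"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        want = 3 if self.kind == "bend" else 4
        if len(self.bead_indices) != want:
            raise ValueError(f"{self.kind} restraint needs {want} bead indices")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.depth_k <= 0:
            raise ValueError("depth_k must be positive")
        if self.kind == "bend" and not (0.0 < self.center_deg < 180.0):
            raise ValueError("bend center must lie in (0, 180) degrees")
        if self.kind == "dihedral" and not (-180.0 <= self.center_deg <= 180.0):
            raise ValueError("dihedral center must lie in [-180, 180] degrees")

    @property
    def centers(self) -> tuple[float, ...]:
        return (self.center_deg, *self.periodic_images)

    @classmethod
    def bend(cls, indices, center_deg, width_sigma=DEFAULT_SIGMA, depth_k=DEFAULT_DEPTH_K):
        return cls("bend", tuple(indices), float(center_deg), width_sigma, depth_k)

    @classmethod
    def dihedral(cls, indices, center_deg, width_sigma=DEFAULT_SIGMA, depth_k=DEFAULT_DEPTH_K):
        c = float(center_deg)
        return cls(
            "dihedral", tuple(indices), c, width_sigma, depth_k,
            periodic_images=(c - 360.0, c + 360.0),
        )


@dataclass
class EnergyForceResult:
    """Energy, internal gradient and per-bead Cartesian forces of one restraint."""

    energy: float  # kJ/mol
    internal_gradient: float  # kJ/mol/deg
    cartesian_forces: np.ndarray = field(repr=False)  # (n_beads, 3), kJ/mol/nm


def restraint_energy(x_deg: float, spec: RestraintSpec) -> float:
    """Gaussian well energy at angle ``x_deg`` (kJ/mol, minimum -depth_k)."""
    e = 0.0
    for c in spec.centers:
        arg = (x_deg - c) ** 2 / spec.width_sigma
        if arg < 700.0:  # exp underflow guard
            e -= spec.depth_k * math.exp(-arg)
    return e


def restraint_internal_gradient(x_deg: float, spec: RestraintSpec) -> float:
    """dV/dx at ``x_deg`` in kJ/mol/deg (analytic)."""
    g = 0.0
    for c in spec.centers:
        d = x_deg - c
        arg = d * d / spec.width_sigma
        if arg < 700.0:
            g += 2.0 * spec.depth_k * d * math.exp(-arg) / spec.width_sigma
    return g


def cartesian_forces(chain: BeadChain, spec: RestraintSpec) -> EnergyForceResult:
    """Energy and per-bead forces of one restraint on a chain.

    Forces are returned for the full chain (n_residues, 3); beads outside
    the restraint carry exactly zero.  Degenerate geometry raises rather
    than returning silent zeros.
    """
    idx = spec.bead_indices
    pos = chain.backbone_positions
    if max(idx) >= chain.n_residues or min(idx) < 0:
        raise IndexError("restraint bead indices out of range for chain")
    pts = [pos[i] for i in idx]
    if spec.kind == "bend":
        x, grad = bend_angle_gradient(*pts)
    else:
        x, grad = dihedral_angle_gradient(*pts)
    dV = restraint_internal_gradient(x, spec)
    forces = np.zeros((chain.n_residues, 3))
    for row, i in enumerate(idx):
        forces[i] -= dV * grad[row]
    return EnergyForceResult(
        energy=restraint_energy(x, spec),
        internal_gradient=dV,
        cartesian_forces=forces,
    )


def build_conformation_restraints(
    n_residues: int,
    mode: str,
    sigma: float = DEFAULT_SIGMA,
    depth_k: float = DEFAULT_DEPTH_K,
) -> list[RestraintSpec]:
    """Restraint set pinning a chain into the helical or extended basin.

    One bend restraint per consecutive backbone triple and one dihedral
    restraint per consecutive quadruple: n-2 bends and n-3 dihedrals.
    """
    if mode not in ("helical", "extended"):
        raise ValueError(f"mode must be 'helical' or 'extended', got {mode!r}")
    if n_residues < 3:
        raise ValueError("need at least 3 residues for a bend restraint")
    if mode == "helical":
        bend_c, dih_c = HELICAL_BEND_CENTER, HELICAL_DIHEDRAL_CENTER
    else:
        bend_c, dih_c = EXTENDED_BEND_CENTER, EXTENDED_DIHEDRAL_CENTER
    specs: list[RestraintSpec] = []
    for i in range(n_residues - 2):
        specs.append(RestraintSpec.bend((i, i + 1, i + 2), bend_c, sigma, depth_k))
    for i in range(n_residues - 3):
        specs.append(RestraintSpec.dihedral((i, i + 1, i + 2, i + 3), dih_c, sigma, depth_k))
    return specs


def _domain(spec: RestraintSpec) -> tuple[float, float]:
    return (0.0, 180.0) if spec.kind == "bend" else (-180.0, 180.0)


def export_tabulated_potentials(spec: RestraintSpec, grid_spacing: float = 0.1) -> str:
    """Tabulate one restraint as a three-column bonded-interaction table.

    Columns are angle (deg), V (kJ/mol) and -dV/dx (kJ/mol/deg) on a uniform
    grid over [0, 180] for bends or [-180, 180] for dihedrals, in the
    whitespace-separated dialect used for tabulated bonded interactions by
    mainstream MD engines.  ``grid_spacing`` must divide the domain exactly.
    """
    lo, hi = _domain(spec)
    span = hi - lo
    n = span / grid_spacing
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"grid spacing {grid_spacing} does not divide the {span} degree domain")
    xs = lo + grid_spacing * np.arange(round(n) + 1)
    lines = [f"# {spec.kind} restraint: center {spec.center_deg} deg, "
             f"sigma {spec.width_sigma}, K {spec.depth_k} kJ/mol"]
    for x in xs:
        v = restraint_energy(float(x), spec)
        f = -restraint_internal_gradient(float(x), spec)
        lines.append(f"{x:12.4f} {v:20.12e} {f:20.12e}")
    return "\n".join(lines) + "\n"


def parse_tabulated_potential(text: str) -> np.ndarray:
    """Parse a tabulated potential back into an (n, 3) array."""
    rows = [
        [float(tok) for tok in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return np.asarray(rows, dtype=float)


def serialize_restraints(specs: list[RestraintSpec], mode: str | None = None) -> str:
    """Plain-text ``key: value`` serialization of a restraint set."""
    out = []
    if mode is not None:
        out.append(f"mode: {mode}")
    out.append(f"n_restraints: {len(specs)}")
    for i, s in enumerate(specs):
        beads = "-".join(str(b) for b in s.bead_indices)
        out.append(
            f"restraint_{i}: kind={s.kind} beads={beads} "
            f"center={s.center_deg} sigma={s.width_sigma} K={s.depth_k}"
        )
    return "\n".join(out) + "\n"
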