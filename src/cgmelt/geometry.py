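"""Internal-coordinate geometry for coarse-grained bead chains.

Bend and dihedral angles between consecutive backbone beads, together with
their analytic Cartesian gradients.  All angles are reported in degrees
(matching the convention in which the restraint parameters are quoted);
gradients are returned in degrees per nm so that the chain rule against a
degree-valued potential needs no hidden unit conversion.

Coordinates are in nm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "BeadChain",
    "bend_angle",
    "dihedral_angle",
    "bend_angle_gradient",
    "dihedral_angle_gradient",
]

RAD2DEG = 180.0 / np.pi

# below this sine the bend/dihedral gradient is numerically singular
_SIN_TOL = 1e-8
_LEN_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when bead geometry makes an internal coordinate ill-defined."""


def _as_vec3(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("coordinates must be finite")
    return v


@dataclass
class BeadChain:
    """Ordered backbone-bead coordinates of a one-bead-per-residue chain.

    Parameters
    ----------
    residue_ids
        1-based residue indices, ordered along the chain.
    residue_names
        One-letter residue codes, same length.
    backbone_positions
        (n, 3) array of bead coordinates in nm.
    """

    residue_ids: list[int]
    residue_names: list[str]
    backbone_positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.backbone_positions = np.asarray(self.backbone_positions, dtype=float)
        n = len(self.residue_ids)
        if len(self.residue_names) != n:
            raise ValueError("residue_ids and residue_names length mismatch")
        if self.backbone_positions.shape != (n, 3):
            raise ValueError(
                f"backbone_positions shape {self.backbone_positions.shape} "
                f"does not match {n} residues"
            )
        if not np.all(np.isfinite(self.backbone_positions)):
            raise ValueError("backbone positions must be finite")
        if n >= 2:
            bond = np.linalg.norm(np.diff(self.backbone_positions, axis=0), axis=1)
            if np.any(bond <= 0):
                raise ValueError("consecutive backbone beads must not coincide")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def sequence(self) -> str:
        return "".join(self.residue_names)

    @classmethod
    def from_sequence(cls, sequence: str, positions: np.ndarray) -> "BeadChain":
        return cls(list(range(1, len(sequence) + 1)), list(sequence), positions)


def bend_angle(pi, pj, pk) -> float:
    """Angle (degrees, in [0, 180]) at bead j between beads i, j, k.

    Defined as the arccosine of the normalized dot product of the two arm
    vectors j->i and j->k.
    """
    pi, pj, pk = _as_vec3(pi), _as_vec3(pj), _as_vec3(pk)
    u = pi - pj
    v = pk - pj
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _LEN_TOL or nv < _LEN_TOL:
        raise DegenerateGeometryError("bend angle undefined: arm bead coincides with vertex")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def bend_angle_gradient(pi, pj, pk) -> tuple[float, np.ndarray]:
    """Bend angle plus its Cartesian gradient.

    Returns ``(theta_deg, grad)`` where ``grad`` is a (3, 3) array holding
    d(theta)/d(r) in deg/nm for beads i, j, k in order.  Raises
    :class:`DegenerateGeometryError` for collinear arms, where the gradient
    is singular.
    """
    pi, pj, pk = _as_vec3(pi), _as_vec3(pj), _as_vec3(pk)
    u = pi - pj
    v = pk - pj
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _LEN_TOL or nv < _LEN_TOL:
        raise DegenerateGeometryError("bend angle undefined: arm bead coincides with vertex")
    uh = u / nu
    vh = v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = np.sqrt(max(1.0 - c * c, 0.0))
    if s < _SIN_TOL:
        raise DegenerateGeometryError("bend gradient singular: beads are collinear")
    dth_dpi = (c * uh - vh) / (nu * s)
    dth_dpk = (c * vh - uh) / (nv * s)
    grad = np.empty((3, 3))
    grad[0] = dth_dpi
    grad[2] = dth_dpk
    grad[1] = -(dth_dpi + dth_dpk)
    return float(np.degrees(np.arccos(c))), grad * RAD2DEG


def _dihedral_vectors(pi, pj, pk, pl):
    pi, pj, pk, pl = _as_vec3(pi), _as_vec3(pj), _as_vec3(pk), _as_vec3(pl)
    b1 = pj - pi
    b2 = pk - pj
    b3 = pl - pk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _LEN_TOL:
        raise DegenerateGeometryError("dihedral undefined: central bond has zero length")
    if np.linalg.norm(n1) < _SIN_TOL * nb2 * np.linalg.norm(b1):
        raise DegenerateGeometryError("dihedral undefined: beads i, j, k are collinear")
    if np.linalg.norm(n2) < _SIN_TOL * nb2 * np.linalg.norm(b3):
        raise DegenerateGeometryError("dihedral undefined: beads j, k, l are collinear")
    return b1, b2, b3, n1, n2, nb2


def dihedral_angle(pi, pj, pk, pl) -> float:
    """Dihedral angle (degrees, in (-180, 180]) over beads i-j-k-l.

    Four-quadrant inverse tangent construction; the cis (eclipsed) planar
    arrangement is 0 degrees and trans is 180 degrees (IUPAC convention).
    """
    b1, b2, b3, n1, n2, nb2 = _dihedral_vectors(pi, pj, pk, pl)
    sin_term = np.dot(b1, n2) * nb2
    cos_term = np.dot(n1, n2)
    phi = float(np.degrees(np.arctan2(sin_term, cos_term)))
    # atan2 returns -180 for the trans pose depending on rounding; fold to +180
    if phi <= -180.0:
        phi += 360.0
    return phi


def dihedral_angle_gradient(pi, pj, pk, pl) -> tuple[float, np.ndarray]:
    """Dihedral angle plus its Cartesian gradient.

    Returns ``(phi_deg, grad)`` with ``grad`` a (4, 3) array holding
    d(phi)/d(r) in deg/nm for beads i, j, k, l in order.
    """
    b1, b2, b3, n1, n2, nb2 = _dihedral_vectors(pi, pj, pk, pl)
    sin_term = np.dot(b1, n2) * nb2
    cos_term = np.dot(n1, n2)
    phi = float(np.degrees(np.arctan2(sin_term, cos_term)))
    if phi <= -180.0:
        phi += 360.0

    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    dphi_dpi = -(nb2 / sq1) * n1
    dphi_dpl = (nb2 / sq2) * n2
    p = float(np.dot(b1, b2)) / (nb2 * nb2)
    q = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_dpj = -(1.0 + p) * dphi_dpi + q * dphi_dpl
    dphi_dpk = p * dphi_dpi - (1.0 + q) * dphi_dpl
    grad = np.vstack([dphi_dpi, dphi_dpj, dphi_dpk, dphi_dpl])
    return phi, grad * RAD2DEG
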