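import numpy as np
import pytest

from cgmelt.geometry import BeadChain


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_chain(rng: np.random.Generator, n: int, bond: float = 0.35) -> BeadChain:
    """Self-avoiding-ish random walk chain with fixed bond length."""
    pos = np.zeros((n, 3))
    for i in range(1, n):
        step = rng.normal(size=3)
        pos[i] = pos[i - 1] + bond * step / np.linalg.norm(step)
    return BeadChain(list(range(1, n + 1)), ["A"] * n, pos)


def finite_difference_forces(chain, spec, h=1e-6):
    """Central finite differences of the restraint energy wrt coordinates."""
    from cgmelt.geometry import bend_angle, dihedral_angle
    from cgmelt.restraints import restraint_energy

    def energy(pos):
        pts = [pos[i] for i in spec.bead_indices]
        x = bend_angle(*pts) if spec.kind == "bend" else dihedral_angle(*pts)
        return restraint_energy(x, spec)

    pos = chain.backbone_positions
    f = np.zeros_like(pos)
    for a in spec.bead_indices:
        for d in range(3):
            pp = pos.copy()
            pp[a, d] += h
            pm = pos.copy()
            pm[a, d] -= h
            f[a, d] = -(energy(pp) - energy(pm)) / (2 * h)
    return f
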