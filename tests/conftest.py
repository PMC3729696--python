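"""Shared fixtures: one template chain and a few small assemblies.

Session-scoped where the object is never mutated by tests; helpers return
fresh copies otherwise.
"""

import numpy as np
import pytest

from crossbeta import (
    PerturbationParams,
    build_pair,
    build_protofilament,
    make_template_chain,
    make_synthetic_ensemble,
)


@pytest.fixture(scope="session")
def template_chain():
    return make_template_chain()


@pytest.fixture(scope="session")
def proto6(template_chain):
    return build_protofilament(template_chain, n=6)


@pytest.fixture(scope="session")
def proto4(template_chain):
    return build_protofilament(template_chain, n=4)


@pytest.fixture(scope="session")
def pair4(template_chain):
    return build_pair(build_protofilament(template_chain, n=4))


def static_ensemble(assembly, n_frames=2):
    """Noise-free, twist-free ensemble: every frame equals the input."""
    return make_synthetic_ensemble(
        assembly,
        PerturbationParams(seed=0, twist_per_monomer=0.0, hinge_bend=0.0,
                           noise_sigma=0.0, n_frames=n_frames))


def twisted_ensemble(assembly, twist, n_frames=11, seed=0, noise=0.0,
                     hinge=0.0):
    return make_synthetic_ensemble(
        assembly,
        PerturbationParams(seed=seed, twist_per_monomer=twist,
                           hinge_bend=hinge, noise_sigma=noise,
                           n_frames=n_frames))


# ---------------------------------------------------------------------------
# independent oracles (deliberately avoid the library's rotation / dihedral
# code paths)

def rodrigues_matrix(axis, angle_deg):
    """Hand-rolled Rodrigues rotation matrix."""
    axis = np.asarray(axis, float)
    axis = axis / np.sqrt((axis ** 2).sum())
    t = np.radians(angle_deg)
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return (np.eye(3) + np.sin(t) * k_cross
            + (1 - np.cos(t)) * (k_cross @ k_cross))


def oracle_dihedral(p0, p1, p2, p3):
    """Signed dihedral via the atan2(|b2| b1.(b2xb3), (b1xb2).(b2xb3))
    identity -- a different algebraic route than the implementation."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    y = np.sqrt((b2 ** 2).sum()) * (b1 @ np.cross(b2, b3))
    x = np.cross(b1, b2) @ np.cross(b2, b3)
    return np.degrees(np.arctan2(y, x))


def oracle_total_twist(assembly, twist_per_monomer, angles_schedule):
    """Expected unwrapped twist trace from explicit rotation matrices.

    For each scheduled fraction f, rotate the dihedral-defining CA points
    of chains 2 and n-1 by their chain index times f * twist about the
    growth axis through the assembly centroid, evaluate the oracle
    dihedral, and unwrap by hand.
    """
    chains = assembly.layers[0]
    n = len(chains)
    pts = np.array([chains[1].residue(18).atom("CA").coord,
                    chains[1].residue(24).atom("CA").coord,
                    chains[n - 2].residue(24).atom("CA").coord,
                    chains[n - 2].residue(18).atom("CA").coord])
    owners = np.array([1, 1, n - 2, n - 2])
    # same axis convention as the generator: through the V24 CA column
    anchor = np.array([c.residue(24).atom("CA").coord
                       for c in assembly.all_chains()]).mean(axis=0)
    axis = assembly.growth_axis
    trace = []
    prev = 0.0
    for f in angles_schedule:
        moved = []
        for p, j in zip(pts, owners):
            mat = rodrigues_matrix(axis, j * twist_per_monomer * f)
            moved.append(mat @ (p - anchor) + anchor)
        raw = oracle_dihedral(*moved)
        if (moved[2] - moved[1]) @ axis < 0:
            raw = -raw
        while raw - prev > 180.0:
            raw -= 360.0
        while raw - prev < -180.0:
            raw += 360.0
        trace.append(raw)
        prev = raw
    return np.array(trace)
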