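"""Synthetic trajectory generation over built assemblies.

A synthetic ensemble emulates the statistical structure of an MD
trajectory of a cross-beta oligomer without any dynamics: a cumulative
twist of the stacked beta-sheets about the growth axis (ramped linearly
from the untwisted start to its full value at the final frame, mimicking
relaxation toward a twisted equilibrium), a flexible hinge in the
C-terminal tail distal to G37/G38 (applied with per-chain random
magnitudes, and only to single-layer protofilaments whose C-terminal sheet
is solvent-exposed -- in a pair that face is covered by the second layer),
iid Gaussian coordinate noise, and an optional breakage of over-twisted
protofilaments into two fragments.

All stochastic draws come from one seeded generator, so identical
parameters give bit-identical ensembles.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Assembly, Ensemble, ValidationError

#: First residue of the flexible C-terminal tail (distal to the G37/G38
#: hinge).
HINGE_TAIL_START = 39


@dataclass
class PerturbationParams:
    """Knobs of the synthetic trajectory generator.

    ``twist_per_monomer`` (degrees) is the cumulative rotation about the
    growth axis per stacking step, reached at the final frame;
    ``hinge_bend`` (degrees) is the maximum bend of the C-terminal tail in
    solvent-exposed layers; ``noise_sigma`` (A) is iid Gaussian noise per
    atom coordinate; ``rupture_threshold`` (degrees) introduces a fragment
    gap when the applied per-monomer twist exceeds it (single layers only).
    ``seed`` is required: one generator drives all draws.
    """

    seed: int
    twist_per_monomer: float = 5.0
    hinge_bend: float = 30.0
    noise_sigma: float = 0.25
    n_frames: int = 51
    frame_dt: float = 5.0  # ps, the trajectory saving interval
    rupture_threshold: Optional[float] = None

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.frame_dt <= 0:
            raise ValidationError("frame_dt must be > 0")


def _atom_groups(assembly: Assembly):
    """Flat-index groups: per (layer, chain) all atoms, and tail atoms."""
    chain_atoms: list[np.ndarray] = []
    tail_atoms: list[np.ndarray] = []
    pivots: list[np.ndarray] = []
    chain_pos: list[int] = []  # stacking position j within its layer
    flat = 0
    for li, layer in enumerate(assembly.layers):
        for j, chain in enumerate(layer):
            idx_all, idx_tail = [], []
            pivot = None
            for res in chain.residues:
                for a in res.atoms:
                    idx_all.append(flat)
                    if res.seq_index >= HINGE_TAIL_START:
                        idx_tail.append(flat)
                    if res.seq_index == HINGE_TAIL_START - 1 and a.name == "CA":
                        pivot = a.coord.copy()
                    flat += 1
            chain_atoms.append(np.array(idx_all, dtype=int))
            tail_atoms.append(np.array(idx_tail, dtype=int))
            pivots.append(pivot if pivot is not None else np.zeros(3))
            chain_pos.append(j)
    return chain_atoms, tail_atoms, pivots, chain_pos


def make_synthetic_ensemble(assembly: Assembly,
                            pert: PerturbationParams) -> Ensemble:
    """Generate a synthetic ensemble from a built assembly.

    Frame k applies (i) cumulative twist -- chain j rotated by
    j * twist_per_monomer * k/(n_frames-1) about the growth axis through
    the assembly centroid, (ii) the hinge bend to exposed C-termini,
    (iii) Gaussian noise, and (iv) optional fragment rupture.  Frame 0 is
    the unperturbed input up to noise.
    """
    pert.validate()
    if pert.rupture_threshold is not None and assembly.topology == "pair":
        raise ValidationError(
            "rupture is modelled for single-layer protofilaments only; "
            "unset rupture_threshold for pair topologies")
    base = assembly.coords()
    axis = assembly.growth_axis
    # the twist axis runs through the V24 CA column -- the pivot of the
    # twist-angle dihedral probe -- so the imposed per-monomer rotation is
    # exactly what the dihedral reads back on noise-free ensembles
    v24 = np.array([c.residue(24).atom("CA").coord
                    for c in assembly.all_chains()])
    anchor = v24.mean(axis=0)
    chain_atoms, tail_atoms, pivots, chain_pos = _atom_groups(assembly)
    n_chains_total = len(chain_atoms)
    rng = np.random.default_rng(pert.seed)

    # all stochastic draws made up front in a fixed order
    hinge_frac = rng.uniform(0.0, 1.0, size=(pert.n_frames, n_chains_total))
    hinge_sign = rng.choice([-1.0, 1.0], size=n_chains_total)
    noise = (rng.standard_normal((pert.n_frames,) + base.shape)
             * pert.noise_sigma if pert.noise_sigma > 0
             else np.zeros((pert.n_frames,) + base.shape))

    single_layer = assembly.topology == "protofilament"
    n_in_layer = len(assembly.layers[0])
    frames = np.empty((pert.n_frames,) + base.shape)
    for k in range(pert.n_frames):
        f = 1.0 if pert.n_frames == 1 else k / (pert.n_frames - 1)
        coords = base.copy()
        twist_now = pert.twist_per_monomer * f
        for ci in range(n_chains_total):
            sel = chain_atoms[ci]
            # hinge bend first, in the untwisted frame of the chain
            if single_layer and pert.hinge_bend != 0.0:
                ang = pert.hinge_bend * f * hinge_frac[k, ci] * hinge_sign[ci]
                if ang != 0.0 and len(tail_atoms[ci]):
                    rot_h = Rotation.from_rotvec(np.deg2rad(ang) * axis)
                    tl = tail_atoms[ci]
                    coords[tl] = rot_h.apply(coords[tl] - pivots[ci]) \
                        + pivots[ci]
            if twist_now != 0.0:
                ang_t = chain_pos[ci] * twist_now
                rot_t = Rotation.from_rotvec(np.deg2rad(ang_t) * axis)
                coords[sel] = rot_t.apply(coords[sel] - anchor) + anchor
        if (pert.rupture_threshold is not None
                and twist_now > pert.rupture_threshold):
            gap = 8.0  # A, fragment separation introduced at the break
            for ci in range(n_chains_total):
                if chain_pos[ci] >= n_in_layer // 2:
                    coords[chain_atoms[ci]] += gap * axis
        frames[k] = coords + noise[k]

    times = pert.frame_dt * np.arange(pert.n_frames)
    if pert.n_frames == 1:
        times = np.array([0.0])
    return Ensemble(template=assembly.copy(), coords=frames, times=times)


def write_provenance(pert: PerturbationParams, path: str | os.PathLike,
                     extra: Optional[dict] = None) -> None:
    """Echo generation parameters into a YAML sidecar for provenance."""
    import yaml
    payload = {"perturbation": asdict(pert)}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
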