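"""Domain types for cross-beta amyloid assemblies.

The object model mirrors the physical hierarchy of a fibrillar oligomer:
atoms -> residues -> chains -> one or two stacked layers (an ``Assembly``)
-> an ordered series of frames (an ``Ensemble``) standing in for a
trajectory.

All coordinates are in Angstrom, energies in kcal/mol, angles in degrees.
Residue numbering follows the Abeta(1-42) convention: the modelled chain
covers residues 9-42, preceded by an N-terminal acetyl cap stored as
residue 8.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: One-letter sequence of the modelled Abeta(9-42) chain.
CORE_SEQUENCE = "GYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Residue index of the first amino acid (G9) and the last (A42).
FIRST_RESIDUE = 9
LAST_RESIDUE = 42

#: Residue index assigned to the N-terminal acetyl cap.
ACE_INDEX = 8
ACE_CODE = "ACE"

#: Residues whose chains carry a hydrophobic side-chain pseudo-atom (SCT),
#: with the pseudo-atom's distance from CA in Angstrom.  The four C-terminal
#: entries (I31, M35, V39, I41) form the CC-interface of protofilament pairs.
SIDECHAIN_TIP_LENGTH = {
    17: 2.6,  # L17, hydrophobic core
    19: 2.9,  # F19, hydrophobic core
    31: 2.7,  # I31
    34: 2.6,  # L34
    35: 3.2,  # M35
    36: 2.0,  # V36
    39: 2.0,  # V39
    40: 2.0,  # V40
    41: 2.7,  # I41
}

#: CC-interface key residues (Sato register).
INTERFACE_RESIDUES = (31, 35, 39, 41)

#: Formal charge per residue type at pH 7, histidine neutral (the only
#: assignment consistent with the published per-system charges, which are
#: uniformly -2 per monomer).
RESIDUE_FORMAL_CHARGE = {"D": -1, "E": -1, "K": +1}

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class ValidationError(ValueError):
    """A structure violates a model invariant."""


class ConstructionError(RuntimeError):
    """A geometric construction could not satisfy its contract."""


def one_letter(seq_index: int) -> str:
    """One-letter code of the modelled sequence at an Abeta seq index."""
    if seq_index == ACE_INDEX:
        return ACE_CODE
    if not FIRST_RESIDUE <= seq_index <= LAST_RESIDUE:
        raise ValidationError(f"seq_index {seq_index} outside [8, 42]")
    return CORE_SEQUENCE[seq_index - FIRST_RESIDUE]


@dataclass
class AtomRecord:
    """One typed atom.

    ``partial_charge`` (e), ``lj_params`` (sigma Angstrom, epsilon kcal/mol)
    and ``radius`` (intrinsic Born/SASA radius, Angstrom) are assigned by the
    energetics parameter stage and are optional until then.
    """

    name: str
    element: str
    coord: np.ndarray
    partial_charge: Optional[float] = None
    lj_params: Optional[tuple[float, float]] = None
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValidationError(
                f"atom {self.name}: coord must be a finite 3-vector")
        if self.radius is not None and self.radius <= 0:
            raise ValidationError(f"atom {self.name}: radius must be > 0")


@dataclass
class ResidueRecord:
    """One residue unit: an amino acid of Abeta(9-42) or the acetyl cap."""

    aa_code: str
    seq_index: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not ACE_INDEX <= self.seq_index <= LAST_RESIDUE:
            raise ValidationError(
                f"residue seq_index {self.seq_index} outside [8, 42]")

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"residue {self.aa_code}{self.seq_index} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class ChainModel:
    """One acetyl-capped Abeta(9-42) chain (35 residue units)."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def residue(self, seq_index: int) -> ResidueRecord:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {seq_index}")

    @property
    def sequence(self) -> str:
        return "".join(
            r.aa_code for r in self.residues if r.seq_index != ACE_INDEX)


def chain_residue_count(chain: ChainModel) -> int:
    """Number of residue units in a chain, counting the acetyl cap."""
    return len(chain.residues)


def validate_chain(chain: ChainModel) -> None:
    """Enforce the ChainModel invariants.

    The chain must be the acetyl cap followed by Abeta residues 9-42, every
    amino acid must carry at least the N/CA/C/O backbone, D23 must carry
    OD1/OD2 and K28 must carry NZ.
    """
    expected = [ACE_INDEX] + list(range(FIRST_RESIDUE, LAST_RESIDUE + 1))
    got = [r.seq_index for r in chain.residues]
    if got != expected:
        raise ValidationError(
            f"chain {chain.chain_id}: residue numbering {got[:3]}...{got[-2:]} "
            f"does not match acetyl cap + 9..42")
    missing: list[str] = []
    for r in chain.residues:
        if r.seq_index == ACE_INDEX:
            if r.aa_code != ACE_CODE:
                raise ValidationError(
                    f"chain {chain.chain_id}: residue 8 must be the acetyl cap")
            continue
        want = one_letter(r.seq_index)
        if r.aa_code != want:
            raise ValidationError(
                f"chain {chain.chain_id}: residue {r.seq_index} is "
                f"{r.aa_code}, expected {want}")
        for name in ("N", "CA", "C", "O"):
            if not r.has_atom(name):
                missing.append(f"{chain.chain_id}/{r.aa_code}{r.seq_index}/{name}")
    for res_idx, names in ((23, ("OD1", "OD2")), (28, ("NZ",))):
        res = chain.residue(res_idx)
        for name in names:
            if not res.has_atom(name):
                missing.append(f"{chain.chain_id}/{res.aa_code}{res_idx}/{name}")
    for res_idx in (18, 24):
        if not chain.residue(res_idx).has_atom("CA"):
            missing.append(f"{chain.chain_id}/V{res_idx}/CA")
    if missing:
        raise ValidationError("missing required atoms: " + ", ".join(missing))


@dataclass
class Assembly:
    """One or two stacked layers of chains.

    ``layers`` are ordered lists of chains; within a layer the order is the
    stacking order along ``growth_axis``.  ``topology`` is ``protofilament``
    (one layer) or ``pair`` (two layers associated through the C-terminal
    interface).
    """

    layers: list[list[ChainModel]]
    topology: str = "protofilament"
    growth_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.growth_axis = np.asarray(self.growth_axis, dtype=float)
        n = np.linalg.norm(self.growth_axis)
        if n > 0:
            self.growth_axis = self.growth_axis / n

    # -- structure access -------------------------------------------------

    def all_chains(self) -> list[ChainModel]:
        return [c for layer in self.layers for c in layer]

    @property
    def n_chains(self) -> int:
        return sum(len(layer) for layer in self.layers)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.all_chains():
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def iter_atoms(self) -> Iterator[tuple[int, ChainModel, ResidueRecord, AtomRecord]]:
        """Yield (layer_index, chain, residue, atom) in canonical order."""
        for li, layer in enumerate(self.layers):
            for c in layer:
                for r in c.residues:
                    for a in r.atoms:
                        yield li, c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    # -- coordinate block access ------------------------------------------

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, canonical order."""
        return np.array([a.coord for *_, a in self.iter_atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = [a for *_, a in self.iter_atoms()]
        if coords.shape != (len(atoms), 3):
            raise ValidationError(
                f"coordinate block shape {coords.shape} != ({len(atoms)}, 3)")
        for atom, xyz in zip(atoms, coords):
            atom.coord = xyz.copy()

    def copy(self) -> "Assembly":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        if self.topology not in ("protofilament", "pair"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if self.topology == "pair":
            if len(self.layers) != 2:
                raise ValidationError("pair topology requires exactly 2 layers")
            if len(self.layers[0]) != len(self.layers[1]):
                raise ValidationError(
                    "both layers of a pair must have equal chain counts")
        elif len(self.layers) != 1:
            raise ValidationError("protofilament topology requires 1 layer")
        if not self.all_chains():
            raise ValidationError("assembly has no chains")
        for c in self.all_chains():
            validate_chain(c)


@dataclass
class Ensemble:
    """An ordered series of Assembly frames emulating a trajectory.

    Frames are stored as a dense coordinate block over a structural
    template, which keeps synthetic trajectories of large oligomers cheap;
    ``frame(k)`` materialises a full Assembly on demand.  ``times`` are in
    ps and strictly increasing.
    """

    template: Assembly
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValidationError("times length must equal frame count")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, k: int) -> Assembly:
        asm = self.template.copy()
        asm.set_coords(self.coords[k])
        return asm

    @property
    def frames(self) -> list[Assembly]:
        return [self.frame(k) for k in range(self.n_frames)]

    @classmethod
    def from_frames(cls, frames: Sequence[Assembly],
                    times: Optional[Sequence[float]] = None) -> "Ensemble":
        if not frames:
            raise ValidationError("an ensemble needs at least one frame")
        if times is None:
            times = np.arange(len(frames), dtype=float)
        block = np.stack([f.coords() for f in frames])
        return cls(template=frames[0].copy(), coords=block,
                   times=np.asarray(times, dtype=float))

    def trailing_window(self, window_ps: float) -> np.ndarray:
        """Boolean mask of frames inside the trailing time window."""
        if window_ps <= 0:
            raise ValidationError("window_ps must be positive")
        t_end = self.times[-1]
        mask = self.times > t_end - window_ps
        if not mask.any():
            raise ValidationError("trailing window contains no frames")
        return mask


def formal_charge(assembly: Assembly) -> int:
    """Total formal charge (e) of an assembly at pH 7.

    Asp/Glu contribute -1, Lys +1, His is neutral, the acetylated N-terminus
    is neutral and each free C-terminal carboxylate contributes -1; the
    modelled chain therefore carries -2, and every assembly of n chains
    carries -2n, matching the published per-system charges.
    """
    total = 0
    for chain in assembly.all_chains():
        for res in chain.residues:
            if res.seq_index == ACE_INDEX:
                continue
            if res.aa_code not in ONE_TO_THREE:
                raise ValidationError(
                    f"non-standard residue {res.aa_code!r} at {res.seq_index}")
            total += RESIDUE_FORMAL_CHARGE.get(res.aa_code, 0)
        if chain.residues:
            total -= 1  # free C-terminal carboxylate
    return total


def snapshot_count(total_ns: float = 50.0, interval_ps: float = 5.0) -> int:
    """Number of saved snapshots for a run of ``total_ns`` at a fixed
    saving interval: 50 ns at 5 ps yields 10,000 per system."""
    return int(round(total_ns * 1000.0 / interval_ps))
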