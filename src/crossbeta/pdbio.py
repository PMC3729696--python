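"""PDB reading and writing for assemblies and ensembles.

Parsing and formatting are delegated to Biopython; this module only maps
between ``Bio.PDB`` entities and the typed domain model.  One PDB chain ID
per chain, residue numbers equal the Abeta seq index (acetyl cap = 8),
ensembles are written as multi-MODEL files.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser, StructureBuilder

from .model import (
    ACE_CODE,
    ACE_INDEX,
    Assembly,
    AtomRecord,
    ChainModel,
    Ensemble,
    ONE_TO_THREE,
    ResidueRecord,
    THREE_TO_ONE,
    ValidationError,
    validate_chain,
)


class PdbFormatError(ValueError):
    """The file is not parseable as PDB or contains unknown residues."""


_ELEMENT_GUESS = {"C": "C", "N": "N", "O": "O", "H": "H", "S": "S"}


def _guess_element(atom_name: str, parsed: str) -> str:
    if parsed and parsed.strip():
        return parsed.strip()
    return _ELEMENT_GUESS.get(atom_name.strip()[0], "C")


def _chain_from_biopdb(bio_chain) -> ChainModel:
    residues: list[ResidueRecord] = []
    for res in bio_chain.get_residues():
        resname = res.get_resname().strip()
        seq_index = res.get_id()[1]
        if resname == ACE_CODE:
            aa = ACE_CODE
        elif resname in THREE_TO_ONE:
            aa = THREE_TO_ONE[resname]
        else:
            raise PdbFormatError(
                f"unknown residue {resname!r} at {bio_chain.id}/{seq_index}")
        atoms = [AtomRecord(name=a.get_name().strip(),
                            element=_guess_element(a.get_name(), a.element),
                            coord=np.array(a.get_coord(), dtype=float))
                 for a in res.get_atoms()]
        residues.append(ResidueRecord(aa_code=aa, seq_index=seq_index,
                                      atoms=atoms))
    return ChainModel(chain_id=bio_chain.id, residues=residues)


def _assembly_from_model(model, layer_map: Optional[Mapping[str, int]]
                         ) -> Assembly:
    chains = [_chain_from_biopdb(c) for c in model.get_chains()]
    if not chains:
        raise PdbFormatError("file contains no chains")
    if layer_map is None:
        layers = [chains]
    else:
        n_layers = max(layer_map.values()) + 1
        layers = [[] for _ in range(n_layers)]
        for c in chains:
            if c.chain_id not in layer_map:
                raise ValidationError(
                    f"layer map does not cover chain {c.chain_id!r}")
            layers[layer_map[c.chain_id]].append(c)
        layers = [l for l in layers if l]
    topology = "pair" if len(layers) == 2 else "protofilament"
    axis = np.array([0.0, 0.0, 1.0])
    if len(layers[0]) >= 2:
        try:
            d = (layers[0][1].residue(18).atom("CA").coord
                 - layers[0][0].residue(18).atom("CA").coord)
            if np.linalg.norm(d) > 0:
                axis = d / np.linalg.norm(d)
        except KeyError:
            pass
    asm = Assembly(layers=layers, topology=topology, growth_axis=axis)
    for c in asm.all_chains():
        validate_chain(c)
    return asm


def read_pdb(path: str | os.PathLike,
             layer_map: Optional[Mapping[str, int]] = None) -> Assembly:
    """Read an assembly from a PDB file.

    ``layer_map`` assigns chain IDs to layer indices (0/1); by default all
    chains form a single protofilament layer.  Unknown residues are
    rejected; chains missing required atoms (backbone, CA of V18/V24,
    OD1/OD2 of D23, NZ of K28) raise a validation error naming them.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("asm", os.fspath(path))
    except Exception as exc:
        raise PdbFormatError(f"cannot parse {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise PdbFormatError(f"{path} contains no models")
    return _assembly_from_model(models[0], layer_map)


def read_ensemble(path: str | os.PathLike,
                  layer_map: Optional[Mapping[str, int]] = None,
                  frame_dt_ps: float = 1.0) -> Ensemble:
    """Read a multi-MODEL PDB as an ensemble (frame times k * frame_dt_ps)."""
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ens", os.fspath(path))
    except Exception as exc:
        raise PdbFormatError(f"cannot parse {path}: {exc}") from exc
    frames = [_assembly_from_model(m, layer_map)
              for m in structure.get_models()]
    if not frames:
        raise PdbFormatError(f"{path} contains no models")
    times = frame_dt_ps * np.arange(len(frames))
    return Ensemble.from_frames(frames, times=times)


def _resname(res: ResidueRecord) -> str:
    return ACE_CODE if res.seq_index == ACE_INDEX else ONE_TO_THREE[res.aa_code]


def _build_structure(frames: Sequence[Assembly]):
    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("asm")
    serial = 1
    for mi, asm in enumerate(frames):
        sb.init_model(mi)
        for chain in asm.all_chains():
            sb.init_chain(chain.chain_id)
            sb.init_seg("    ")
            for res in chain.residues:
                sb.init_residue(_resname(res), " ", res.seq_index, " ")
                for atom in res.atoms:
                    name = atom.name
                    fullname = name if len(name) == 4 else f" {name:<3}"
                    sb.init_atom(name, np.asarray(atom.coord, float),
                                 0.0, 1.0, " ", fullname,
                                 serial_number=serial,
                                 element=atom.element)
                    serial += 1
    return sb.get_structure()


def write_pdb(assembly: Assembly, path: str | os.PathLike) -> None:
    """Write an assembly as a standard single-model PDB file."""
    if not assembly.all_chains():
        raise ValidationError("refusing to write an assembly with no chains")
    io = PDBIO()
    io.set_structure(_build_structure([assembly]))
    io.save(os.fspath(path))


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-MODEL PDB file."""
    io = PDBIO()
    io.set_structure(_build_structure(ensemble.frames))
    io.save(os.fspath(path))
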