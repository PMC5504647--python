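"""Minimal PDB input/output for receptor-ligand complexes.

Reading follows the convention that ``ATOM`` records are the receptor and
``HETATM`` records the ligand (waters are ignored); a multi-model file of
ligand ``HETATM`` records is read as a discrete conformer library. Parsing is
delegated to Biopython; writing emits standard fixed-width records with
coordinates to 3 decimals, multiple poses as MODEL/ENDMDL blocks.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .structure import (
    BACKBONE_ATOM_NAMES,
    ROLE_BACKBONE,
    ROLE_LIGAND,
    ROLE_SIDECHAIN,
    AtomRecord,
    ConformerSet,
    Pose,
    Receptor,
)

__all__ = ["read_pdb", "read_conformers", "load_pose", "write_pdb"]

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


def _parse(path):
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            return parser.get_structure("complex", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc


def _atom_record(atom, residue) -> AtomRecord:
    hetflag = residue.id[0]
    element = (atom.element or "").strip() or atom.get_name()[0]
    is_ligand = hetflag.strip() not in ("", "W")
    if is_ligand:
        role = ROLE_LIGAND
    elif atom.get_name() in BACKBONE_ATOM_NAMES:
        role = ROLE_BACKBONE
    else:
        role = ROLE_SIDECHAIN
    return AtomRecord(
        element=element,
        coords=np.asarray(atom.coord, dtype=float),
        is_hydrogen=element.upper() == "H",
        role=role,
        name=atom.get_name(),
    )


def _model_atoms(model) -> tuple[list[AtomRecord], list[AtomRecord]]:
    receptor: list[AtomRecord] = []
    ligand: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip() in _WATER_RESNAMES:
                continue
            for atom in residue:
                rec = _atom_record(atom, residue)
                (ligand if rec.role == ROLE_LIGAND else receptor).append(rec)
    return receptor, ligand


def read_pdb(path) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Read a complex: ATOM records as receptor, HETATM (minus waters) as ligand."""
    structure = _parse(path)
    model = next(iter(structure))
    receptor, ligand = _model_atoms(model)
    if not ligand:
        raise ValueError(f"{path}: no HETATM ligand records found")
    return receptor, ligand


def read_conformers(path) -> ConformerSet:
    """Read a multi-model ligand PDB as a discrete conformer library."""
    structure = _parse(path)
    coord_sets = []
    template: list[AtomRecord] | None = None
    for model in structure:
        _, ligand = _model_atoms(model)
        if not ligand:
            raise ValueError(f"{path}: model without HETATM ligand records")
        if template is None:
            template = ligand
        elif len(ligand) != len(template) or any(
            a.element != b.element for a, b in zip(ligand, template)
        ):
            raise ValueError(f"{path}: conformers disagree in atom identity/order")
        coord_sets.append([a.coords for a in ligand])
    assert template is not None
    return ConformerSet(
        coords=np.array(coord_sets),
        elements=[a.element for a in template],
        names=[a.name for a in template],
        is_hydrogen=[a.is_hydrogen for a in template],
    )


def load_pose(path, conformers_path=None) -> Pose:
    """Build a sampling pose from a complex PDB (+ optional conformer library)."""
    receptor_atoms, ligand_atoms = read_pdb(path)
    receptor = Receptor.from_atom_records(receptor_atoms)
    if conformers_path is not None:
        conformers = read_conformers(conformers_path)
    else:
        conformers = ConformerSet(
            coords=np.array([[a.coords for a in ligand_atoms]]),
            elements=[a.element for a in ligand_atoms],
            names=[a.name for a in ligand_atoms],
            is_hydrogen=[a.is_hydrogen for a in ligand_atoms],
        )
    return Pose(receptor=receptor, conformers=conformers)


def _format_atom(
    serial: int, record: str, name: str, resname: str, chain: str, resseq: int,
    xyz: np.ndarray, element: str,
) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record:<6s}{serial:>5d} {name_field} {resname:<3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element.upper():>2s}\n"
    )


def _pose_lines(pose: Pose, ligand_only: bool) -> list[str]:
    lines: list[str] = []
    serial = 0
    if not ligand_only:
        rec = pose.receptor
        resseq = 0
        for i in range(len(rec)):
            name = str(rec.names[i]) or "X"
            if name == "N" or i == 0:
                resseq += 1
            serial += 1
            lines.append(
                _format_atom(serial, "ATOM", name, "ALA", "A", resseq,
                             rec.coords[i], str(rec.elements[i]))
            )
    coords = pose.ligand_coords()
    cs = pose.conformers
    for i in range(cs.n_atoms):
        serial += 1
        lines.append(
            _format_atom(serial, "HETATM", str(cs.names[i]) or f"L{i + 1}", "LIG", "X", 1,
                         coords[i], str(cs.elements[i]))
        )
    return lines


def write_pdb(poses: Pose | Sequence[Pose], path, ligand_only: bool = False) -> None:
    """Write pose(s) as PDB; several poses become MODEL/ENDMDL blocks."""
    single = isinstance(poses, Pose)
    pose_list = [poses] if single else list(poses)
    if not pose_list:
        raise ValueError("no poses to write")
    path = Path(path)
    with open(path, "w") as fh:
        if len(pose_list) == 1:
            fh.writelines(_pose_lines(pose_list[0], ligand_only))
        else:
            for i, pose in enumerate(pose_list, start=1):
                fh.write(f"MODEL {i:>8d}\n")
                fh.writelines(_pose_lines(pose, ligand_only))
                fh.write("ENDMDL\n")
        fh.write("END\n")
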