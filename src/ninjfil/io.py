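"""Reading and writing structural models and result sidecars.

mmCIF and PDB handling is delegated to biotite; this module maps between
atom arrays and the package's protomer/assembly types, partitions the
chains of a deposited model into filaments (a deposited double filament is
two filaments in one file), and round-trips screw parameters as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import numpy as np
from biotite.sequence import ProteinSequence
from biotite.structure.io import pdb as pdb_io
from biotite.structure.io import pdbx as pdbx_io

from .assembly import (
    AssemblyModel,
    NINJ1_HELIX_RANGES,
    ProtomerModel,
    ScrewSymmetry,
    _kabsch,
    estimate_screw,
)
from .errors import InvalidModelError


def read_atoms(path) -> struc.AtomArray:
    """Read the first model of a PDB or mmCIF file (heavy atoms only)."""
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
        cif = pdbx_io.CIFFile.read(str(path))
        atoms = pdbx_io.get_structure(cif, model=1)
    elif path.suffix.lower() in {".pdb", ".ent"}:
        atoms = pdb_io.PDBFile.read(str(path)).get_structure(model=1)
    else:
        raise InvalidModelError(f"unrecognised structure format: {path.suffix!r}")
    atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.element != "H"]
    return atoms


def write_atoms(atoms: struc.AtomArray, path) -> None:
    """Write an atom array as mmCIF (default) or PDB, by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        if max(len(str(c)) for c in np.unique(atoms.chain_id)) > 1:
            raise InvalidModelError(
                "PDB format supports single-character chain ids; write mmCIF instead"
            )
        f = pdb_io.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))
    else:
        cif = pdbx_io.CIFFile()
        pdbx_io.set_structure(cif, atoms, data_block="ninjfil")
        cif.write(str(path))


def _chain_sequence(atoms: struc.AtomArray) -> str:
    mask = atoms.atom_name == "CA"
    letters = []
    for name in atoms.res_name[mask]:
        try:
            letters.append(ProteinSequence.convert_letter_3to1(str(name)))
        except Exception:
            letters.append("X")
    return "".join(letters)


def protomer_from_atoms(
    atoms: struc.AtomArray, chain_id: str | None = None, helix_ranges: dict | None = None
) -> ProtomerModel:
    """Build a ProtomerModel from one chain of an atom array."""
    chains = np.unique(atoms.chain_id)
    if chain_id is None:
        if len(chains) != 1:
            raise InvalidModelError(
                f"file contains chains {list(chains)}; specify one with chain_id"
            )
        chain_id = chains[0]
    sel = atoms[atoms.chain_id == chain_id]
    if sel.array_length() == 0:
        raise InvalidModelError(f"no atoms in chain {chain_id!r}")
    return ProtomerModel(
        atoms=sel,
        sequence=_chain_sequence(sel),
        helix_ranges=dict(helix_ranges) if helix_ranges else dict(NINJ1_HELIX_RANGES),
    )


def read_protomer(path, chain_id: str | None = None, helix_ranges=None) -> ProtomerModel:
    return protomer_from_atoms(read_atoms(path), chain_id, helix_ranges)


def assembly_from_atoms(atoms: struc.AtomArray, topology: str = "linear") -> AssemblyModel:
    """Treat each chain (in order of appearance) as one subunit."""
    chain_ids = list(dict.fromkeys(atoms.chain_id.tolist()))
    if not chain_ids:
        raise InvalidModelError("structure has no chains")
    parts = [atoms[atoms.chain_id == c] for c in chain_ids]
    merged = parts[0]
    for p in parts[1:]:
        merged = merged + p
    bounds = np.cumsum([0] + [p.array_length() for p in parts]).tolist()
    return AssemblyModel(
        atoms=merged,
        chain_ids=chain_ids,
        topology=topology,
        symmetry=None,
        bounds=bounds,
    )


def read_assembly(path, topology: str = "linear") -> AssemblyModel:
    return assembly_from_atoms(read_atoms(path), topology=topology)


def write_assembly(assembly: AssemblyModel, path) -> None:
    write_atoms(assembly.atoms, path)


def split_filaments(assembly: AssemblyModel, rise_tol: float = 0.10) -> list:
    """Partition chains into filaments by consecutive-pair screw consistency.

    Chains are scanned in file order; a chain extends the current filament
    while the Kabsch fit against the previous chain yields a rise within
    ``rise_tol`` (relative) of the running filament rise, otherwise a new
    filament starts. A deposited antiparallel double filament splits into
    its two filaments this way.
    """
    from .assembly import _decompose_screw

    groups: list[list[int]] = [[0]]
    group_rise: list[float | None] = [None]
    for i in range(1, assembly.n_subunits):
        from .assembly import _matched_ca_pair

        a, b = _matched_ca_pair(assembly, i - 1, i)
        ok = False
        if len(a) >= 3:
            rot, t = _kabsch(a, b)
            try:
                rise, _, _, _ = _decompose_screw(rot, t)
                ref = group_rise[-1]
                ok = ref is None or abs(rise - ref) <= rise_tol * ref
            except Exception:
                ok = False
        if ok:
            groups[-1].append(i)
            group_rise[-1] = rise if group_rise[-1] is None else group_rise[-1]
        else:
            groups.append([i])
            group_rise.append(None)

    out = []
    for idx_group in groups:
        parts = [assembly.subunit(i) for i in idx_group]
        merged = parts[0]
        for p in parts[1:]:
            merged = merged + p
        bounds = np.cumsum([0] + [p.array_length() for p in parts]).tolist()
        sub = AssemblyModel(
            atoms=merged,
            chain_ids=[assembly.chain_ids[i] for i in idx_group],
            topology="linear",
            symmetry=None,
            bounds=bounds,
        )
        if sub.n_subunits >= 2:
            try:
                sub.symmetry = estimate_screw(sub, allow_partial=True)
            except Exception:
                pass
        out.append(sub)
    return out


def save_screw(sym: ScrewSymmetry, path) -> None:
    with open(path, "w") as fh:
        json.dump(sym.to_dict(), fh, indent=2)


def load_screw(path) -> ScrewSymmetry:
    with open(path) as fh:
        return ScrewSymmetry.from_dict(json.load(fh))
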