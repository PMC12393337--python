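"""Crystal-structure observables: nearest donors and ring-to-ring distances.

Crystal structures generally lack hydrogens, so this module reports
heavy-atom contacts only: nitrogen/oxygen atoms within a cutoff of the
nitrile nitrogen (potential hydrogen-bond donors) and centroid-to-centroid
distances between aromatic rings (probe phenyl to chromophore phenol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "SelectionError",
    "RING_ATOM_NAMES",
    "read_structure",
    "structure_from_pdb_text",
    "nearest_donors",
    "ring_to_ring_distance",
]

#: atom names of the six aromatic carbons, shared by phenylalanine-derived
#: probe rings and the hydroxycinnamoyl phenol ring in common nomenclature
RING_ATOM_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


class SelectionError(ValueError):
    """An atom selector matched zero or more than one atom (or missing ring atoms)."""


@dataclass
class StructureModel:
    """Flat atom table of one model: name, residue, chain, element, xyz, occupancy."""

    atoms: pd.DataFrame
    source_id: str = ""

    def select(self, chain: str | None = None, resseq: int | None = None,
               resname: str | None = None, name: str | None = None) -> pd.DataFrame:
        df = self.atoms
        if chain is not None:
            df = df[df["chain"] == chain]
        if resseq is not None:
            df = df[df["resseq"] == resseq]
        if resname is not None:
            df = df[df["resname"] == resname]
        if name is not None:
            df = df[df["name"] == name]
        return df

    def coords(self, df: pd.DataFrame) -> np.ndarray:
        return df[["x", "y", "z"]].to_numpy(float)


def _structure_to_model(st: gemmi.Structure, source_id: str) -> StructureModel:
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for residue in chain:
            # resolve alternate locations: highest occupancy, ties -> first
            # altloc in alphabetical order ('A')
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
                    by_name[atom.name] = atom
            for atom in by_name.values():
                rows.append({
                    "serial": atom.serial,
                    "name": atom.name,
                    "altloc": atom.altloc or "",
                    "resname": residue.name,
                    "chain": chain.name,
                    "resseq": residue.seqid.num,
                    "element": atom.element.name,
                    "x": atom.pos.x, "y": atom.pos.y, "z": atom.pos.z,
                    "occupancy": atom.occ,
                })
    if not rows:
        raise ValueError(f"no atoms parsed from {source_id!r}")
    atoms = pd.DataFrame.from_records(rows)
    if not np.all(np.isfinite(atoms[["x", "y", "z"]].to_numpy())):
        raise ValueError("non-finite coordinates in structure")
    return StructureModel(atoms, source_id)


def read_structure(path: str) -> StructureModel:
    """Parse a PDB (or mmCIF) file into a flat atom table."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path!r}: {exc}") from exc
    return _structure_to_model(st, source_id=str(path))


def structure_from_pdb_text(text: str, source_id: str = "<text>") -> StructureModel:
    """Parse PDB-format text (used for programmatically built structures)."""
    st = gemmi.read_pdb_string(text)
    return _structure_to_model(st, source_id)


def _single_atom(struct: StructureModel, selector: dict) -> pd.Series:
    hits = struct.select(**selector)
    if len(hits) != 1:
        raise SelectionError(
            f"selector {selector} matched {len(hits)} atoms (need exactly 1)"
        )
    return hits.iloc[0]


def nearest_donors(struct: StructureModel, nitrile_n: dict,
                   cutoff_A: float = 3.5,
                   whitelist: Sequence[str] | None = ("N", "O")) -> pd.DataFrame:
    """Heavy atoms within ``cutoff_A`` of the nitrile nitrogen, nearest first.

    ``nitrile_n`` is a selector dict (chain / resseq / resname / name) that
    must match exactly one atom.  ``whitelist`` restricts the reported
    elements to plausible donors (N, O); pass None to disable.  Atoms of the
    nitrile's own residue are excluded.
    """
    n_atom = _single_atom(struct, nitrile_n)
    n_pos = np.array([n_atom["x"], n_atom["y"], n_atom["z"]])
    df = struct.atoms
    same_residue = (
        (df["chain"] == n_atom["chain"])
        & (df["resseq"] == n_atom["resseq"])
        & (df["resname"] == n_atom["resname"])
    )
    cand = df[~same_residue].copy()
    if whitelist is not None:
        cand = cand[cand["element"].isin(list(whitelist))]
    cand = cand[cand["element"] != "H"]
    d = np.linalg.norm(cand[["x", "y", "z"]].to_numpy(float) - n_pos, axis=1)
    cand = cand.assign(distance_A=d)
    cand = cand[cand["distance_A"] <= cutoff_A].sort_values("distance_A")
    return cand[["name", "resname", "chain", "resseq", "element", "distance_A"]]\
        .reset_index(drop=True)


def _ring_centroid(struct: StructureModel, selector: dict,
                   atom_names: Sequence[str]) -> np.ndarray:
    found = []
    for nm in atom_names:
        hits = struct.select(name=nm, **selector)
        if len(hits) == 1:
            found.append(hits.iloc[0][["x", "y", "z"]].to_numpy(float))
        elif len(hits) > 1:
            raise SelectionError(f"ring atom {nm} ambiguous under {selector}")
    if len(found) < 5:
        raise SelectionError(
            f"only {len(found)} ring atoms of {list(atom_names)} found under {selector}"
        )
    return np.mean(found, axis=0)


def ring_to_ring_distance(struct: StructureModel, ring_a: dict, ring_b: dict,
                          atom_names: Sequence[str] = RING_ATOM_NAMES) -> float:
    """Euclidean distance between the centroids of two aromatic rings (A).

    Each ring selector (chain / resseq / resname) must resolve at least five
    of the named ring atoms.
    """
    ca = _ring_centroid(struct, ring_a, atom_names)
    cb = _ring_centroid(struct, ring_b, atom_names)
    return float(np.linalg.norm(ca - cb))
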