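"""Atomic model: parsing of PDB/mmCIF files, binding-residue dictionary.

The internal model is deliberately small: an ordered list of residues with
plain numpy coordinates, plus a flat list of bound metal het-ions.  Only the
first model of multi-model files is retained; hydrogens are discarded;
alternate locations are resolved to the highest-occupancy conformer (ties go
to altloc 'A').
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyStructureError,
    MissingAtomError,
    NotBindingResidueError,
    ParseError,
)

#: residue type -> side-chain atoms that may coordinate a zinc ion
BINDING_ATOMS: dict[str, tuple[str, ...]] = {
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: het-ion element symbols recognised as bound metals
METAL_ELEMENTS = {
    "ZN", "CO", "CU", "FE", "MN", "NI", "CA", "MG", "NA", "K", "CD",
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ParseError(f"non-finite coordinate for atom {self.name}")


@dataclass
class Residue:
    chain: str
    seq_id: int
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_id, self.insertion_code)

    @property
    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain}:{self.res_type}:{self.seq_id}{icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require_atom(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            raise MissingAtomError(f"{self.label} is missing atom {name}")
        return a


@dataclass
class HetIon:
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class ProteinStructure:
    structure_id: str
    residues: list[Residue] = field(default_factory=list)
    het_ions: list[HetIon] = field(default_factory=list)

    def residue_by_key(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    @property
    def n_residues(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _looks_like_mmcif(text: str) -> bool:
    head = text[:4000]
    return head.lstrip().startswith("data_") or "_atom_site." in head


def _resolve_format(source, fmt: str) -> tuple[str, str]:
    """Return (format, text) for a path-or-text source."""
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise ParseError(f"file not found: {path}")
        text = path.read_text()
        if fmt == "auto":
            suffix = path.suffix.lower()
            if suffix in {".cif", ".mmcif"}:
                fmt = "mmcif"
            elif suffix in {".pdb", ".ent"}:
                fmt = "pdb"
            else:
                fmt = "mmcif" if _looks_like_mmcif(text) else "pdb"
        return fmt, text
    text = str(source)
    if fmt == "auto":
        fmt = "mmcif" if _looks_like_mmcif(text) else "pdb"
    return fmt, text


def _pick_altloc(children: Iterable) -> "object":
    # highest occupancy wins; ties broken toward altloc 'A'
    def sort_key(atom):
        occ = atom.get_occupancy()
        occ = 1.0 if occ is None else occ
        return (-occ, atom.get_altloc())

    return sorted(children, key=sort_key)[0]


def parse_structure(source, format: str = "auto", structure_id: str | None = None) -> ProteinStructure:
    """Parse a PDB or mmCIF file (path or raw text) into a ProteinStructure.

    Altloc conflicts resolve to the highest-occupancy conformer (ties to
    label 'A'); hydrogens are dropped; missing occupancies default to 1.0;
    metal het-atoms are collected into ``het_ions``.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    fmt, text = _resolve_format(source, format)
    if structure_id is None:
        if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
            structure_id = Path(source).stem
        else:
            structure_id = "structure"

    handle = io.StringIO(text)
    try:
        if fmt == "pdb":
            parser = PDBParser(QUIET=True, PERMISSIVE=True)
        elif fmt == "mmcif":
            parser = MMCIFParser(QUIET=True)
        else:
            raise ParseError(f"unknown format {fmt!r}")
        bio_structure = parser.get_structure(structure_id, handle)
    except ParseError:
        raise
    except Exception as exc:  # Bio.PDB raises many concrete types
        raise ParseError(f"could not parse {structure_id}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise EmptyStructureError(f"{structure_id}: no models found")
    model = models[0]  # first model only

    structure = ProteinStructure(structure_id=structure_id)
    for chain in model:
        for bio_res in chain:
            hetflag, seq_id, icode = bio_res.id
            icode = icode.strip()
            resname = bio_res.get_resname().strip().upper()
            atoms: list[Atom] = []
            for bio_atom in bio_res.child_list:
                if bio_atom.is_disordered():
                    bio_atom = _pick_altloc(bio_atom.child_dict.values())
                element = (bio_atom.element or "").strip().upper()
                if element in {"H", "D"}:
                    continue
                occ = bio_atom.get_occupancy()
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        element=element,
                        coord=np.array(bio_atom.get_coord(), dtype=float),
                        occupancy=1.0 if occ is None else float(occ),
                        altloc=(bio_atom.get_altloc() or "").strip(),
                        bfactor=float(bio_atom.get_bfactor() or 0.0),
                    )
                )
            if hetflag.strip():
                for atom in atoms:
                    if atom.element in METAL_ELEMENTS:
                        structure.het_ions.append(
                            HetIon(atom.element, atom.coord, atom.occupancy)
                        )
                continue
            if resname not in _STANDARD_AA:
                continue  # nonstandard residues excluded
            if atoms:
                structure.residues.append(
                    Residue(chain.id, int(seq_id), resname, atoms, icode)
                )

    if not structure.residues and not structure.het_ions:
        raise EmptyStructureError(f"{structure_id}: structure is empty")
    return structure


# ---------------------------------------------------------------------------
# binding residues
# ---------------------------------------------------------------------------

def binding_point(residue: Residue) -> np.ndarray:
    """Coordinate used to represent the residue's metal-binding locus.

    Single listed atom -> its coordinate; two listed atoms present -> their
    midpoint; one of two present -> that atom (degenerate fallback).
    """
    names = BINDING_ATOMS.get(residue.res_type)
    if names is None:
        raise NotBindingResidueError(
            f"{residue.label} is not a metal-binding residue type"
        )
    coords = [residue.atom(n).coord for n in names if residue.atom(n) is not None]
    if not coords:
        raise MissingAtomError(
            f"{residue.label}: none of {names} present"
        )
    return np.mean(coords, axis=0)


def extract_binding_residues(structure: ProteinStructure) -> list[Residue]:
    """Residues (all chains) whose type can coordinate zinc and whose
    binding point is computable."""
    out = []
    for res in structure.residues:
        if res.res_type not in BINDING_ATOMS:
            continue
        try:
            binding_point(res)
        except MissingAtomError:
            continue
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# writing (fixtures / round-trips)
# ---------------------------------------------------------------------------

_ION_RESNAME = {"ZN": "ZN", "CA": "CA", "MG": "MG", "NA": "NA", "K": "K",
                "FE": "FE", "CO": "CO", "CU": "CU", "MN": "MN", "NI": "NI",
                "CD": "CD"}


def write_pdb(structure: ProteinStructure, path, remarks: Sequence[str] = ()) -> None:
    """Write the model as a minimal PDB file (fixtures, round-trip tests)."""
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 999 {remark}")
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            name = atom.name
            # column-13 convention: 4-char names start at col 13, else col 14
            padded = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                "ATOM  {serial:5d} {name:4s}{alt:1s}{res:>3s} {chain:1s}"
                "{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{bf:6.2f}          {el:>2s}".format(
                    serial=serial, name=padded, alt=atom.altloc[:1] or " ",
                    res=res.res_type, chain=res.chain[:1], seq=res.seq_id,
                    icode=res.insertion_code[:1] or " ",
                    x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                    occ=atom.occupancy, bf=atom.bfactor, el=atom.element,
                )
            )
            serial += 1
    hetseq = 900
    for ion in structure.het_ions:
        resname = _ION_RESNAME.get(ion.element, ion.element)[:3]
        lines.append(
            "HETATM{serial:5d} {name:4s} {res:>3s} {chain:1s}{seq:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          {el:>2s}".format(
                serial=serial, name=f"{ion.element:<4s}"[:4], res=resname,
                chain="Z", seq=hetseq,
                x=ion.coord[0], y=ion.coord[1], z=ion.coord[2],
                occ=ion.occupancy, bf=0.0, el=ion.element,
            )
        )
        serial += 1
        hetseq += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def fetch_structure(entry_id: str, source: str = "pdb", dest_dir=".") -> Path:
    """Convenience fetcher for PDB / AlphaFold DB entries (network access).

    Never used by the test suite; provided for interactive use only.
    """
    import urllib.request

    entry_id = entry_id.strip()
    if source == "pdb":
        url = f"https://files.rcsb.org/download/{entry_id.upper()}.cif"
        name = f"{entry_id.upper()}.cif"
    elif source == "afdb":
        url = f"https://alphafold.ebi.ac.uk/files/AF-{entry_id}-F1-model_v4.cif"
        name = f"AF-{entry_id}-F1-model_v4.cif"
    else:
        raise ValueError(f"unknown source {source!r}")
    dest = Path(dest_dir) / name
    urllib.request.urlretrieve(url, dest)
    return dest
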