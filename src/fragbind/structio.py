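"""Structure input/output.

Reads protein–ligand complexes from PDB files (via gemmi) into a flat,
uniform atom model, partitions atoms into protein / ligand / water / other,
and writes PDB files, tab-separated interaction tables and a minimal PyMOL
command script.

Conventions: author residue numbering with insertion codes, single model
(first by default), one altloc kept per atom (highest occupancy, ties broken
toward altloc 'A').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "ParseError",
    "read_complex",
    "write_complex",
    "write_pymol_script",
    "hbond_table",
    "write_hbond_table",
    "COFACTOR_CLASSES",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O"}

# Residue names of common adenine-bearing cofactors and close analogs,
# grouped by cofactor class.  Used to tag fragment instances; a ligand not
# listed here is classified "other".
COFACTOR_CLASSES: dict[str, str] = {
    "ATP": "ATP", "ADP": "ATP", "AMP": "ATP", "ANP": "ATP", "AGS": "ATP",
    "ACP": "ATP", "APC": "ATP", "ADN": "ATP", "A": "ATP",
    "NAD": "NAD", "NAI": "NAD", "NAP": "NAD", "NDP": "NAD",
    "FAD": "FAD", "FDA": "FAD", "FMN": "FAD",
    "SAM": "SAM", "SAH": "SAM", "SFG": "SAM",
    "COA": "CoA", "ACO": "CoA", "SCA": "CoA", "MCA": "CoA",
}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class AtomRecord:
    """One atom of a parsed complex (author numbering, Å coordinates)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coords: np.ndarray
    occupancy: float
    category: str  # protein | ligand | water | other
    is_backbone: bool

    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code, self.residue_name)


@dataclass
class ComplexStructure:
    """One protein–ligand complex as a flat atom table plus ligand index."""

    id: str
    atoms: list[AtomRecord]
    ligand_instances: list[tuple[str, str, int]] = field(default_factory=list)
    model_number: int = 1

    def __post_init__(self) -> None:
        if not self.ligand_instances:
            seen: list[tuple[str, str, int]] = []
            for a in self.atoms:
                if a.category == "ligand":
                    key = (a.residue_name, a.chain_id, a.residue_seq)
                    if key not in seen:
                        seen.append(key)
            self.ligand_instances = seen
        self._by_serial = {a.serial: a for a in self.atoms}

    def atom(self, serial: int) -> AtomRecord:
        return self._by_serial[serial]

    def atoms_in(self, category: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.category == category]

    def ligand_atoms(self, ligand: tuple[str, str, int]) -> list[AtomRecord]:
        name, chain, seq = ligand
        return [
            a
            for a in self.atoms
            if a.category == "ligand"
            and a.residue_name == name
            and a.chain_id == chain
            and a.residue_seq == seq
        ]


def _category(residue_name: str, is_hetatm: bool) -> str:
    if residue_name in WATER_NAMES:
        return "water"
    if residue_name in AMINO_ACIDS:
        return "protein"
    if is_hetatm:
        return "ligand"
    return "other"


def read_complex(
    path: str | Path,
    altloc_policy: str = "highest_occupancy",
    model_policy: str = "first",
) -> ComplexStructure:
    """Parse a PDB file into a :class:`ComplexStructure`.

    Only the first model is kept (``model_policy="first"``, the sole policy);
    of alternate locations the highest-occupancy copy is kept, ties broken
    toward altloc 'A'.  Hydrogens are retained when present but nothing in the
    pipeline requires them.
    """
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy {model_policy!r}")
    if altloc_policy != "highest_occupancy":
        raise ValueError(f"unsupported altloc_policy {altloc_policy!r}")
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    # group altlocs per (residue, atom name), then select one copy
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                groups.setdefault(atom.name, []).append(atom)
            is_het = res.het_flag == "H"
            cat = _category(res.name, is_het)
            for name in groups:
                atom = _select_altloc(groups[name])
                records.append(
                    AtomRecord(
                        serial=atom.serial,
                        atom_name=name,
                        element=atom.element.name.upper(),
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=chain.name.strip(),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=float(atom.occ),
                        category=cat,
                        is_backbone=(cat == "protein" and name in BACKBONE_NAMES),
                    )
                )
    if not records:
        raise ParseError(f"{path}: zero atoms")
    records.sort(key=lambda a: a.serial)
    return ComplexStructure(id=path.stem, atoms=records, model_number=1)


def _select_altloc(copies: list[gemmi.Atom]) -> gemmi.Atom:
    if len(copies) == 1:
        return copies[0]
    # highest occupancy; ties -> lowest altloc letter ('A' before 'B', and
    # a blank altloc, which should not normally co-occur, sorts first)
    return max(copies, key=lambda a: (a.occ, -(ord(a.altloc or " "))))


_COORD_MIN, _COORD_MAX = -999.999, 9999.999


def write_complex(cs: ComplexStructure, path: str | Path) -> Path:
    """Write a complex as fixed-width PDB.

    The writer emits records directly so that dialect details under test
    (blank chain ids, HETATM for ligands/waters) are under explicit control;
    round-tripping through :func:`read_complex` preserves names, numbering
    and coordinates to the format's 3-decimal precision.
    """
    path = Path(path)
    lines: list[str] = []
    for a in cs.atoms:
        x, y, z = (float(v) for v in a.coords)
        for v in (x, y, z):
            if not (_COORD_MIN <= v <= _COORD_MAX):
                raise ValueError(f"coordinate {v} outside PDB fixed-width range")
        record = "HETATM" if a.category in ("ligand", "water") else "ATOM  "
        name = a.atom_name
        if len(name) < 4 and len(a.element) < 2:
            name = " " + name
        lines.append(
            f"{record}{a.serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{(a.chain_id or ' '):1s}{a.residue_seq:4d}{(a.insertion_code or ' '):1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pymol_script(sites: Sequence, path: str | Path) -> Path:
    """Write a PyMOL command script visualising superposed interaction sites.

    One pseudoatom marker per hydrogen-bond partner in the canonical frame;
    bridging-water oxygens get a distinct cross ("+") representation, direct
    protein partners are spheres colored by element.  The script is plain
    text data; this package never executes it.
    """
    path = Path(path)
    lines = [
        "# fragbind interaction-site overlay (canonical fragment frame)",
        "bg_color white",
    ]
    for site in sorted(sites, key=lambda s: s.complex_id):
        sid = site.complex_id
        for i, hb in enumerate(site.hbonds):
            x, y, z = (float(v) for v in site.partner_coords_canonical[i])
            if hb.water_mediated:
                obj = f"{sid}_w{i}"
                lines.append(
                    f"pseudoatom {obj}, pos=[{x:.3f}, {y:.3f}, {z:.3f}], name=O"
                )
                lines.append(f"show nonbonded, {obj}")  # renders as a 3D cross
                lines.append(f"color red, {obj}")
            else:
                obj = f"{sid}_p{i}"
                elem = hb.partner_descriptor.split("_")[-1].upper()
                color = {"N": "blue", "O": "red", "S": "yellow"}.get(elem, "gray")
                lines.append(
                    f"pseudoatom {obj}, pos=[{x:.3f}, {y:.3f}, {z:.3f}], name={elem}"
                )
                lines.append(f"show spheres, {obj}")
                lines.append(f"color {color}, {obj}")
    lines.append("set sphere_scale, 0.25")
    path.write_text("\n".join(lines) + "\n")
    return path


def hbond_table(sites: Iterable) -> pd.DataFrame:
    """Flatten interaction sites into a one-row-per-hydrogen-bond table."""
    rows = []
    for site in sites:
        for hb in site.hbonds:
            rows.append(
                {
                    "complex_id": site.complex_id,
                    "fragment_atom": hb.fragment_atom,
                    "edge": str(hb.edge),
                    "partner_serial": hb.partner_serial,
                    "partner_descriptor": hb.partner_descriptor,
                    "partner_residue": hb.partner_residue_name,
                    "partner_chain": hb.partner_chain_id,
                    "partner_seq": hb.partner_residue_seq,
                    "direction": hb.direction,
                    "distance": round(hb.distance, 3),
                    "water_mediated": hb.water_mediated,
                    "bridge_water": hb.bridge_water if hb.bridge_water is not None else "",
                }
            )
    cols = [
        "complex_id", "fragment_atom", "edge", "partner_serial",
        "partner_descriptor", "partner_residue", "partner_chain", "partner_seq",
        "direction", "distance", "water_mediated", "bridge_water",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["complex_id", "fragment_atom", "partner_serial"]).reset_index(
        drop=True
    )


def write_hbond_table(sites: Iterable, path: str | Path) -> Path:
    path = Path(path)
    hbond_table(sites).to_csv(path, sep="\t", index=False)
    return path
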