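import numpy as np
import pytest

from fragbind import builtin_adenine
from fragbind.geometry import match_fragment, superpose
from fragbind.interactions import build_site
from fragbind.structio import AtomRecord, ComplexStructure


@pytest.fixture(scope="session")
def adenine():
    return builtin_adenine()


@pytest.fixture(scope="session")
def site_from_structure(adenine):
    """Run the standard pipeline (match -> superpose -> site) on a complex."""

    def _run(cs, params=None):
        instances = match_fragment(cs, cs.ligand_instances[0], adenine)
        assert len(instances) == 1
        t = superpose(instances[0], cs, adenine)
        return build_site(cs, instances[0], adenine, params, t)

    return _run


def make_ligand_complex(atoms, residue_name="ATP", cid="fix"):
    """Build a one-ligand complex from (name, element, xyz) triples."""
    records = [
        AtomRecord(
            serial=i + 1,
            atom_name=name,
            element=element,
            residue_name=residue_name,
            residue_seq=500,
            insertion_code="",
            chain_id="L",
            coords=np.asarray(xyz, dtype=float),
            occupancy=1.0,
            category="ligand",
            is_backbone=False,
        )
        for i, (name, element, xyz) in enumerate(atoms)
    ]
    return ComplexStructure(id=cid, atoms=records)


def make_scene(adenine, protein_atoms=(), waters=(), cid="scene"):
    """Adenine ligand at its reference coordinates plus hand-placed atoms.

    ``protein_atoms``: (atom_name, element, residue_name, residue_seq, xyz);
    ``waters``: bare xyz.  Because the ligand sits at the canonical frame,
    the superposition transform is the identity and canonical coordinates
    can be checked analytically.
    """
    serial = 0
    records = []

    def add(name, element, res, seq, chain, xyz, cat, bb):
        nonlocal serial
        serial += 1
        records.append(
            AtomRecord(
                serial=serial, atom_name=name, element=element, residue_name=res,
                residue_seq=seq, insertion_code="", chain_id=chain,
                coords=np.asarray(xyz, dtype=float), occupancy=1.0,
                category=cat, is_backbone=bb,
            )
        )
        return serial

    for name, element in adenine.atoms:
        add(name, element, "ATP", 500, "L", adenine.reference_coords[name], "ligand", False)
    n9, c4, c8 = (adenine.reference_coords[k] for k in ("N9", "C4", "C8"))
    out = -((c4 - n9) / np.linalg.norm(c4 - n9) + (c8 - n9) / np.linalg.norm(c8 - n9))
    add("C1'", "C", "ATP", 500, "L", n9 + 1.47 * out / np.linalg.norm(out), "ligand", False)
    for name, element, res, seq, xyz in protein_atoms:
        add(name, element, res, seq, "A", xyz, "protein",
            name in ("N", "CA", "C", "O"))
    for i, xyz in enumerate(waters):
        add("O", "O", "HOH", 700 + i, "W", xyz, "water", False)
    return ComplexStructure(id=cid, atoms=records)


def outward(adenine, atom_name):
    pos = adenine.reference_coords[atom_name]
    nbrs = adenine.neighbors(atom_name)
    mean = np.mean([adenine.reference_coords[n] - pos for n in nbrs], axis=0)
    v = -mean
    v[2] = 0.0
    return v / np.linalg.norm(v)


def hexagon(center, radius=1.39, z=0.0):
    """Planar regular hexagon coordinates (six ring positions)."""
    pts = []
    for k in range(6):
        a = np.pi / 3 * k
        pts.append(np.array([center[0] + radius * np.cos(a), center[1] + radius * np.sin(a), z]))
    return pts
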