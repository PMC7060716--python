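"""Fragment location and rigid superposition.

Two steps put every complex into a common frame: (1) find the rigid fragment
inside each ligand by element-labeled subgraph isomorphism on a bond graph
inferred from interatomic distances, and (2) compute the least-squares rigid
transform (Kabsch, reflections rejected) that maps the found instance onto
the fragment's canonical reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .fragment import FragmentDefinition
from .structio import COFACTOR_CLASSES, AtomRecord, ComplexStructure

__all__ = [
    "FragmentInstance",
    "RigidTransform",
    "infer_bonds",
    "match_fragment",
    "superpose",
    "apply_transform",
]

# single-bond covalent radii (Å); pair cutoff = r1 + r2 + slack
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20, "B": 0.84,
}
BOND_SLACK = 0.4  # Å beyond summed covalent radii
MIN_BOND = 0.4  # Å; shorter contacts are coordinate errors, not bonds


@dataclass(frozen=True)
class FragmentInstance:
    """One occurrence of the fragment inside a ligand of one complex."""

    complex_id: str
    ligand: tuple[str, str, int]  # (residue_name, chain_id, residue_seq)
    atom_mapping: dict[str, int]  # fragment atom name -> AtomRecord serial
    cofactor_class: str  # ATP | NAD | FAD | SAM | CoA | other

    def coords(self, cs: ComplexStructure, names: list[str]) -> np.ndarray:
        return np.array([cs.atom(self.atom_mapping[n]).coords for n in names])


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion y = R x + t with its post-fit RMSD."""

    rotation: np.ndarray  # 3x3, proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    fit_rmsd: float

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is improper (det != +1)")
        if self.fit_rmsd < 0:
            raise ValueError("negative rmsd")

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.fit_rmsd)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "fit_rmsd": self.fit_rmsd,
        }


def _pair_cutoff(e1: str, e2: str) -> float:
    r1 = COVALENT_RADII.get(e1.upper(), 0.77)
    r2 = COVALENT_RADII.get(e2.upper(), 0.77)
    return r1 + r2 + BOND_SLACK


def infer_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int]]:
    """Infer covalent bonds among heavy atoms from interatomic distances.

    A pair is bonded when its distance falls between a lower sanity bound and
    the summed covalent radii plus slack.  CONECT records are ignored:
    heteroatom connectivity in deposited files is unreliable, while idealized
    bond lengths deviate far less than the slack allows.
    """
    heavy = [a for a in atoms if a.element != "H"]
    bonds = []
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            d = float(np.linalg.norm(heavy[i].coords - heavy[j].coords))
            if MIN_BOND < d < _pair_cutoff(heavy[i].element, heavy[j].element):
                bonds.append((heavy[i].serial, heavy[j].serial))
    return bonds


def match_fragment(
    cs: ComplexStructure,
    ligand: tuple[str, str, int],
    frag: FragmentDefinition,
) -> list[FragmentInstance]:
    """Find all occurrences of the fragment inside one ligand.

    Element-labeled subgraph isomorphism between the fragment graph and the
    ligand's inferred bond graph, with degree constraints: non-attachment
    fragment atoms must keep their free-fragment degree in the ligand (no
    extra substituents), attachment atoms may gain substituents.  Matches
    covering the same atom set (symmetry-equivalent self-mappings) are
    reported once.
    """
    lig_atoms = [a for a in cs.ligand_atoms(ligand) if a.element != "H"]
    if len(lig_atoms) < len(frag.atoms):
        return []
    G = nx.Graph()
    for a in lig_atoms:
        G.add_node(a.serial, element=a.element)
    G.add_edges_from(infer_bonds(lig_atoms))

    F = nx.Graph()
    for name, elem in frag.atoms:
        F.add_node(name, element=elem)
    F.add_edges_from(frag.bonds)
    frag_deg = frag.degrees()

    gm = nx.algorithms.isomorphism.GraphMatcher(
        G, F, node_match=lambda a, b: a["element"] == b["element"]
    )
    instances: list[FragmentInstance] = []
    seen: set[frozenset[int]] = set()
    for mapping in gm.subgraph_isomorphisms_iter():  # ligand serial -> frag name
        inv = {name: serial for serial, name in mapping.items()}
        ok = True
        for name, serial in inv.items():
            if name in frag.attachment_atoms:
                if G.degree(serial) < frag_deg[name]:
                    ok = False
                    break
            elif G.degree(serial) != frag_deg[name]:
                ok = False
                break
        if not ok:
            continue
        key = frozenset(inv.values())
        if key in seen:
            continue
        seen.add(key)
        instances.append(
            FragmentInstance(
                complex_id=cs.id,
                ligand=ligand,
                atom_mapping=dict(sorted(inv.items())),
                cofactor_class=COFACTOR_CLASSES.get(ligand[0], "other"),
            )
        )
    instances.sort(key=lambda inst: min(inst.atom_mapping.values()))
    return instances


def kabsch(moving: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``moving`` onto ``target``.

    SVD solution with the determinant correction, so reflections are never
    returned even for planar point sets.  Raises on (near-)collinear inputs,
    where the in-plane rotation would be undetermined.
    """
    X = np.asarray(moving, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or len(X) < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    s = np.linalg.svd(X0, compute_uv=False)
    if s[1] < 1e-6 * max(s[0], 1.0):
        raise ValueError("degenerate geometry: mapped atoms are collinear")
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    resid = (R @ X.T).T + t - Y
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rotation=R, translation=t, fit_rmsd=rmsd)


def superpose(
    instance: FragmentInstance,
    cs: ComplexStructure,
    frag: FragmentDefinition,
) -> RigidTransform:
    """Superpose a fragment instance onto the canonical reference frame.

    All mapped heavy atoms contribute with equal weight; the returned
    transform maps crystal coordinates into the canonical frame.
    """
    names = sorted(instance.atom_mapping)
    moving = instance.coords(cs, names)
    target = frag.reference_array(names)
    return kabsch(moving, target)


def apply_transform(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply y = R x + t to an (n, 3) array or a single 3-vector."""
    P = np.asarray(points, dtype=float)
    single = P.ndim == 1
    P = np.atleast_2d(P)
    out = (t.rotation @ P.T).T + t.translation
    return out[0] if single else out
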