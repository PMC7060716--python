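"""Rigid fragment definitions and binding-edge geometry.

A *fragment* is a rigid, planar substructure of a larger ligand — the default
is the adenine moiety shared by ATP, NAD, FAD, SAM and CoA.  The definition
carries the chemical graph (atoms + bonds), the hydrogen-bonding roles of each
atom, the assignment of atoms to the purine's three binding edges
(Watson–Crick, Hoogsteen, sugar), and canonical reference coordinates that
every complex is superposed into.

The canonical frame convention: the centroid of the ring atoms sits at the
origin, the ring plane is the xy-plane, and +x points toward the midpoint of
the C4–C5 bond (the ring-fusion bond for adenine); the frame is right-handed
with N1 at positive y.  Fragment definitions are data (JSON files shipped with
the package), so additional rigid fragments can be added without code changes.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EdgeLabel",
    "FragmentDefinition",
    "builtin_adenine",
    "load_fragment",
    "resolve_edge",
]


class EdgeLabel(str, enum.Enum):
    """One of the three hydrogen-bonding faces of a purine."""

    WATSON_CRICK = "watson_crick"
    HOOGSTEEN = "hoogsteen"
    SUGAR = "sugar"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class FragmentDefinition:
    """A rigid fragment: chemical graph, H-bond roles, edges, reference frame.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"adenine"``.
    atoms
        ``(atom_name, element)`` pairs; heavy atoms only.
    bonds
        Covalent bonds as atom-name pairs.
    donor_atoms, acceptor_atoms
        Polar hydrogen-bonding roles.  Disjoint for adenine (N6 donates;
        N1/N3/N7 accept).
    weak_ch_donor_atoms
        Aromatic C–H positions (C2, C8) that may act as weak donors; excluded
        from the default polar chemistry and only used when explicitly
        requested.
    attachment_atoms
        Positions substituted in the parent ligand (N9 carries the ribose);
        not available for hydrogen bonding.
    edge_map
        Atom name -> set of edge labels; atoms at edge junctions (C2, N6)
        carry two labels.
    edge_refs
        For two-edge atoms, a reference fragment atom per edge used to
        disambiguate which side of the atom's exocyclic axis a partner lies on.
    reference_coords
        Atom name -> 3-vector (Å) in the canonical frame.
    """

    name: str
    atoms: tuple[tuple[str, str], ...]
    bonds: tuple[tuple[str, str], ...]
    donor_atoms: frozenset[str]
    acceptor_atoms: frozenset[str]
    attachment_atoms: frozenset[str]
    edge_map: dict[str, frozenset[EdgeLabel]]
    reference_coords: dict[str, np.ndarray]
    weak_ch_donor_atoms: frozenset[str] = frozenset()
    edge_refs: dict[str, dict[EdgeLabel, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {a for a, _ in self.atoms}
        for a, b in self.bonds:
            if a not in names or b not in names:
                raise ValueError(f"bond references unknown atom: {a}-{b}")
        if not self._connected(names):
            raise ValueError("fragment bond graph is not connected")
        overlap = self.donor_atoms & self.acceptor_atoms
        if overlap:
            raise ValueError(f"atoms both donor and acceptor: {sorted(overlap)}")
        for a in self.donor_atoms | self.acceptor_atoms:
            if a not in self.edge_map:
                raise ValueError(f"polar atom {a} has no edge_map entry")
        missing = names - set(self.reference_coords)
        if missing:
            raise ValueError(f"atoms without reference coordinates: {sorted(missing)}")

    def _connected(self, names: set[str]) -> bool:
        adj: dict[str, set[str]] = {n: set() for n in names}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[str] = set()
        stack = [next(iter(names))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj[n] - seen)
        return seen == names

    @property
    def element_of(self) -> dict[str, str]:
        return dict(self.atoms)

    @property
    def ring_atoms(self) -> tuple[str, ...]:
        """Atoms with two or more covalent neighbours (the fused ring system)."""
        deg = self.degrees()
        return tuple(a for a, _ in self.atoms if deg[a] >= 2)

    def degrees(self) -> dict[str, int]:
        deg = {a: 0 for a, _ in self.atoms}
        for a, b in self.bonds:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, atom_name: str) -> tuple[str, ...]:
        out = []
        for a, b in self.bonds:
            if a == atom_name:
                out.append(b)
            elif b == atom_name:
                out.append(a)
        return tuple(sorted(out))

    def reference_array(self, names: list[str] | None = None) -> np.ndarray:
        """Stack reference coordinates into an (n, 3) array."""
        if names is None:
            names = [a for a, _ in self.atoms]
        return np.array([self.reference_coords[n] for n in names], dtype=float)

    def planarity_residual(self) -> float:
        """RMS out-of-plane distance of all atoms from their best-fit plane."""
        X = self.reference_array()
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        return float(s[2] / np.sqrt(len(X)))


def load_fragment(path: str | Path) -> FragmentDefinition:
    """Load a fragment definition from a JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    return _from_dict(raw)


def builtin_adenine() -> FragmentDefinition:
    """The 10-heavy-atom adenine fragment shipped with the package.

    Ring atoms N1, C2, N3, C4, C5, C6, N7, C8, N9 plus the exocyclic amine N6.
    Acceptors are the ring nitrogens N1 (Watson–Crick), N3 (sugar) and N7
    (Hoogsteen); the single donor is N6, which sits on the junction of the
    Watson–Crick and Hoogsteen edges.  N9 is the attachment point (bonded to
    the ribose in nucleotide cofactors).
    """
    ref = resources.files("fragbind.data").joinpath("adenine.json")
    return _from_dict(json.loads(ref.read_text()))


def _from_dict(raw: dict) -> FragmentDefinition:
    return FragmentDefinition(
        name=raw["name"],
        atoms=tuple((a, e) for a, e in raw["atoms"]),
        bonds=tuple((a, b) for a, b in raw["bonds"]),
        donor_atoms=frozenset(raw["donor_atoms"]),
        acceptor_atoms=frozenset(raw["acceptor_atoms"]),
        weak_ch_donor_atoms=frozenset(raw.get("weak_ch_donor_atoms", [])),
        attachment_atoms=frozenset(raw["attachment_atoms"]),
        edge_map={
            a: frozenset(EdgeLabel(e) for e in edges)
            for a, edges in raw["edge_map"].items()
        },
        edge_refs={
            a: {EdgeLabel(e): ref for e, ref in refs.items()}
            for a, refs in raw.get("edge_refs", {}).items()
        },
        reference_coords={
            a: np.asarray(v, dtype=float) for a, v in raw["reference_coords"].items()
        },
    )


def _in_plane(v: np.ndarray) -> np.ndarray:
    """Project a canonical-frame vector onto the fragment plane (z = 0)."""
    w = np.array([v[0], v[1], 0.0])
    return w


def resolve_edge(
    frag: FragmentDefinition, atom_name: str, partner_pos: np.ndarray
) -> EdgeLabel:
    """Assign the binding edge for a hydrogen bond at ``atom_name``.

    Atoms mapped to a single edge return it directly.  Atoms on an edge
    junction (N6, and C2 when weak C–H donors are enabled) are disambiguated
    geometrically: the partner's in-plane direction from the atom is compared
    against the two edges' reference atoms, mirrored across the atom's
    exocyclic axis.  For N6 the axis is the C6→N6 bond: a partner on the N1
    side of that axis is a Watson–Crick contact, one on the N7 side a
    Hoogsteen contact.  Mirror-image partner positions across the axis
    therefore resolve to opposite edges.

    Raises
    ------
    KeyError
        Unknown atom name.
    ValueError
        Attachment atoms (substituted, not available for bonding).
    """
    if atom_name in frag.attachment_atoms:
        raise ValueError(f"{atom_name} is an attachment atom, not available for bonding")
    if atom_name not in frag.edge_map:
        raise KeyError(f"unknown or non-bonding atom {atom_name!r}")
    edges = frag.edge_map[atom_name]
    if len(edges) == 1:
        return next(iter(edges))

    refs = frag.edge_refs.get(atom_name)
    if refs is None or set(refs) != set(edges):
        raise ValueError(f"no edge references to disambiguate {atom_name}")
    pos = frag.reference_coords[atom_name]
    nbrs = frag.neighbors(atom_name)
    # outward exocyclic axis: away from the mean neighbour direction
    nbr_mean = np.mean([frag.reference_coords[n] - pos for n in nbrs], axis=0)
    axis = _in_plane(-nbr_mean)
    axis /= np.linalg.norm(axis)
    p = _in_plane(np.asarray(partner_pos, dtype=float) - pos)
    perp = p - np.dot(p, axis) * axis
    best: tuple[float, EdgeLabel] | None = None
    for edge, ref_name in sorted(refs.items(), key=lambda kv: kv[0].value):
        r = _in_plane(frag.reference_coords[ref_name] - pos)
        r_perp = r - np.dot(r, axis) * axis
        nr = np.linalg.norm(r_perp)
        np_ = np.linalg.norm(perp)
        if nr == 0.0:
            continue
        if np_ == 0.0:
            score = 0.0  # on-axis partner: deterministic first-edge tie-break
        else:
            score = float(np.dot(perp, r_perp) / (nr * np_))
        if best is None or score > best[0]:
            best = (score, edge)
    assert best is not None
    return best[1]
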