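"""Synthetic protein–fragment complexes with known ground truth.

Builds fully self-contained PDB-style complexes around the canonical
fragment geometry: a minimal adenine-bearing ligand (N9 capped by a carbon
standing in for the ribose), pseudo-residue hydrogen-bond partners planted
at prescribed polar geometry, bridging waters, optional non-bonding decoy
residues, and a random overall rigid motion so that superposition is always
exercised.  Every generator is a pure function of its plan and seed, and
each returns the exact planted truth (bond list, motif label, family label)
for use as an oracle.

Partner pseudo-residues are minimal (3–4 heavy atoms) but carry valid
residue names and author numbering, so sequence-order motif rules work; the
backbone walks away from the fragment so planted atoms are the only polar
contacts.  Planted geometry is validated: no inter-residue heavy-atom pair
below 2 Å, and every non-partner polar atom keeps a clearance margin from
complementary fragment atoms so that detection thresholds see planted bonds
and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .fragment import FragmentDefinition, builtin_adenine
from .structio import AtomRecord, ComplexStructure
from .networks import ThemeAnnotation

__all__ = [
    "PlannedBond",
    "SitePlan",
    "SiteTruth",
    "generate_site",
    "motif_plan",
    "generate_family_dataset",
    "ThemeFixtureEntry",
    "generate_theme_fixture",
    "generate_corpus",
]

# clearance (Å) kept between any *unplanned* complementary polar pair, so a
# 3.5 Å detection threshold retains a >= 0.5 Å margin against spurious bonds
CLEARANCE = 4.0
MIN_CONTACT = 2.0  # Å, inter-residue clash limit


@dataclass(frozen=True)
class PlannedBond:
    """One planted polar interaction.

    ``in_plane_angle`` rotates the partner away from the fragment atom's
    idealized outward (lone-pair / N–H) direction, counterclockwise in the
    canonical plane; positive angles at N6 move toward the Watson–Crick
    side, negative toward the Hoogsteen side.  For mediated bonds the
    planted distance is the fragment–water leg; the protein partner sits
    ``water_leg`` further out along the same direction.
    """

    fragment_atom: str
    descriptor: str  # backbone_N | backbone_O | sidechain_N/O/S
    distance: float = 2.9
    in_plane_angle: float = 0.0
    mediated: bool = False
    water_leg: float = 2.8
    residue_name: Optional[str] = None
    residue_seq: Optional[int] = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not (2.5 <= self.distance <= 3.4):
            raise ValueError("planted distances must lie within [2.5, 3.4] Å")


@dataclass(frozen=True)
class SitePlan:
    planted_bonds: tuple[PlannedBond, ...]
    motif_label: Optional[str] = None
    family_id: int = 0
    jitter_sigma: float = 0.0
    seed: int = 0
    n_decoys: int = 0
    complex_id: Optional[str] = None


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth of one generated complex."""

    complex_id: str
    bonds: tuple[tuple, ...]  # (fragment_atom, partner_serial, descriptor, mediated, bridge_water)
    motif_label: Optional[str]
    family_id: int

    def bond_keys(self) -> set[tuple[str, int]]:
        return {(b[0], b[1]) for b in self.bonds}


_DEFAULT_RESIDUE = {
    "backbone_N": "GLY",
    "backbone_O": "GLY",
    "sidechain_O": "ASP",
    "sidechain_N": "LYS",
    "sidechain_S": "CYS",
}

# atom bearing the planted position, per descriptor and residue
_PLANT_ATOM = {
    ("sidechain_O", "ASP"): "OD1",
    ("sidechain_O", "GLU"): "OE1",
    ("sidechain_O", "ASN"): "OD1",
    ("sidechain_O", "GLN"): "OE1",
    ("sidechain_O", "SER"): "OG",
    ("sidechain_O", "THR"): "OG1",
    ("sidechain_S", "CYS"): "SG",
    ("sidechain_N", "LYS"): "NZ",
}


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([v[0] * c - v[1] * s, v[0] * s + v[1] * c, 0.0])


def _outward(frag: FragmentDefinition, atom_name: str) -> np.ndarray:
    """Idealized in-plane lone-pair / N–H direction at a fragment atom."""
    pos = frag.reference_coords[atom_name]
    nbrs = frag.neighbors(atom_name)
    mean = np.mean([frag.reference_coords[n] - pos for n in nbrs], axis=0)
    v = -mean
    v[2] = 0.0
    return v / np.linalg.norm(v)


def _plant_position(frag: FragmentDefinition, bond: PlannedBond) -> np.ndarray:
    pos = frag.reference_coords[bond.fragment_atom]
    direction = _rot2(_outward(frag, bond.fragment_atom), bond.in_plane_angle)
    return pos + bond.distance * direction


class _Builder:
    """Accumulates atoms with sequential serials."""

    def __init__(self) -> None:
        self.atoms: list[AtomRecord] = []
        self._serial = 0

    def add(
        self,
        name: str,
        element: str,
        res_name: str,
        seq: int,
        chain: str,
        xyz: np.ndarray,
        category: str,
    ) -> AtomRecord:
        self._serial += 1
        rec = AtomRecord(
            serial=self._serial,
            atom_name=name,
            element=element,
            residue_name=res_name,
            residue_seq=seq,
            insertion_code="",
            chain_id=chain,
            coords=np.asarray(xyz, dtype=float),
            occupancy=1.0,
            category=category,
            is_backbone=(category == "protein" and name in ("N", "CA", "C", "O")),
        )
        self.atoms.append(rec)
        return rec


def _away_direction(anchor: np.ndarray, frag_center: np.ndarray) -> np.ndarray:
    v = anchor - frag_center
    v[2] = 0.0
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def _pick_turn(
    start: np.ndarray, toward_fragment: np.ndarray, step: float, obstacles: np.ndarray
) -> np.ndarray:
    """Next backbone position: turn off the H-bond axis, away from everything
    already placed (the ring and earlier partner residues)."""
    best, best_d = None, -1.0
    for ang in (115.0, -115.0, 130.0, -130.0, 145.0, -145.0):
        cand = start + step * _rot2(toward_fragment, ang)
        d = float(np.min(np.linalg.norm(obstacles - cand, axis=1)))
        if d > best_d:
            best, best_d = cand, d
    return best


def _build_partner_residue(
    builder: _Builder,
    bond: PlannedBond,
    plant_pos: np.ndarray,
    frag_atom_pos: np.ndarray,
    frag_xyz: np.ndarray,
    res_name: str,
    seq: int,
    extra_obstacles: np.ndarray | None = None,
) -> tuple[AtomRecord, list[tuple[AtomRecord, str]]]:
    """Place the planted atom plus a minimal backbone walking outward.

    Every walk step picks, among a fan of candidate directions, the position
    farthest from everything already placed (fragment, earlier residues and
    all planted positions), staggered above/below the fragment plane by
    residue parity.  Returns the planted atom record and the residue's polar
    atoms with roles ('donor'/'acceptor') for the clearance audit.
    """
    v_hb = (frag_atom_pos - plant_pos)
    v_hb = v_hb / np.linalg.norm(v_hb)
    chain = bond.chain_id
    polar: list[tuple[AtomRecord, str]] = []
    zsign = 1.0 if (seq // 2) % 2 == 0 else -1.0

    def obstacles() -> np.ndarray:
        obs = np.array([a.coords for a in builder.atoms])
        if extra_obstacles is not None and len(extra_obstacles):
            obs = np.vstack([obs, extra_obstacles])
        return obs

    def step_from(
        start: np.ndarray, base_dir: np.ndarray, step: float, dz: float, polar: bool = False
    ) -> np.ndarray:
        obs = obstacles()
        best, best_d = None, -1.0
        for ang in (0.0, 40.0, -40.0, 80.0, -80.0, 115.0, -115.0):
            cand = start + step * _rot2(base_dir, ang) + np.array([0.0, 0.0, dz * zsign])
            d = float(np.min(np.linalg.norm(obs - cand, axis=1)))
            if polar:
                # polar walk atoms must stay outside the no-spurious margin
                margin = float(np.min(np.linalg.norm(frag_xyz - cand, axis=1)))
                if margin < CLEARANCE + 0.1:
                    d -= 2.0 * (CLEARANCE + 0.1 - margin)
            if d > best_d:
                best, best_d = cand, d
        return best

    if bond.descriptor == "backbone_N":
        n = builder.add("N", "N", res_name, seq, chain, plant_pos, "protein")
        # the amide's CA must keep the antecedent angle X-D...A open
        ca_pos = _pick_turn(plant_pos, v_hb, 1.46, obstacles()) + np.array([0.0, 0.0, 0.55 * zsign])
        builder.add("CA", "C", res_name, seq, chain, ca_pos, "protein")
        away = _away_direction(ca_pos, frag_xyz.mean(axis=0))
        c_pos = step_from(ca_pos, away, 1.52, 0.35)
        builder.add("C", "C", res_name, seq, chain, c_pos, "protein")
        o_pos = step_from(c_pos, away, 1.23, 0.2, polar=True)
        o = builder.add("O", "O", res_name, seq, chain, o_pos, "protein")
        polar += [(n, "donor"), (o, "acceptor")]
        return n, polar

    if bond.descriptor == "backbone_O":
        o = builder.add("O", "O", res_name, seq, chain, plant_pos, "protein")
        c_pos = _pick_turn(plant_pos, v_hb, 1.23, obstacles()) + np.array([0.0, 0.0, 0.55 * zsign])
        builder.add("C", "C", res_name, seq, chain, c_pos, "protein")
        away = _away_direction(c_pos, frag_xyz.mean(axis=0))
        ca_pos = step_from(c_pos, away, 1.52, 0.35)
        builder.add("CA", "C", res_name, seq, chain, ca_pos, "protein")
        n_pos = step_from(ca_pos, away, 1.46, 0.2, polar=True)
        n = builder.add("N", "N", res_name, seq, chain, n_pos, "protein")
        polar += [(o, "acceptor"), (n, "donor")]
        return o, polar

    # side-chain plants: planted tip atom, then walk CB/CA/N outward
    tip_name = _PLANT_ATOM[(bond.descriptor, res_name)]
    element = bond.descriptor.rsplit("_", 1)[-1]
    tip = builder.add(tip_name, element, res_name, seq, chain, plant_pos, "protein")
    step = {"O": 1.41, "S": 1.81, "N": 1.47}[element]
    cb_pos = _pick_turn(plant_pos, v_hb, step, obstacles()) + np.array([0.0, 0.0, 0.55 * zsign])
    builder.add("CB", "C", res_name, seq, chain, cb_pos, "protein")
    away = _away_direction(cb_pos, frag_xyz.mean(axis=0))
    ca_pos = step_from(cb_pos, away, 1.54, 0.35)
    builder.add("CA", "C", res_name, seq, chain, ca_pos, "protein")
    n_pos = step_from(ca_pos, away, 1.46, 0.2, polar=True)
    n = builder.add("N", "N", res_name, seq, chain, n_pos, "protein")
    role = "acceptor" if element in ("O", "S") else "donor"
    if res_name in ("SER", "THR"):
        polar.append((tip, "donor"))  # hydroxyls are ambivalent
    polar += [(tip, role), (n, "donor")]
    return tip, polar


def _build_shared_residue(
    builder: _Builder,
    bonds: Sequence[tuple[PlannedBond, np.ndarray]],
    frag: FragmentDefinition,
    frag_xyz: np.ndarray,
    res_name: str,
    seq: int,
) -> tuple[list[tuple[PlannedBond, AtomRecord]], list[tuple[AtomRecord, str]]]:
    """One residue contributing several backbone bonds (amide + carbonyl)."""
    placed: list[tuple[PlannedBond, AtomRecord]] = []
    polar: list[tuple[AtomRecord, str]] = []
    chain = bonds[0][0].chain_id
    obstacles = np.array([a.coords for a in builder.atoms])
    n_pos = None
    for bond, pos in bonds:
        if bond.descriptor == "backbone_N":
            rec = builder.add("N", "N", res_name, seq, chain, pos, "protein")
            polar.append((rec, "donor"))
            n_pos = pos
        elif bond.descriptor == "backbone_O":
            rec = builder.add("O", "O", res_name, seq, chain, pos, "protein")
            polar.append((rec, "acceptor"))
        else:
            raise ValueError("shared residues support backbone bonds only")
        placed.append((bond, rec))
    anchor = n_pos if n_pos is not None else bonds[0][1]
    frag_atom_pos = frag.reference_coords[bonds[0][0].fragment_atom]
    v_hb = frag_atom_pos - anchor
    v_hb /= np.linalg.norm(v_hb)
    ca_pos = _pick_turn(anchor, v_hb, 1.46, obstacles)
    builder.add("CA", "C", res_name, seq, chain, ca_pos, "protein")
    return placed, polar


def generate_site(
    plan: SitePlan, frag: FragmentDefinition | None = None
) -> tuple[ComplexStructure, SiteTruth]:
    """Build one complex from a plan; returns the structure and its truth.

    The fragment sits at its reference coordinates during construction, the
    partners are planted, Gaussian jitter of ``plan.jitter_sigma`` is applied
    to protein and water atoms, and finally the whole complex receives a
    seeded random rigid motion.  Raises on geometrically infeasible plans:
    inter-residue contacts under 2 Å, or unplanned polar pairs inside the
    clearance margin.
    """
    frag = frag or builtin_adenine()
    rng = np.random.default_rng(plan.seed)
    cid = plan.complex_id or f"synth{plan.seed}"
    builder = _Builder()

    # ligand: fragment + attachment cap (carbon standing in for the ribose C1')
    frag_names = [a for a, _ in frag.atoms]
    frag_xyz = frag.reference_array(frag_names)
    frag_serials: dict[str, int] = {}
    for name, elem in frag.atoms:
        rec = builder.add(
            name, elem, "LIG", 900, "L", frag.reference_coords[name], "ligand"
        )
        frag_serials[name] = rec.serial
    for att in sorted(frag.attachment_atoms):
        cap_pos = frag.reference_coords[att] + 1.47 * _outward(frag, att)
        builder.add(f"C{att[-1]}'", "C", "LIG", 900, "L", cap_pos, "ligand")

    # group bonds by (chain, seq) to support shared residues
    next_seq = 10
    keyed: dict[tuple[str, int], list[PlannedBond]] = {}
    for bond in plan.planted_bonds:
        seq = bond.residue_seq
        if seq is None:
            seq = next_seq
            next_seq += 10
        keyed.setdefault((bond.chain_id, seq), []).append(bond)

    # all planted positions (and mediated protein anchors) are known up
    # front; residue walks must steer clear of every one of them
    all_plants = []
    for bonds_here in keyed.values():
        for b in bonds_here:
            pp = _plant_position(frag, b)
            all_plants.append(pp)
            if b.mediated:
                fap = frag.reference_coords[b.fragment_atom]
                dirn = (pp - fap) / np.linalg.norm(pp - fap)
                all_plants.append(pp + b.water_leg * dirn)
    all_plants = np.array(all_plants) if all_plants else np.zeros((0, 3))

    truth_bonds: list[tuple] = []
    polar_atoms: list[tuple[AtomRecord, str]] = []  # (atom, role)
    planned_pairs: set[tuple[str, int]] = set()
    water_partner: dict[int, int] = {}  # water serial -> its protein partner serial
    first_protein = len(builder.atoms)

    for (chain, seq), bonds in sorted(keyed.items()):
        positions = [_plant_position(frag, b) for b in bonds]
        if len(bonds) > 1:
            res_name = bonds[0].residue_name or "GLY"
            placed, polar = _build_shared_residue(
                builder, list(zip(bonds, positions)), frag, frag_xyz, res_name, seq
            )
            polar_atoms += polar
            for bond, rec in placed:
                truth_bonds.append((bond.fragment_atom, rec.serial, bond.descriptor, False, None))
                planned_pairs.add((bond.fragment_atom, rec.serial))
            continue
        bond, pos = bonds[0], positions[0]
        res_name = bond.residue_name or _DEFAULT_RESIDUE[bond.descriptor]
        frag_atom_pos = frag.reference_coords[bond.fragment_atom]
        if bond.mediated:
            # water at the planted position, protein partner further out
            direction = (pos - frag_atom_pos) / np.linalg.norm(pos - frag_atom_pos)
            w = builder.add("O", "O", "HOH", 700 + seq, "W", pos, "water")
            partner_pos = pos + bond.water_leg * direction
            rec, polar = _build_partner_residue(
                builder, bond, partner_pos, pos, frag_xyz, res_name, seq, all_plants
            )
            polar_atoms += polar
            truth_bonds.append((bond.fragment_atom, rec.serial, bond.descriptor, True, w.serial))
            planned_pairs.add((bond.fragment_atom, rec.serial))
            water_partner[w.serial] = rec.serial
        else:
            rec, polar = _build_partner_residue(
                builder, bond, pos, frag_atom_pos, frag_xyz, res_name, seq, all_plants
            )
            polar_atoms += polar
            truth_bonds.append((bond.fragment_atom, rec.serial, bond.descriptor, False, None))
            planned_pairs.add((bond.fragment_atom, rec.serial))

    # decoy residues: polar atoms well outside every detection threshold
    placed_xyz = np.array([a.coords for a in builder.atoms])
    for k in range(plan.n_decoys):
        for _ in range(200):
            theta = rng.uniform(0, 2 * math.pi)
            z = rng.uniform(-2.0, 2.0)
            radius = rng.uniform(7.5, 10.0)
            pos = np.array([radius * math.cos(theta), radius * math.sin(theta), z])
            d_all = np.linalg.norm(placed_xyz - pos, axis=1)
            if d_all.min() < 2.5 or np.linalg.norm(frag_xyz - pos, axis=1).min() < CLEARANCE + 0.5:
                continue
            n = builder.add("N", "N", "GLY", 400 + k, "D", pos, "protein")
            away = _away_direction(pos, frag_xyz.mean(axis=0))
            builder.add("CA", "C", "GLY", 400 + k, "D", pos + 1.46 * away, "protein")
            polar_atoms.append((n, "donor"))
            placed_xyz = np.vstack([placed_xyz, pos])
            break
        else:
            raise ValueError("could not place decoy residue without violating clearance")

    _audit_geometry(frag, frag_serials, builder.atoms, polar_atoms, planned_pairs, water_partner)

    # jitter protein/water atoms, then a random global rigid motion
    for a in builder.atoms[first_protein:]:
        if a.category in ("protein", "water") and plan.jitter_sigma > 0:
            a.coords = a.coords + rng.normal(0.0, plan.jitter_sigma, 3)
    R = _random_rotation(rng)
    t = rng.uniform(-15.0, 15.0, 3)
    for a in builder.atoms:
        a.coords = R @ a.coords + t

    cs = ComplexStructure(id=cid, atoms=builder.atoms)
    truth = SiteTruth(
        complex_id=cid,
        bonds=tuple(truth_bonds),
        motif_label=plan.motif_label,
        family_id=plan.family_id,
    )
    return cs, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _audit_geometry(
    frag: FragmentDefinition,
    frag_serials: dict[str, int],
    atoms: list[AtomRecord],
    polar_atoms: list[tuple[AtomRecord, str]],
    planned_pairs: set[tuple[str, int]],
    water_partner: dict[int, int],
) -> None:
    """Reject plans whose geometry could confuse detection.

    Checks: (1) no inter-residue heavy-atom pair closer than 2 Å; (2) every
    complementary fragment/protein polar pair that was *not* planted keeps
    the clearance margin; (3) waters keep the margin to every fragment polar
    atom and protein polar atom other than their own bridge partners.
    """
    # clash audit (inter-residue)
    for i, a in enumerate(atoms):
        for b in atoms[i + 1 :]:
            if a.residue_key() == b.residue_key():
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d < MIN_CONTACT and not (
                a.category == "ligand" and b.category == "ligand"
            ):
                raise ValueError(
                    f"infeasible plan: {a.atom_name}/{a.residue_name}{a.residue_seq} "
                    f"clashes with {b.atom_name}/{b.residue_name}{b.residue_seq} at {d:.2f} Å"
                )

    frag_pos = {n: frag.reference_coords[n] for n in frag_serials}
    waters = [a for a in atoms if a.category == "water"]
    for atom, role in polar_atoms:
        for name in sorted(frag.donor_atoms | frag.acceptor_atoms):
            complementary = (role == "acceptor" and name in frag.donor_atoms) or (
                role == "donor" and name in frag.acceptor_atoms
            )
            if not complementary or (name, atom.serial) in planned_pairs:
                continue
            d = float(np.linalg.norm(frag_pos[name] - atom.coords))
            if d < CLEARANCE:
                raise ValueError(
                    f"infeasible plan: unplanned polar contact {name}–"
                    f"{atom.atom_name}/{atom.residue_name}{atom.residue_seq} at {d:.2f} Å"
                )
    for w in waters:
        target_partner = water_partner.get(w.serial)
        planted_frag_atoms = {
            fa for (fa, serial) in planned_pairs if serial == target_partner
        }
        for name in sorted(frag.donor_atoms | frag.acceptor_atoms):
            if name in planted_frag_atoms:
                continue
            if float(np.linalg.norm(frag_pos[name] - w.coords)) < CLEARANCE:
                raise ValueError(
                    f"infeasible plan: water {w.serial} within clearance of fragment {name}"
                )
        for atom, _role in polar_atoms:
            if atom.serial == target_partner:
                continue
            if float(np.linalg.norm(atom.coords - w.coords)) < CLEARANCE:
                raise ValueError(
                    f"infeasible plan: water {w.serial} within clearance of "
                    f"{atom.atom_name}/{atom.residue_name}{atom.residue_seq}"
                )


# ---------------------------------------------------------------------------
# standard plans

_WC_N6 = 20.0  # in-plane angle of the Watson–Crick-side N6 partner
_HG_N6 = -45.0  # Hoogsteen-side N6 partner


def motif_plan(
    label: str,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    n_decoys: int = 0,
    complex_id: str | None = None,
) -> SitePlan:
    """A standard plan realising one motif (or extended variant) geometry."""
    if label == "direct":
        bonds = (
            PlannedBond("N6", "backbone_O", 2.9, _WC_N6, residue_seq=10),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=12),
        )
    elif label == "reverse":
        bonds = (
            PlannedBond("N6", "backbone_O", 2.9, _WC_N6, residue_seq=12),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=10),
        )
    elif label == "asp":
        bonds = (
            PlannedBond("N6", "sidechain_O", 2.9, _WC_N6, residue_name="ASP", residue_seq=10),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=12),
        )
    elif label == "asp_ser":
        bonds = (
            PlannedBond("N6", "sidechain_O", 2.9, _WC_N6, residue_name="SER", residue_seq=10),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=12),
        )
    elif label == "asp_cys":
        bonds = (
            PlannedBond("N6", "sidechain_S", 2.9, _WC_N6, residue_name="CYS", residue_seq=10),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=12),
        )
    elif label == "reverse_xv_xvi":
        bonds = (
            PlannedBond("N6", "backbone_O", 2.9, _WC_N6, residue_seq=12),
            PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=10),
            PlannedBond("N6", "backbone_O", 2.9, _HG_N6, residue_seq=34),
        )
    elif label == "position_iii_hoogsteen":
        bonds = (
            PlannedBond("N6", "backbone_O", 2.9, _HG_N6, residue_seq=40),
            PlannedBond("N7", "backbone_N", 2.9, 0.0, residue_seq=40),
        )
    else:
        raise ValueError(f"unknown motif plan {label!r}")
    base = {"direct": "direct", "reverse": "reverse", "asp": "asp",
            "asp_ser": "asp", "asp_cys": "asp", "reverse_xv_xvi": "reverse",
            "position_iii_hoogsteen": "other"}[label]
    return SitePlan(
        planted_bonds=bonds,
        motif_label=base,
        seed=seed,
        jitter_sigma=jitter_sigma,
        n_decoys=n_decoys,
        complex_id=complex_id,
    )


# pool of distinct planted-partner placements: (fragment_atom, descriptor,
# in-plane angle).  Any two placements are >= 2.2 Å apart (45° of arc at a
# 2.9 Å bond, or different fragment atoms); each family draws three of them.
_PARTNER_POOL: tuple[tuple[str, str, float], ...] = (
    ("N1", "backbone_N", 0.0),
    ("N1", "backbone_N", 45.0),
    ("N3", "backbone_N", 0.0),
    ("N3", "backbone_N", -45.0),
    ("N6", "backbone_O", -60.0),
    ("N6", "backbone_O", -15.0),
    ("N6", "backbone_O", 30.0),
    ("N6", "backbone_O", 75.0),
    ("N7", "backbone_N", 0.0),
    ("N7", "backbone_N", -45.0),
)
_STANDARD_TRIPLE = (0, 6, 8)  # N1@0, N6@30 (Watson–Crick side), N7@0


def _triple_plan(
    triple: Sequence[int],
    family: int = 0,
    member: int = 0,
    sigma: float = 0.0,
    seed: int = 0,
    complex_id: str | None = None,
) -> SitePlan:
    bonds = tuple(
        PlannedBond(atom, desc, 2.9, angle, residue_seq=10 * (k + 1))
        for k, (atom, desc, angle) in enumerate(
            _PARTNER_POOL[i] for i in sorted(triple)
        )
    )
    return SitePlan(
        planted_bonds=bonds,
        family_id=family,
        jitter_sigma=sigma,
        seed=seed,
        complex_id=complex_id or f"fam{family}_m{member}",
    )


# maximum packing of audit-feasible triples pairwise sharing <= 1 placement
_FAMILY_TRIPLES: tuple[tuple[int, int, int], ...] = (
    _STANDARD_TRIPLE,
    (0, 2, 4), (0, 3, 5), (1, 2, 5), (1, 3, 8), (1, 4, 6),
    (1, 7, 9), (2, 6, 7), (2, 8, 9), (3, 4, 7), (3, 6, 9), (5, 7, 8),
)


def _family_triples(n_families: int) -> list[tuple[int, ...]]:
    """Partner triples for the requested number of families.

    Families pairwise share at most one partner placement, so two sites from
    different families can match in at most one of three partners (fraction
    1/3, below any sensible similarity threshold).
    """
    if n_families > len(_FAMILY_TRIPLES):
        raise ValueError(
            f"at most {len(_FAMILY_TRIPLES)} well-separated families supported, "
            f"{n_families} requested"
        )
    return list(_FAMILY_TRIPLES[:n_families])


def generate_family_dataset(
    n_families: int,
    members_per_family: int,
    sigma_within: float = 0.05,
    min_between: float = 2.0,
    seed: int = 0,
) -> tuple[list[ComplexStructure], dict[str, int]]:
    """Site families with controlled within-family jitter.

    Each family plants three hydrogen-bond partners drawn from a fixed pool
    of well-separated placements; two families share at most one placement
    and differ in at least two partner positions by >= 2.2 Å, so distinct
    families never satisfy the default similarity thresholds while members
    of one family (at small jitter) do.  Truth maps complex id to family
    label.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    chord = 2 * 2.9 * math.sin(math.radians(45.0 / 2))
    if min_between > chord:
        raise ValueError(
            f"infeasible separation: family partners are {chord:.2f} Å apart "
            f"but {min_between:.2f} Å was requested"
        )
    triples = _family_triples(n_families)
    rng = np.random.default_rng(seed)
    structures, truth = [], {}
    for fam in range(n_families):
        for m in range(members_per_family):
            member_seed = int(rng.integers(0, 2**31 - 1))
            plan = _triple_plan(triples[fam], fam, m, sigma_within, member_seed)
            cs, _t = generate_site(plan)
            structures.append(cs)
            truth[cs.id] = fam
    return structures, truth


@dataclass(frozen=True)
class ThemeFixtureEntry:
    """One complex of a theme fixture: which themes it carries, and whether
    each theme's range covers the hydrogen-bonding residues."""

    complex_id: str
    themes: tuple[tuple[int, bool], ...]  # (theme_id, covers_binder)


def generate_theme_fixture(
    entries: Sequence[ThemeFixtureEntry],
    seed: int = 0,
) -> tuple[list[ComplexStructure], list[ThemeAnnotation], set[tuple[str, str]]]:
    """Structures + theme annotations + the expected theme-network edges.

    Each complex gets the standard three-bond site (partner residues 10, 20,
    30 on chain A).  A covering annotation spans residues 8–45; a
    non-covering one spans 60–100 of the same chain, so the theme is present
    but none of its residues touches the fragment.  Truth edges connect
    complexes sharing a theme that covers the binding residues on both.
    """
    rng = np.random.default_rng(seed)
    structures = []
    annotations = []
    for e in entries:
        plan = _triple_plan(
            _STANDARD_TRIPLE,
            seed=int(rng.integers(0, 2**31 - 1)),
            complex_id=e.complex_id,
        )
        cs, _ = generate_site(plan)
        structures.append(cs)
        for theme_id, covers in e.themes:
            lo, hi = (8, 45) if covers else (60, 100)
            annotations.append(
                ThemeAnnotation(theme_id, e.complex_id, "A", lo, hi)
            )
    participating: dict[int, list[str]] = {}
    for e in entries:
        for theme_id, covers in e.themes:
            if covers:
                participating.setdefault(theme_id, []).append(e.complex_id)
    truth_edges: set[tuple[str, str]] = set()
    for ids in participating.values():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                truth_edges.add(tuple(sorted((ids[i], ids[j]))))
    return structures, annotations, truth_edges


def generate_corpus(
    n: int,
    p_theme: float = 0.1,
    p_ligand: float = 0.1,
    p_ligand_given_theme: float | None = None,
    seed: int = 0,
):
    """A synthetic enrichment corpus; independent by default."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    has_theme = rng.random(n) < p_theme
    if p_ligand_given_theme is None:
        has_ligand = rng.random(n) < p_ligand
    else:
        u = rng.random(n)
        has_ligand = np.where(has_theme, u < p_ligand_given_theme, u < p_ligand)
    return pd.DataFrame(
        {
            "entry_id": [f"e{i:06d}" for i in range(n)],
            "has_theme": has_theme,
            "has_fragment_ligand": has_ligand,
        }
    )
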