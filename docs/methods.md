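# Methods

## The model

fragbind treats a ligand fragment as a *rigid, planar* chemical graph with
fixed reference coordinates. That assumption is what makes cross-complex
comparison trivial: because the fragment cannot flex, a single proper rigid
transform per complex (no scaling, no reflection) places every structure in
one common frame, and hydrogen-bond partners can then be compared as bare
point sets. Everything downstream — site similarity, motif calls, networks
— lives in this canonical frame.

The shipped fragment is adenine. Its reference coordinates were derived
once from a force-field-optimized 3D embedding of the molecule, rotated
into the canonical frame and projected exactly onto the plane (the residual
out-of-plane amplitude of the optimized geometry was < 0.01 Å, so the
projection is a faithful idealization). The canonical frame convention is:
ring-atom centroid at the origin, ring plane = xy, +x toward the midpoint
of the C4–C5 ring-fusion bond, right-handed with N1 at +y. The convention
is arbitrary but fixed, so fixtures, outputs and tests agree bit-for-bit.
Fragment definitions are package data (JSON), not code; another rigid
planar fragment can be added by writing a file with the same fields.

Hydrogen-bonding roles follow the amine/ring-nitrogen chemistry: N6
(exocyclic amine) donates; N1, N3, N7 accept. C2 and C8 are weak aromatic
C–H donors and are excluded by default (`include_weak_ch`) — the analyses
this package supports are about N/O polar contacts. N9 is the attachment
position (ribose in the nucleotide cofactors) and never bonds.

### Binding edges

Each polar atom maps to one of the purine's three edges (Watson–Crick,
Hoogsteen, sugar). N6 sits on the junction of the Watson–Crick and
Hoogsteen edges, and the assignment of an N6 hydrogen bond is geometric:
the partner's in-plane direction is compared across the exocyclic C6→N6
axis — the N1 side is Watson–Crick, the N7 side Hoogsteen. Mirror-image
partner positions across that axis therefore always resolve to opposite
edges. This disambiguation rule is a design choice of this package; the
degenerate on-axis direction (a measure-zero case) resolves
deterministically to the first edge in sorted order.

## Pipeline stages and parameters

**Fragment matching.** Bonds inside each ligand are inferred from
interatomic distances (single-bond covalent radii + 0.4 Å slack) rather
than CONECT records, which are unreliable for heteroatoms in deposited
files. Matching is node-induced subgraph isomorphism with element labels,
plus degree constraints: non-attachment atoms must keep their
free-fragment degree (so N6-substituted analogs do not match), attachment
atoms may gain substituents. Adenine's heavy-atom graph has no nontrivial
automorphism, so deduplication of symmetry-equivalent mappings is a no-op
for the default fragment but kept for generality.

**Superposition.** Kabsch via SVD with the determinant correction, all 10
mapped atoms with equal weight. Planar point sets admit an improper
optimum (reflection through the plane); the correction guarantees a proper
rotation. Near-collinear inputs (second singular value < 1e-6 of the
first) raise rather than return an ill-conditioned rotation. Tests compare
the result against an independent brute-force oracle (several hundred
random rotation starts with Nelder–Mead refinement).

**Hydrogen bonds.** Criteria are hydrogen-free, since most crystal
structures lack hydrogens: heavy-atom donor–acceptor distance ≤
`max_da_distance` (default 3.5 Å; 3.2 Å and 3.9 Å are the strict/lax
presets used in sensitivity checks) and, for every covalent neighbour X of
the donor D, angle X–D···A ≥ 90°. This emulates the polar-contact
definitions of structure-interaction tools that work from heavy atoms; the
exact angular term is an operationalization, validated property-wise
(planted-geometry recovery), not against any particular third-party tool.
Cys/Met sulfur is accepted as a weak acceptor (flag, default on). Water
bridges use the same distance cutoff per leg, a single water only, no
angle term (waters reorient freely), and record the bridging water; chains
of two or more waters are never followed. When a direct and a mediated
bond connect the same (fragment atom, partner) pair, the direct bond wins;
among duplicate mediated bonds the shortest total leg length is kept.

**Interaction sites.** The canonical-frame point recorded for a direct
bond is the partner atom; for a mediated bond it is the bridging-water
oxygen — the water is the geometrically conserved element of a bridge, and
it is what overlays of many sites actually display.

**Motifs.** direct/reverse are distinguished purely by the sequence order
of the carbonyl vs amide residues, with a loop window |i − j| ≤ 3
(configurable; the motifs live on one loop, but the source literature does
not pin the exact window). The asp rule admits Asp/Glu/Asn/Gln side-chain
oxygens plus the Ser/Cys hydroxyl/thiol variant, and takes priority over
the backbone-only rules when both fire (configurable). Candidates spanning
two chains are rejected. The extended single-residue variant is
implemented with the chemically consistent role assignment — backbone
carbonyl O accepts from N6 on the Hoogsteen side while the same residue's
amide N donates to N7 — because the alternative pairing (amide↔N6,
carbonyl↔N7) would put two donors, and two acceptors, against each other.

**Site similarity and networks.** Sites are compared with no
re-superposition (the frames are already common): mutual-nearest-neighbour
matching within 1.0 Å, restricted to partners of the same element category
(N, O, S, or bridging water as its own category). The matched fraction
uses the *larger* site as denominator — the conservative reading of
"shared atoms" — and the edge criterion is fraction ≥ 0.6 AND matched-pair
RMSD < 0.3 Å, with sites of < 3 bonds excluded from the network (three
contacts are the minimum that anchors a rigid fragment). Relaxing either
threshold can only add edges; tests assert this monotonicity, which is the
behaviour one expects when exploring the strict-to-lax threshold range.
Theme participation is a property of the *residue* (any atom of a residue
inside the annotated range that hydrogen-bonds the fragment, directly or
through water); a theme edge requires participation at both endpoints.
Consensus binding modes aggregate interaction classes (fragment atom,
edge, partner descriptor, mediated flag) present in ≥ `min_share` of a
cluster's sites (default 1.0 — the mode shared by *every* member).

All orderings in outputs (components, tables, scripts) are fixed by size
then identifier, so reruns are byte-identical.

## The synthetic-data generator

The generator emulates the *geometry* of fragment recognition, not protein
structure: an adenine placed at its reference coordinates inside a minimal
ligand (a carbon caps N9 as a ribose stand-in), pseudo-residues of 3–4
heavy atoms planted at prescribed polar geometry (distance along the
idealized lone-pair/N–H direction, rotated in-plane by a stated angle),
waters for bridges, optional far decoy residues, Gaussian coordinate
jitter on the environment, and a random global rigid motion so that
superposition is always exercised. Partner backbones walk away from the
fragment, each step choosing the direction farthest from everything
already placed, staggered above/below the fragment plane by residue
parity.

Every generated structure passes a geometric audit before it is returned:
no inter-residue heavy-atom pair under 2.0 Å, and every *unplanned*
complementary polar pair (protein donor vs fragment acceptor, protein
acceptor vs fragment donor, waters vs everything except their own bridge)
at least 4.0 Å apart — i.e. 0.5 Å beyond the default detection threshold.
Infeasible plans raise instead of silently producing ambiguous truth.
Random recovery plans sample planted distances in 2.6–3.0 Å: within the
hydrogen-bond range, and leaving ≥ 5σ headroom below the 3.5 Å cutoff at
the σ = 0.1 Å jitter these fixtures use, so a planted bond is never lost
to noise. First-turn antecedent atoms are placed at ≥ 115° in-plane for
the same reason (≥ 4σ above the 90° angle criterion).

Site families draw three planted partners from a fixed pool of ten
well-separated placements (≥ 2.2 Å apart — 45° of arc at 2.9 Å, or
different fragment atoms). Any two families share at most one placement,
so cross-family sites can match in at most 1 of 3 partners (fraction 1/3,
below the 0.6 threshold) while members of one family at σ = 0.05 Å match
completely. The pool and its 12-triple packing were derived from the
fragment geometry with the audit as the feasibility check. At σ = 1.0 Å
within-family partner RMSD far exceeds the 0.3 Å edge threshold and the
families disintegrate — the generator covers both regimes.

**What passing tests do and do not show.** The fixtures have no folds, no
sterics beyond a clash floor, no competing polar atoms near the planted
margin, and idealized bond geometry. Recovery sensitivity of 1.0 on them
demonstrates that the *detection logic* is correct at its stated
thresholds — not that those thresholds are optimal for real crystal
structures, where resolution limits, alternate conformations and
near-threshold contacts blur every criterion. Likewise, perfect family
recovery shows the network machinery separates what its thresholds say it
should separate; real binding-site families overlap far more.

## Numerical choices and degenerate inputs

- Altloc policy: highest occupancy, ties toward 'A'. First model only.
- PDB writer rejects coordinates outside the fixed-width field range.
- Empty sites compare with fraction 0 and RMSD +inf (never an edge).
- Mutual-NN matching breaks distance ties by lowest index; the matched
  pair set is symmetric under argument swap by construction.
- Proper-rotation and orthogonality invariants on transforms are enforced
  at 1e-8; transforms passed into site assembly are validated against the
  instance they claim to superpose (residual < 0.75 Å).
- Seeds: every generator is a pure function of (plan, seed); derived seeds
  stay below 2³¹.

## Problem sizes

Default test and acceptance runs use 100 recovery plans, 4 families × 6
members (24 complexes) for network recovery, 10 × 10 for the large-cluster
report, and an enrichment corpus of 10⁵ entries — sizes at which every
statistic in the suite is stable to well within its asserted tolerance
while the whole suite completes in seconds.

## Known limitations

- Only single-model, single-altloc views of a structure are analyzed;
  NMR ensembles and symmetry mates are out of scope.
- The fragment must be rigid and planar; flexible or puckered fragments
  would need a different superposition and edge model.
- Aromatic stacking, cation–π and halogen bonds are not detected — the
  package is about polar contacts.
- Theme discovery itself is out of scope; themes are consumed as
  annotations (id, chain, residue range) produced elsewhere.
- The heavy-atom hydrogen-bond criterion cannot distinguish donor from
  acceptor on ambivalent protein atoms (Ser/Thr/Tyr OH, His N); roles are
  assigned by complementarity with the fragment atom.
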