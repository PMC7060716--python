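# fragbind

Profiling how proteins hydrogen-bond a **rigid ligand fragment** — by
default the adenine moiety shared by the nucleotide cofactors ATP, NAD,
FAD, SAM and CoA.

Structural biologists comparing many protein–cofactor complexes face a
recurring problem: the proteins may share no sequence or fold similarity,
so their binding sites cannot be aligned directly. fragbind sidesteps the
proteins entirely and aligns on the one thing every complex shares — the
rigid fragment itself. Once all complexes are expressed in the fragment's
frame, hydrogen-bonding geometry becomes directly comparable across the
whole set.

## What it computes

For each complex (PDB format):

1. **Fragment detection** — element-labeled subgraph isomorphism of the
   fragment graph (adenine: N1, C2, N3, C4, C5, C6, N6, N7, C8, N9) into
   the ligand's bond graph, with bonds inferred from interatomic distances.
2. **Superposition** — the least-squares rigid transform (Kabsch, SVD with
   reflection rejection) mapping the found instance onto canonical
   reference coordinates; `min_R,t √(1/n Σᵢ ‖R xᵢ + t − yᵢ‖²)` over the 10
   mapped heavy atoms.
3. **Interaction site** — direct hydrogen bonds (heavy-atom donor–acceptor
   distance ≤ 3.5 Å by default, antecedent angle X–D···A ≥ 90°) and
   single-water-mediated bridges between the fragment and the protein, with
   every bond assigned to one of the purine's three binding edges
   (Watson–Crick: N1/N6; Hoogsteen: N6/N7; sugar: N3).
4. **Motifs** — the classic adenine-binding loop motifs on the
   Watson–Crick edge: *direct* (backbone carbonyl *i* → N6, amide *j* → N1,
   i < j), *reverse* (mirrored order), *asp* (side-chain O/S at position
   II, including the Ser/Cys variant), plus two extended variants
   (reverse + downstream Hoogsteen carbonyl at offset 22–23; the
   single-residue N6-Hoogsteen/N7 pattern).
5. **Networks** — the interaction-site similarity network (nodes: sites
   with ≥ 3 hydrogen bonds; edge when ≥ 60% of partner atoms match by
   mutual nearest neighbours with RMSD < 0.3 Å in the common frame), its
   connected components and large clusters; the theme-sharing network
   (edge when a sequence *theme* annotation hydrogen-bonds the fragment in
   both complexes); per-cluster consensus binding modes; and fold
   enrichment `P(fragment ligand | theme) / P(fragment ligand)` over a
   structure corpus.

A synthetic-data module generates complete PDB fixtures with planted
hydrogen bonds, motif geometries, site families and theme annotations, and
returns the exact planted truth — the test oracle for the whole pipeline.

## Worked example

Generate 30 synthetic complexes (six motif fixtures plus four site
families of six members), scan them, and build the similarity network:

```sh
fragbind simulate --out demo/fixtures --n-per-motif 1 --families 4 --members 6 --seed 7
# wrote 30 structures to demo/fixtures
fragbind scan demo/fixtures/*.pdb --out demo/scan
# 30 site(s) from 30 file(s) processed, 0 skipped
fragbind network demo/fixtures/*.pdb --out demo/net
# network: 25 nodes, 60 edges, 5 components
```

`demo/scan/hbonds.tsv` holds one row per hydrogen bond; e.g. the planted
Asp-motif fixture yields

```
complex_id  fragment_atom  edge          partner_descriptor  partner_residue  direction          distance
asp_0       N1             watson_crick  backbone_N          GLY              fragment_accepts   2.9
asp_0       N6             watson_crick  sidechain_O         ASP              fragment_donates   2.9
```

— the backbone amide donating to N1 and the aspartate carboxylate
accepting from N6, both on the Watson–Crick edge, exactly as planted. The
network run recovers the four planted families as four separate components
(the 25 nodes are the 24 family members, which carry three bonds each and
therefore qualify, plus one three-bond motif fixture; the five components
are the four families plus that singleton). `fragbind themes` adds the
theme network, consensus binding modes and enrichment when annotation/corpus
tables are supplied.

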