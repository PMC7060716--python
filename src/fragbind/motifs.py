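"""Classification of adenine-binding motifs.

Three classic loop motifs recognise the Watson–Crick edge (N1 + N6) of
adenine through a backbone carbonyl accepting from N6 and a backbone amide
donating to N1:

* **direct** — carbonyl residue *i* precedes the amide residue *j* in
  sequence (i < j, within a short loop window);
* **reverse** — the mirrored order (i > j);
* **asp** — a side-chain oxygen (classically an Asp carboxylate, also
  Glu/Asn/Gln, and the Ser/Cys hydroxyl/thiol variant) replaces the carbonyl
  at position II.

Two extended variants are recognised on top: the reverse motif plus an extra
backbone carbonyl 22–23 residues downstream accepting from N6 on the
Hoogsteen edge, and a single-residue pattern whose backbone carbonyl accepts
from N6 on the Hoogsteen edge while its amide donates to N7 (the SET-domain
pattern).  For the latter the donor/acceptor roles follow from the
heavy-atom chemistry: N6 (amine) donates, N7 accepts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .fragment import EdgeLabel
from .interactions import HBond, InteractionSite
from .structio import ComplexStructure

__all__ = [
    "MotifCall",
    "MotifParams",
    "classify_motif",
    "detect_extended_variants",
    "tabulate_motifs",
]

ASP_LIKE_RESIDUES = {"ASP", "GLU", "ASN", "GLN", "SER", "CYS"}
SER_CYS = {"SER", "CYS"}

ResidueRef = tuple[str, int]  # (chain_id, residue_seq)


@dataclass
class MotifParams:
    """Tunable windows of the motif rules.

    ``loop_window`` is the maximum sequence separation |i - j| between the
    carbonyl and amide residues of the direct/reverse motifs (the motif lives
    on one loop).  ``downstream_offsets`` are the accepted sequence offsets of
    the extra Hoogsteen carbonyl in the extended reverse variant.
    ``asp_priority`` keeps the side-chain (asp) reading when a site satisfies
    both the asp and a backbone-only rule.
    """

    loop_window: int = 3
    downstream_offsets: tuple[int, ...] = (22, 23)
    asp_priority: bool = True


@dataclass
class MotifCall:
    """The motif assignment of one interaction site."""

    label: str  # direct | reverse | asp | other
    position_I: Optional[ResidueRef] = None  # carbonyl residue (backbone motifs)
    position_II: Optional[ResidueRef] = None  # side-chain residue (asp motif)
    position_III: Optional[ResidueRef] = None  # amide residue donating to N1
    variants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.label == "other" and any(
            (self.position_I, self.position_II, self.position_III)
        ):
            raise ValueError("'other' carries no positions")
        if self.label == "asp" and self.position_II is None:
            raise ValueError("asp motif requires position_II")


def _wc_n6_bonds(site: InteractionSite) -> list[HBond]:
    return [
        hb
        for hb in site.hbonds
        if hb.fragment_atom == "N6"
        and hb.edge == EdgeLabel.WATSON_CRICK
        and not hb.water_mediated
    ]


def _n1_amide_bonds(site: InteractionSite) -> list[HBond]:
    return [
        hb
        for hb in site.hbonds
        if hb.fragment_atom == "N1"
        and hb.partner_descriptor == "backbone_N"
        and not hb.water_mediated
    ]


def _ref(hb: HBond) -> ResidueRef:
    return (hb.partner_chain_id, hb.partner_residue_seq)


def classify_motif(
    site: InteractionSite,
    cs: ComplexStructure | None = None,
    params: MotifParams | None = None,
) -> MotifCall:
    """Assign direct / reverse / asp / other to one interaction site.

    Rules are checked in priority order asp > direct > reverse; candidates
    whose two bonds sit on different chains are rejected.  The result is
    independent of hydrogen-bond list order: among multiple satisfying bond
    pairs the one with smallest (carbonyl seq, amide seq) wins.
    """
    params = params or MotifParams()
    amides = _n1_amide_bonds(site)
    n6_bonds = _wc_n6_bonds(site)

    def candidates(kind: str) -> list[tuple[ResidueRef, ResidueRef]]:
        found = []
        for n6 in n6_bonds:
            for n1 in amides:
                if n6.partner_chain_id != n1.partner_chain_id:
                    continue
                i, j = n6.partner_residue_seq, n1.partner_residue_seq
                if kind == "asp":
                    if (
                        n6.partner_descriptor in ("sidechain_O", "sidechain_S")
                        and n6.partner_residue_name in ASP_LIKE_RESIDUES
                    ):
                        found.append((_ref(n6), _ref(n1)))
                elif n6.partner_descriptor == "backbone_O":
                    if kind == "direct" and i < j and j - i <= params.loop_window:
                        found.append((_ref(n6), _ref(n1)))
                    elif kind == "reverse" and i > j and i - j <= params.loop_window:
                        found.append((_ref(n6), _ref(n1)))
        return sorted(found, key=lambda pair: (pair[0][1], pair[1][1]))

    order = ["asp", "direct", "reverse"] if params.asp_priority else [
        "direct", "reverse", "asp"
    ]
    for kind in order:
        cand = candidates(kind)
        if not cand:
            continue
        carbonyl_or_sidechain, amide = cand[0]
        if kind == "asp":
            residue_name = next(
                hb.partner_residue_name
                for hb in n6_bonds
                if _ref(hb) == carbonyl_or_sidechain
            )
            variants = {"asp_ser_cys"} if residue_name in SER_CYS else set()
            return MotifCall(
                label="asp",
                position_II=carbonyl_or_sidechain,
                position_III=amide,
                variants=variants,
            )
        return MotifCall(
            label=kind, position_I=carbonyl_or_sidechain, position_III=amide
        )
    return MotifCall(label="other")


def detect_extended_variants(
    site: InteractionSite,
    cs: ComplexStructure | None = None,
    call: MotifCall | None = None,
    params: MotifParams | None = None,
) -> MotifCall:
    """Annotate a motif call with the extended binding variants.

    ``reverse_plus_hoogsteen_XV_XVI``: a reverse motif with an additional
    backbone carbonyl, 22–23 residues downstream of the motif residues on
    the same chain, accepting from N6 on the Hoogsteen edge.

    ``position_III_hoogsteen``: one residue whose backbone carbonyl accepts
    from N6 (Hoogsteen side) while its backbone amide donates to N7 —
    recognised regardless of the primary label.
    """
    params = params or MotifParams()
    if call is None:
        call = classify_motif(site, cs, params)

    hoog_n6 = [
        hb
        for hb in site.hbonds
        if hb.fragment_atom == "N6"
        and hb.edge == EdgeLabel.HOOGSTEEN
        and hb.partner_descriptor == "backbone_O"
        and not hb.water_mediated
    ]

    if call.label == "reverse" and call.position_I is not None:
        chain, anchor = call.position_I
        anchor = max(anchor, call.position_III[1] if call.position_III else anchor)
        for hb in hoog_n6:
            if (
                hb.partner_chain_id == chain
                and hb.partner_residue_seq - anchor in params.downstream_offsets
            ):
                call.variants.add("reverse_plus_hoogsteen_XV_XVI")
                break

    n7_amides = {
        _ref(hb)
        for hb in site.hbonds
        if hb.fragment_atom == "N7"
        and hb.partner_descriptor == "backbone_N"
        and not hb.water_mediated
    }
    for hb in hoog_n6:
        if _ref(hb) in n7_amides:
            call.variants.add("position_III_hoogsteen")
            break
    return call


def tabulate_motifs(
    calls: Iterable[tuple[str, MotifCall]]
) -> pd.DataFrame:
    """Counts and row percentages per cofactor class and motif label."""
    labels = ["direct", "reverse", "asp", "other"]
    counts: dict[str, Counter] = {}
    for cofactor_class, call in calls:
        counts.setdefault(cofactor_class, Counter())[call.label] += 1
    rows = []
    for cls in sorted(counts):
        row: dict[str, object] = {"cofactor_class": cls}
        total = sum(counts[cls].values())
        for lab in labels:
            n = counts[cls].get(lab, 0)
            row[lab] = n
            row[f"{lab}_pct"] = round(100.0 * n / total, 1) if total else 0.0
        row["total"] = total
        rows.append(row)
    cols = (
        ["cofactor_class"]
        + labels
        + [f"{lab}_pct" for lab in labels]
        + ["total"]
    )
    return pd.DataFrame(rows, columns=cols)
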