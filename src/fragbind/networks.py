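"""Interaction-site similarity and theme-sharing networks.

Once every complex's hydrogen-bond partners are expressed in the canonical
fragment frame, two complexes can be compared without any further
superposition: partner atoms are matched by mutual nearest neighbours and
two sites are *similar* when a large enough fraction of their atoms match
(default >= 60%) with a small enough RMSD (default < 0.3 Å).  Sites with at
least three hydrogen bonds — the minimum to anchor a rigid fragment — become
nodes of the similarity network; connected components group protein families
sharing a binding pattern.

A *theme* (a recurring sequence segment of roughly 35–200 residues) is said
to participate in a site when at least one residue in its range
hydrogen-bonds the fragment; the theme network connects two sites that share
a participating theme.  Enrichment of fragment-bearing ligands among
theme-containing corpus entries is summarised as a fold ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactions import InteractionSite

__all__ = [
    "SiteSimilarity",
    "ThemeAnnotation",
    "EnrichmentResult",
    "NetworkParams",
    "site_similarity",
    "build_site_network",
    "connected_components",
    "build_theme_network",
    "cluster_consensus",
    "theme_enrichment",
    "report_large_clusters",
    "read_theme_annotations",
]


@dataclass
class NetworkParams:
    min_hbonds: int = 3
    min_fraction: float = 0.6
    max_rmsd: float = 0.3  # Å
    match_cutoff: float = 1.0  # Å
    category_restricted: bool = True


@dataclass(frozen=True)
class SiteSimilarity:
    """Geometric agreement of two interaction sites in the common frame."""

    matched_pairs: tuple[tuple[int, int], ...]
    matched_fraction: float
    partner_rmsd: float  # +inf when no pair matched


@dataclass(frozen=True)
class ThemeAnnotation:
    """One theme occurrence: an inclusive residue range on one chain."""

    theme_id: int
    complex_id: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, residue_seq: int) -> bool:
        return self.start <= residue_seq <= self.end


@dataclass(frozen=True)
class EnrichmentResult:
    n_entries: int
    n_with_ligand: int
    n_theme_entries: int
    n_theme_with_ligand: int
    background_fraction: float
    theme_fraction: float
    fold: float


def _mutual_nearest_pairs(
    A: np.ndarray, B: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs within cutoff; deterministic order."""
    if len(A) == 0 or len(B) == 0:
        return []
    D = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    nn_a = D.argmin(axis=1)
    nn_b = D.argmin(axis=0)
    pairs = [
        (i, int(nn_a[i]))
        for i in range(len(A))
        if nn_b[nn_a[i]] == i and D[i, nn_a[i]] <= cutoff
    ]
    return pairs


def site_similarity(
    a: InteractionSite,
    b: InteractionSite,
    match_cutoff: float = 1.0,
    category_restricted: bool = True,
) -> SiteSimilarity:
    """Match two sites' canonical partner positions and score the overlap.

    Matching is greedy mutual-nearest-neighbour within ``match_cutoff``,
    restricted (by default) to partners of the same element category — N, O,
    S, or bridging water.  ``matched_fraction`` uses the larger site as
    denominator (conservative); ``partner_rmsd`` is computed over matched
    pairs with no re-superposition, since both sites already live in the
    canonical fragment frame.  The score is symmetric in its arguments.
    """
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return SiteSimilarity((), 0.0, math.inf)
    A = np.asarray(a.partner_coords_canonical, dtype=float)
    B = np.asarray(b.partner_coords_canonical, dtype=float)
    cats_a = [hb.match_category for hb in a.hbonds]
    cats_b = [hb.match_category for hb in b.hbonds]

    pairs: list[tuple[int, int]] = []
    if category_restricted:
        for cat in sorted(set(cats_a) & set(cats_b)):
            ia = [i for i, c in enumerate(cats_a) if c == cat]
            ib = [j for j, c in enumerate(cats_b) if c == cat]
            for i, j in _mutual_nearest_pairs(A[ia], B[ib], match_cutoff):
                pairs.append((ia[i], ib[j]))
    else:
        pairs = _mutual_nearest_pairs(A, B, match_cutoff)
    pairs.sort()

    fraction = len(pairs) / max(na, nb)
    if pairs:
        diffs = np.array([A[i] - B[j] for i, j in pairs])
        rmsd = float(np.sqrt(np.mean(np.sum(diffs**2, axis=1))))
    else:
        rmsd = math.inf
    return SiteSimilarity(tuple(pairs), fraction, rmsd)


def build_site_network(
    sites: Sequence[InteractionSite],
    min_hbonds: int = 3,
    min_fraction: float = 0.6,
    max_rmsd: float = 0.3,
    match_cutoff: float = 1.0,
    category_restricted: bool = True,
) -> nx.Graph:
    """Similarity network over sites with at least ``min_hbonds`` bonds.

    Nodes carry cofactor class, motif/family attributes copied from each
    site's ``node_attrs``; an edge joins two sites whose matched fraction
    reaches ``min_fraction`` with partner RMSD below ``max_rmsd``.
    """
    g = nx.Graph(kind="site_similarity")
    kept = [s for s in sites if len(s) >= min_hbonds]
    for s in kept:
        g.add_node(
            s.node_id,
            cofactor_class=s.instance.cofactor_class,
            n_hbonds=len(s),
            **s.node_attrs,
        )
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            sim = site_similarity(
                kept[i], kept[j], match_cutoff, category_restricted
            )
            if sim.matched_fraction >= min_fraction and sim.partner_rmsd < max_rmsd:
                g.add_edge(
                    kept[i].node_id,
                    kept[j].node_id,
                    matched_fraction=round(sim.matched_fraction, 4),
                    partner_rmsd=round(sim.partner_rmsd, 4),
                )
    return g


def connected_components(net: nx.Graph) -> list[list[str]]:
    """Components ordered by size (descending), then smallest node id."""
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def build_theme_network(
    sites: Sequence[InteractionSite],
    annotations: Iterable[ThemeAnnotation],
) -> nx.Graph:
    """Connect two sites when a theme participates in both.

    A theme participates in a site when at least one residue of its range on
    the annotated chain is among the site's hydrogen-bonding residues
    (direct or water-mediated; participation is a property of the residue,
    not of a particular atom).  Annotations naming unknown complexes are
    skipped with a node-less warning attribute rather than an error.
    """
    by_complex: dict[str, list[InteractionSite]] = {}
    for s in sites:
        by_complex.setdefault(s.complex_id, []).append(s)

    g = nx.Graph(kind="theme_sharing")
    for s in sites:
        g.add_node(s.node_id, cofactor_class=s.instance.cofactor_class, **s.node_attrs)

    participants: dict[int, list[str]] = {}
    skipped: list[str] = []
    for ann in annotations:
        if ann.complex_id not in by_complex:
            skipped.append(ann.complex_id)
            continue
        for s in by_complex[ann.complex_id]:
            hits = any(
                chain == ann.chain_id and ann.covers(seq)
                for chain, seq in s.partner_residues()
            )
            if hits:
                participants.setdefault(ann.theme_id, []).append(s.node_id)
    g.graph["skipped_annotations"] = ",".join(sorted(set(skipped)))

    for theme_id in sorted(participants):
        nodes = sorted(set(participants[theme_id]))
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if g.has_edge(nodes[i], nodes[j]):
                    g.edges[nodes[i], nodes[j]]["themes"] = (
                        g.edges[nodes[i], nodes[j]]["themes"] + f",{theme_id}"
                    )
                else:
                    g.add_edge(nodes[i], nodes[j], themes=str(theme_id))
    return g


def cluster_consensus(
    sites_in_cluster: Sequence[InteractionSite],
    min_share: float = 1.0,
) -> pd.DataFrame:
    """Interaction classes shared by (a fraction of) a cluster's sites.

    An interaction class is (fragment_atom, edge, partner descriptor,
    water-mediated flag).  With the default ``min_share`` of 1.0 the
    consensus is the binding mode common to every member.  Returns one row
    per retained class with its support, mean canonical partner position and
    spread (RMS deviation from the mean).
    """
    if not sites_in_cluster:
        raise ValueError("empty cluster")
    if len(sites_in_cluster) < 2:
        raise ValueError("consensus requires at least two sites")
    classes: dict[tuple, list[np.ndarray]] = {}
    support: dict[tuple, int] = {}
    for s in sites_in_cluster:
        seen: dict[tuple, list[np.ndarray]] = {}
        for hb, xyz in zip(s.hbonds, s.partner_coords_canonical):
            cls = (
                hb.fragment_atom,
                str(hb.edge),
                hb.partner_descriptor,
                hb.water_mediated,
            )
            seen.setdefault(cls, []).append(xyz)
        for cls, pts in seen.items():
            support[cls] = support.get(cls, 0) + 1
            classes.setdefault(cls, []).extend(pts)

    n = len(sites_in_cluster)
    rows = []
    for cls in sorted(classes):
        share = support[cls] / n
        if share + 1e-12 < min_share:
            continue
        pts = np.asarray(classes[cls])
        mean = pts.mean(axis=0)
        spread = float(np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1))))
        rows.append(
            {
                "fragment_atom": cls[0],
                "edge": cls[1],
                "partner_descriptor": cls[2],
                "water_mediated": cls[3],
                "share": round(share, 4),
                "mean_x": round(float(mean[0]), 4),
                "mean_y": round(float(mean[1]), 4),
                "mean_z": round(float(mean[2]), 4),
                "spread": round(spread, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fragment_atom", "edge", "partner_descriptor", "water_mediated",
            "share", "mean_x", "mean_y", "mean_z", "spread",
        ],
    )


def theme_enrichment(corpus: pd.DataFrame) -> EnrichmentResult:
    """Fold enrichment of fragment ligands among theme-containing entries.

    ``corpus`` has one row per structure with boolean columns ``has_theme``
    and ``has_fragment_ligand``; the fold is
    P(ligand | theme) / P(ligand).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    theme = corpus[corpus["has_theme"].astype(bool)]
    if len(theme) == 0:
        raise ValueError("corpus has no theme entries")
    n = len(corpus)
    n_lig = int(corpus["has_fragment_ligand"].astype(bool).sum())
    n_theme = len(theme)
    n_theme_lig = int(theme["has_fragment_ligand"].astype(bool).sum())
    background = n_lig / n
    theme_frac = n_theme_lig / n_theme
    fold = theme_frac / background if background > 0 else math.inf
    return EnrichmentResult(
        n_entries=n,
        n_with_ligand=n_lig,
        n_theme_entries=n_theme,
        n_theme_with_ligand=n_theme_lig,
        background_fraction=background,
        theme_fraction=theme_frac,
        fold=fold,
    )


def report_large_clusters(net: nx.Graph, min_size: int = 10) -> list[dict]:
    """Connected components of at least ``min_size`` nodes, ranked by size."""
    out = []
    for rank, comp in enumerate(
        [c for c in connected_components(net) if len(c) >= min_size], start=1
    ):
        out.append({"rank": rank, "size": len(comp), "nodes": comp})
    return out


def read_theme_annotations(path) -> list[ThemeAnnotation]:
    """Read a theme annotation TSV (theme_id, complex_id, chain, start, end)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ThemeAnnotation(
                theme_id=int(row.theme_id),
                complex_id=str(row.complex_id),
                chain_id=str(row.chain),
                start=int(row.start),
                end=int(row.end),
            )
        )
    return out
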