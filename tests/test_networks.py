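import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fragbind.geometry import match_fragment
from fragbind.interactions import build_site
from fragbind.networks import (
    ThemeAnnotation,
    build_site_network,
    build_theme_network,
    cluster_consensus,
    connected_components,
    report_large_clusters,
    site_similarity,
    theme_enrichment,
)
from fragbind.synthdata import (
    PlannedBond,
    SitePlan,
    ThemeFixtureEntry,
    generate_corpus,
    generate_family_dataset,
    generate_site,
    generate_theme_fixture,
)


def _sites(structs, adenine):
    out = []
    for cs in structs:
        inst = match_fragment(cs, cs.ligand_instances[0], adenine)[0]
        out.append(build_site(cs, inst, adenine))
    return out


def _standard_site(adenine, site_from_structure, seed, extra=(), displace=None):
    bonds = [
        PlannedBond("N1", "backbone_N", 2.9, 0.0, residue_seq=10),
        PlannedBond("N6", "backbone_O", 2.9, 30.0, residue_seq=20),
        PlannedBond("N7", "backbone_N", 2.9, 0.0, residue_seq=30),
    ] + list(extra)
    cs, _ = generate_site(SitePlan(tuple(bonds), seed=seed))
    site = site_from_structure(cs)
    if displace is not None:
        idx, delta = displace
        site.partner_coords_canonical[idx] = site.partner_coords_canonical[idx] + delta
    return site


class TestSiteSimilarity:
    def test_identical_sites(self, adenine, site_from_structure):
        a = _standard_site(adenine, site_from_structure, seed=1)
        b = _standard_site(adenine, site_from_structure, seed=2)
        sim = site_similarity(a, b)
        assert sim.matched_fraction == pytest.approx(1.0)
        assert sim.partner_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_two_of_three_shared(self, adenine, site_from_structure):
        a = _standard_site(adenine, site_from_structure, seed=3)
        b = _standard_site(adenine, site_from_structure, seed=4,
                           displace=(2, np.array([5.0, 0, 0])))
        sim = site_similarity(a, b)
        assert sim.matched_fraction == pytest.approx(2 / 3)
        assert sim.matched_fraction >= 0.6

    def test_three_of_five_uses_larger_denominator(self, adenine, site_from_structure):
        from fragbind.fragment import EdgeLabel
        from fragbind.interactions import HBond

        a = _standard_site(adenine, site_from_structure, seed=5)
        b = _standard_site(adenine, site_from_structure, seed=6)
        # extend b with two partners far from anything a has
        for k, (atom, edge) in enumerate([("N3", EdgeLabel.SUGAR), ("N6", EdgeLabel.HOOGSTEEN)]):
            b.hbonds.append(
                HBond(
                    fragment_atom=atom, edge=edge, partner_serial=900 + k,
                    partner_descriptor="backbone_N", direction="fragment_accepts",
                    distance=2.9, partner_chain_id="A", partner_residue_seq=90 + k,
                    partner_residue_name="GLY",
                )
            )
            b.partner_coords_canonical.append(np.array([10.0 + 5 * k, -10.0, 0.0]))
        sim = site_similarity(a, b)
        assert len(sim.matched_pairs) == 3
        assert sim.matched_fraction == pytest.approx(3 / 5)

    def test_symmetry(self, adenine, site_from_structure):
        a = _standard_site(adenine, site_from_structure, seed=7,
                           displace=(0, np.array([0.2, 0.1, 0.0])))
        b = _standard_site(adenine, site_from_structure, seed=8)
        s1, s2 = site_similarity(a, b), site_similarity(b, a)
        assert s1.matched_fraction == s2.matched_fraction
        assert s1.partner_rmsd == s2.partner_rmsd

    def test_empty_site(self, adenine, site_from_structure):
        from fragbind.interactions import InteractionSite

        a = _standard_site(adenine, site_from_structure, seed=9)
        empty = InteractionSite(a.complex_id, a.instance, [], [])
        sim = site_similarity(a, empty)
        assert sim.matched_fraction == 0.0
        assert math.isinf(sim.partner_rmsd)

    def test_water_partners_match_as_own_category(self, adenine, site_from_structure):
        a = _standard_site(
            adenine, site_from_structure, seed=10,
            extra=[PlannedBond("N3", "backbone_N", 2.9, -45.0, residue_seq=44, mediated=True)],
        )
        b = _standard_site(adenine, site_from_structure, seed=11)
        sim = site_similarity(a, b)
        assert sim.matched_fraction == pytest.approx(3 / 4)


class TestSiteNetwork:
    def test_min_hbonds_excludes_small_sites(self, adenine, site_from_structure):
        cs, _ = generate_site(
            SitePlan((PlannedBond("N1", "backbone_N", 2.9, 0.0),
                      PlannedBond("N6", "backbone_O", 2.9, 30.0, residue_seq=20)), seed=12)
        )
        small = site_from_structure(cs)
        full = _standard_site(adenine, site_from_structure, seed=13)
        net = build_site_network([small, full])
        assert net.number_of_nodes() == 1
        assert full.node_id in net

    def test_rmsd_threshold_branches(self, adenine, site_from_structure):
        a = _standard_site(adenine, site_from_structure, seed=14)
        shift = np.array([0.4, 0.0, 0.0]) / math.sqrt(3)
        b = _standard_site(adenine, site_from_structure, seed=15)
        for i in range(3):
            b.partner_coords_canonical[i] = b.partner_coords_canonical[i] + np.array([0.4, 0, 0])
        assert site_similarity(a, b).partner_rmsd == pytest.approx(0.4, abs=1e-9)
        assert build_site_network([a, b]).number_of_edges() == 0  # 0.4 > 0.3
        for i in range(3):
            b.partner_coords_canonical[i] = b.partner_coords_canonical[i] - np.array([0.2, 0, 0])
        assert build_site_network([a, b]).number_of_edges() == 1  # 0.2 < 0.3

    def test_edges_monotone_under_threshold_relaxation(self, adenine, site_from_structure):
        rng = np.random.default_rng(0)
        sites = []
        for seed in range(8):
            s = _standard_site(adenine, site_from_structure, seed=30 + seed)
            for i in range(3):
                s.partner_coords_canonical[i] = (
                    s.partner_coords_canonical[i] + rng.normal(0, 0.25, 3)
                )
            sites.append(s)
        strict = build_site_network(sites, min_fraction=0.7, max_rmsd=0.25)
        lax = build_site_network(sites, min_fraction=0.6, max_rmsd=0.45)
        assert set(strict.edges) <= set(lax.edges)

    def test_family_components_recovered(self, adenine):
        structs, fams = generate_family_dataset(4, 6, sigma_within=0.05, seed=1)
        sites = _sites(structs, adenine)
        net = build_site_network(sites)
        comps = connected_components(net)
        assert len(comps) == 4
        node_fam = {s.node_id: fams[s.complex_id] for s in sites}
        lt, lp = [], []
        for ci, comp in enumerate(comps):
            for n in comp:
                lt.append(node_fam[n])
                lp.append(ci)
        assert adjusted_rand_score(lt, lp) == pytest.approx(1.0)

    def test_high_jitter_breaks_families(self, adenine):
        structs, fams = generate_family_dataset(4, 6, sigma_within=1.0, seed=1)
        sites = _sites(structs, adenine)
        net = build_site_network(sites)
        comps = connected_components(net)
        node_fam = {s.node_id: fams[s.complex_id] for s in sites}
        lt, lp = [], []
        for ci, comp in enumerate(comps):
            for n in comp:
                lt.append(node_fam[n])
                lp.append(ci)
        assert len(lt) < 24 or adjusted_rand_score(lt, lp) < 1.0

    def test_singletons_when_one_member_each(self, adenine):
        structs, _ = generate_family_dataset(3, 1, sigma_within=0.05, seed=5)
        sites = _sites(structs, adenine)
        net = build_site_network(sites)
        assert net.number_of_edges() == 0
        assert len(connected_components(net)) == 3


class TestComponents:
    def test_ordering_and_sizes(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        g.add_nodes_from(["z1", "z2", "z3", "z4", "z5"])
        comps = connected_components(g)
        assert comps[0] == ["a", "b", "c"]
        assert len(comps) == 6

    def test_large_cluster_report(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from((f"a{i}", f"a{i+1}") for i in range(11))  # 12 nodes
        g.add_edges_from((f"b{i}", f"b{i+1}") for i in range(8))  # 9 nodes
        g.add_edges_from([("c0", "c1"), ("c1", "c2")])  # 3 nodes
        assert len(report_large_clusters(g, 10)) == 1
        assert len(report_large_clusters(g, 3)) == 3  # every component >= 3

    def test_ten_planted_families_give_ten_large_clusters(self, adenine):
        structs, _ = generate_family_dataset(10, 10, sigma_within=0.05, seed=2)
        net = build_site_network(_sites(structs, adenine))
        assert len(report_large_clusters(net, 10)) == 10


class TestThemeNetwork:
    def test_dual_participation_required(self, adenine):
        entries = [
            ThemeFixtureEntry("t_a", ((1, True),)),
            ThemeFixtureEntry("t_b", ((1, True),)),
            ThemeFixtureEntry("t_c", ((1, False), (2, True))),
        ]
        structs, anns, truth = generate_theme_fixture(entries, seed=3)
        sites = _sites(structs, adenine)
        net = build_theme_network(sites, anns)
        got = {
            tuple(sorted((u.split("/")[0], v.split("/")[0]))) for u, v in net.edges
        }
        assert got == truth == {("t_a", "t_b")}

    def test_theme_present_but_nonbinding_gives_no_edge(self, adenine):
        entries = [
            ThemeFixtureEntry("x_a", ((5, True),)),
            ThemeFixtureEntry("x_b", ((5, False),)),
        ]
        structs, anns, truth = generate_theme_fixture(entries, seed=4)
        net = build_theme_network(_sites(structs, adenine), anns)
        assert net.number_of_edges() == 0 and truth == set()

    def test_mixed_fixture_recovers_exact_truth(self, adenine):
        rng_entries = [
            ThemeFixtureEntry(f"m{i}", tuple(
                (tid, (i + tid) % 3 != 0) for tid in (1, 2, 3) if (i + tid) % 2 == 0
            ))
            for i in range(10)
        ]
        structs, anns, truth = generate_theme_fixture(rng_entries, seed=5)
        net = build_theme_network(_sites(structs, adenine), anns)
        got = {
            tuple(sorted((u.split("/")[0], v.split("/")[0]))) for u, v in net.edges
        }
        assert got == truth

    def test_unknown_complex_annotation_skipped(self, adenine):
        structs, anns, _ = generate_theme_fixture(
            [ThemeFixtureEntry("k_a", ((1, True),))], seed=6
        )
        anns.append(ThemeAnnotation(9, "missing", "A", 1, 40))
        net = build_theme_network(_sites(structs, adenine), anns)
        assert net.graph["skipped_annotations"] == "missing"


class TestConsensus:
    def test_shared_class_retained(self, adenine, site_from_structure):
        sites = [_standard_site(adenine, site_from_structure, seed=s) for s in (40, 41, 42)]
        df = cluster_consensus(sites)
        assert set(df["fragment_atom"]) == {"N1", "N6", "N7"}
        assert (df["share"] == 1.0).all()

    def test_min_share_threshold(self, adenine, site_from_structure):
        extra = [PlannedBond("N3", "backbone_N", 2.9, 0.0, residue_seq=40)]
        sites = [
            _standard_site(adenine, site_from_structure, seed=50, extra=extra),
            _standard_site(adenine, site_from_structure, seed=51, extra=extra),
            _standard_site(adenine, site_from_structure, seed=52),
        ]
        strict = cluster_consensus(sites, min_share=1.0)
        assert "N3" not in set(strict["fragment_atom"])
        lax = cluster_consensus(sites, min_share=0.6)
        assert "N3" in set(lax["fragment_atom"])

    def test_planted_cluster_consensus_exact(self, adenine, site_from_structure):
        from fragbind.motifs import classify_motif

        sites = []
        for s in (60, 61, 62):
            from fragbind.synthdata import motif_plan

            cs, _ = generate_site(motif_plan("reverse", seed=s))
            sites.append(site_from_structure(cs))
        df = cluster_consensus(sites)
        classes = set(zip(df["fragment_atom"], df["partner_descriptor"]))
        assert classes == {("N6", "backbone_O"), ("N1", "backbone_N")}

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            cluster_consensus([])


class TestEnrichment:
    def test_worked_five_fold(self):
        rows = []
        for i in range(100):
            has_theme = i < 10
            has_lig = i < 5 or (10 <= i < 15)
            rows.append({"entry_id": i, "has_theme": has_theme, "has_fragment_ligand": has_lig})
        res = theme_enrichment(pd.DataFrame(rows))
        assert res.theme_fraction == pytest.approx(0.5)
        assert res.background_fraction == pytest.approx(0.1)
        assert res.fold == pytest.approx(5.0)

    def test_independent_corpus_fold_near_one(self):
        corpus = generate_corpus(100_000, p_theme=0.2, p_ligand=0.1, seed=77)
        res = theme_enrichment(corpus)
        assert abs(res.fold - 1.0) < 0.05

    def test_fully_dedicated_theme(self):
        df = pd.DataFrame(
            {
                "entry_id": range(10),
                "has_theme": [True] * 4 + [False] * 6,
                "has_fragment_ligand": [True] * 4 + [True] * 1 + [False] * 5,
            }
        )
        res = theme_enrichment(df)
        assert res.theme_fraction == pytest.approx(1.0)
        assert res.fold == pytest.approx(2.0)

    def test_zero_theme_entries_error(self):
        df = pd.DataFrame(
            {"entry_id": [1], "has_theme": [False], "has_fragment_ligand": [True]}
        )
        with pytest.raises(ValueError):
            theme_enrichment(df)
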