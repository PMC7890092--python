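"""CSPP network construction, edge scoring, organ labels, propagation, export."""
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from csppnet import cspp
from csppnet.chem import (
    Biotransformation,
    default_catalog,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)
from csppnet.cspp import (
    build_network,
    export_network,
    import_network,
    label_organ_of_max,
    propagate_annotations,
    score_edges,
)
from csppnet.spectra_io import Feature

from conftest import make_spectrum

OXY = [bt for bt in default_catalog() if bt.short_code == "OXY"][0]
MET = [bt for bt in default_catalog() if bt.short_code == "MET"][0]
HEX = [bt for bt in default_catalog() if bt.short_code == "HEX"][0]


def feature(fid, mz, rt, abundances=None):
    ab = abundances or {"stem:OH43:1": 1.0}
    return Feature(
        feature_id=fid, mz=mz, rt=rt, polarity="neg", instrument="FT",
        abundances=ab, sample_meta={s: (s.split(":")[0], s.split(":")[1]) for s in ab},
    )


class TestBuildNetwork:
    def test_oxygenation_edge_with_compliant_elution(self):
        """An oxygenated product eluting earlier than its substrate forms
        a CSPP edge."""
        feats = [feature("sub", 300.0, 14.0), feature("prod", 300.0 + 15.9949, 12.5)]
        net = build_network(feats, [OXY], require_spectra=False)
        assert set(net.edges(keys=True)) == {("sub", "prod", "OXY")}

    def test_elution_rule_violation_blocks_edge(self):
        feats = [feature("sub", 300.0, 14.0), feature("prod", 300.0 + 15.9949, 15.0)]
        net = build_network(feats, [OXY], require_spectra=False)
        assert net.number_of_edges() == 0

    def test_planted_chain_recovered_exactly(self):
        """A -MET-> B -HEX-> C with exact deltas and compliant RTs yields
        exactly those two edges."""
        m = 300.0
        feats = [
            feature("A", m, 10.0),
            feature("B", m + MET.delta_mass, 11.0),  # MET: product later
            feature("C", m + MET.delta_mass + HEX.delta_mass, 9.0),  # HEX: earlier
        ]
        net = build_network(feats, [MET, HEX], require_spectra=False)
        assert set(net.edges(keys=True)) == {("A", "B", "MET"), ("B", "C", "HEX")}

    def test_require_spectra_restricts_nodes(self):
        feats = [feature("sub", 300.0, 14.0), feature("prod", 315.9949, 12.5)]
        net = build_network(feats, [OXY], require_spectra=True,
                            feature_spectra={"sub": ["s1"]})
        assert set(net.nodes) == {"sub"}
        assert net.number_of_edges() == 0

    def test_every_edge_satisfies_mass_and_rt_constraints(self, small_sim):
        cfg = small_sim.config
        ft = small_sim.subdbs["FTMS_neg"]
        net = build_network(ft.features, cfg.catalog(), mass_tol=0.002,
                            feature_spectra=ft.feature_spectra)
        catalog = {bt.short_code: bt for bt in cfg.catalog()}
        feats = {f.feature_id: f for f in ft.features}
        assert net.number_of_edges() > 0
        for u, v, code, data in net.edges(keys=True, data=True):
            assert u != v
            bt = catalog[code]
            sub, prod = feats[u], feats[v]
            assert prod.mz > sub.mz
            assert abs(prod.mz - sub.mz - bt.delta_mass) <= 0.002
            assert abs(data["mass_error"]) <= 0.002
            if bt.rt_rule == "product_earlier":
                assert prod.rt < sub.rt
            elif bt.rt_rule == "product_later":
                assert prod.rt > sub.rt

    def test_edge_set_invariant_under_feature_order(self, rng):
        feats = [feature(f"f{i}", mz, rt)
                 for i, (mz, rt) in enumerate(zip(rng.uniform(100, 900, 60),
                                                  rng.uniform(1, 29, 60)))]
        net1 = build_network(feats, default_catalog(), require_spectra=False)
        perm = list(feats)
        rng.shuffle(perm)
        net2 = build_network(perm, default_catalog(), require_spectra=False)
        assert set(net1.edges(keys=True)) == set(net2.edges(keys=True))

    def test_windowed_search_equals_brute_force(self, rng):
        n = 300
        feats = [feature(f"f{i}", mz, rt)
                 for i, (mz, rt) in enumerate(zip(rng.uniform(100, 1000, n),
                                                  rng.uniform(0.5, 29.5, n)))]
        catalog = default_catalog()
        net = build_network(feats, catalog, mass_tol=0.01, require_spectra=False)
        brute = set()
        for a, b in combinations(feats, 2):
            sub, prod = (a, b) if a.mz < b.mz else (b, a)
            for bt in catalog:
                if abs(prod.mz - sub.mz - bt.delta_mass) > 0.01:
                    continue
                if bt.rt_rule == "product_earlier" and not prod.rt < sub.rt:
                    continue
                if bt.rt_rule == "product_later" and not prod.rt > sub.rt:
                    continue
                brute.add((sub.feature_id, prod.feature_id, bt.short_code))
        assert set(net.edges(keys=True)) == brute

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            build_network([feature("a", 300.0, 1.0)], [], require_spectra=False)


class TestScoreEdges:
    def test_shared_spectrum_scores_one(self):
        feats = [feature("sub", 300.0, 14.0), feature("prod", 315.9949, 12.5)]
        net = build_network(feats, [OXY], require_spectra=False)
        spec = make_spectrum([(100.0, 1.0), (150.0, 2.0)])
        score_edges(net, {"sub": [spec], "prod": [spec]})
        assert net["sub"]["prod"]["OXY"]["similarity"] == pytest.approx(1.0)

    def test_missing_spectra_leave_similarity_unset(self):
        feats = [feature("sub", 300.0, 14.0), feature("prod", 315.9949, 12.5)]
        net = build_network(feats, [OXY], require_spectra=False)
        score_edges(net, {"sub": [make_spectrum([(100.0, 1.0)])]})
        assert "similarity" not in net["sub"]["prod"]["OXY"]
        assert net.number_of_edges() == 1

    def test_edge_score_equals_direct_cosine(self, small_sim):
        from csppnet.similarity import cosine_similarity

        ft = small_sim.subdbs["FTMS_neg"]
        by_id = ft.spectra_by_id()
        spectra = {fid: [by_id[s] for s in sids] for fid, sids in ft.feature_spectra.items()}
        net = build_network(ft.features, small_sim.config.catalog(),
                            feature_spectra=ft.feature_spectra)
        score_edges(net, spectra, mz_tol=0.01)
        checked = 0
        for u, v, code, data in list(net.edges(keys=True, data=True))[:20]:
            direct = max(
                cosine_similarity(su, sv, mz_tol=0.01).value
                for su in spectra[u] for sv in spectra[v]
            )
            assert data["similarity"] == pytest.approx(direct, abs=1e-12)
            checked += 1
        assert checked > 0


class TestOrganLabel:
    def test_dominant_organ_wins(self):
        ab = {"tassel:OH43:1": 100.0, "leaf:OH43:1": 1.0}
        net = build_network([feature("f", 300.0, 1.0, ab)], [OXY], require_spectra=False)
        label_organ_of_max(net)
        assert net.nodes["f"]["organ"] == "tassel"

    def test_tie_broken_by_fixed_order_and_flagged(self):
        ab = {"ear:OH43:1": 5.0, "leaf:OH43:1": 5.0}
        net = build_network([feature("f", 300.0, 1.0, ab)], [OXY], require_spectra=False)
        label_organ_of_max(net)
        assert net.nodes["f"]["organ"] == "ear"
        assert net.nodes["f"]["organ_tie"]

    def test_all_zero_abundances_unassigned(self):
        ab = {"ear:OH43:1": 0.0}
        net = build_network([feature("f", 300.0, 1.0, ab)], [OXY], require_spectra=False)
        label_organ_of_max(net)
        assert net.nodes["f"]["organ"] == "unassigned"

    def test_planted_enrichment_recovered(self, small_sim):
        """With 10-fold organ enrichment the label matches the home organ
        whenever the feature is detected there."""
        ft = small_sim.subdbs["FTMS_neg"]
        net = build_network(ft.features, small_sim.config.catalog(),
                            feature_spectra=ft.feature_spectra)
        label_organ_of_max(net)
        truth = small_sim.truth
        f2c = truth.feature_to_compound["FTMS_neg"]
        correct = total = 0
        for node, data in net.nodes(data=True):
            home = truth.organ_of_compound[f2c[node]]
            feats = data["feature"]
            if feats.organ_abundance(home) <= 0:
                continue  # dropped out of its home organ entirely
            total += 1
            correct += data["organ"] == home
        assert total > 0
        assert correct == total


class TestPropagation:
    def test_methylation_neighbor_annotated(self):
        caffeic = parse_formula("C9H8O4")
        mz_sub = ion_mz(monoisotopic_mass(caffeic), "neg")
        mz_prod = ion_mz(monoisotopic_mass(caffeic) + MET.delta_mass, "neg")
        feats = [feature("s", mz_sub, 10.0), feature("p", mz_prod, 11.0)]
        net = build_network(feats, [MET], require_spectra=False)
        result = propagate_annotations(net, {"s": (caffeic, "caffeic acid")})
        assert result["p"][0].formula == parse_formula("C10H10O4")  # ferulic acid
        assert result["p"][0].path == ("MET",)
        assert result["p"][0].hops == 1

    def test_isolated_seed_does_not_propagate(self):
        caffeic = parse_formula("C9H8O4")
        feats = [feature("s", ion_mz(monoisotopic_mass(caffeic), "neg"), 10.0)]
        net = build_network(feats, [MET], require_spectra=False)
        result = propagate_annotations(net, {"s": (caffeic, "caffeic acid")})
        assert set(result) == {"s"}

    def test_seed_mass_mismatch_rejected(self):
        feats = [feature("s", 500.0, 10.0)]
        net = build_network(feats, [MET], require_spectra=False)
        with pytest.raises(ValueError, match="neutral mass"):
            propagate_annotations(net, {"s": (parse_formula("C9H8O4"), "x")})

    def test_planted_tree_fully_annotated(self, small_sim):
        """Seeding one scaffold's base compound labels its whole lineage
        with the generating formulas."""
        truth = small_sim.truth
        ft = small_sim.subdbs["FTMS_neg"]
        cfg = small_sim.config
        net = build_network(ft.features, cfg.catalog(), mass_tol=0.002,
                            feature_spectra=ft.feature_spectra)
        compounds = {c.compound_id: c for c in truth.compounds}
        f2c = truth.feature_to_compound["FTMS_neg"]
        c2f = {v: k for k, v in f2c.items()}
        base = compounds["cpd000_base"]
        seeds = {c2f["cpd000_base"]: (base.formula, "scaffold0")}
        result = propagate_annotations(net, seeds, max_hops=3, mass_tol=0.002)
        mismatches = 0
        reached = 0
        for node, anns in result.items():
            true_formula = compounds[f2c[node]].formula
            reached += 1
            mismatches += anns[0].formula != true_formula
        assert reached > 1
        assert mismatches == 0

    def test_propagated_mass_always_matches_node(self, small_sim):
        from csppnet.chem import neutral_mass

        ft = small_sim.subdbs["FTMS_neg"]
        net = build_network(ft.features, small_sim.config.catalog(),
                            feature_spectra=ft.feature_spectra)
        truth = small_sim.truth
        f2c = truth.feature_to_compound["FTMS_neg"]
        compounds = {c.compound_id: c for c in truth.compounds}
        c2f = {v: k for k, v in f2c.items()}
        seed_node = c2f["cpd001_base"]
        result = propagate_annotations(
            net, {seed_node: (compounds["cpd001_base"].formula, "seed")}, max_hops=3
        )
        for node, anns in result.items():
            for ann in anns:
                node_neutral = neutral_mass(net.nodes[node]["mz"], "neg")
                assert abs(monoisotopic_mass(ann.formula) - node_neutral) <= 0.002


class TestExport:
    def _net(self):
        feats = [feature("sub", 300.0, 14.0), feature("mid", 315.9949, 12.5),
                 feature("prod", 330.0106, 13.5)]
        net = build_network(feats, [OXY, MET], require_spectra=False)
        label_organ_of_max(net)
        return net

    def test_graphml_round_trip(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.graphml"
        export_network(net, path)
        back = import_network(path)
        assert set(back.nodes) == set(net.nodes)
        assert set(back.edges(keys=True)) == set(net.edges(keys=True))
        for node in net.nodes:
            assert back.nodes[node]["mz"] == pytest.approx(net.nodes[node]["mz"])
            assert back.nodes[node]["organ"] == net.nodes[node]["organ"]

    def test_edge_table_export(self, tmp_path):
        net = self._net()
        path = tmp_path / "edges.tsv"
        export_network(net, path, format="edge_table")
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == [
            "substrate", "product", "biotransformation", "mass_error", "similarity"]
        assert len(lines) == 1 + net.number_of_edges()

    def test_empty_network_exports(self, tmp_path):
        net = nx.MultiDiGraph()
        path = tmp_path / "empty.graphml"
        export_network(net, path)
        assert import_network(path).number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._net(), tmp_path / "x.bin", format="parquet")
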