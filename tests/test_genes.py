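"""Gene partitioning: term graph, uncertainty rule, component sets."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

import molevo as m
from molevo.genes import Term


def _record(rid, features, length=60):
    return m.AnnotatedRecord(id=rid, sequence="ACGT" * (length // 4), features=features)


def _cds(start, end, **quals):
    return m.Feature(
        "CDS", (m.Locus(start, end),), {k: (v,) for k, v in quals.items()}
    )


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("ATPase 6", "atpase 6"),
            ("  ND3\t", "nd3"),
            ("NADH dehydrogenase subunit 2", "nadh dehydrogenase subunit 2"),
            ('"quoted  name"', "quoted name"),
            ("MiXeD   Case\tTabs", "mixed case tabs"),
        ],
    )
    def test_normal_form(self, raw, expected):
        assert m.normalize_term(raw) == expected

    def test_all_whitespace_rejected(self):
        with pytest.raises(m.ValidationError):
            m.normalize_term("   \t ")


class TestTermGraph:
    def test_single_instance_links_gene_and_product(self):
        rec = _record("r1", (_cds(0, 30, gene="ATP6", product="ATP synthase 6"),))
        graph = m.build_term_graph([rec], {"CDS"})
        assert len(graph) == 2
        ((a, b, support),) = graph.edges()
        assert support == frozenset({"r1"})

    def test_disjoint_nomenclatures_stay_disconnected(self):
        r1 = _record("r1", (_cds(0, 30, gene="atp6"),))
        r2 = _record("r2", (_cds(0, 30, gene="atpase 6"),))
        graph = m.build_term_graph([r1, r2], {"CDS"})
        assert len(graph) == 2 and graph.edges() == []
        assert len(graph.components()) == 2

    def test_gene_mode_ignores_product_only_features(self):
        rec = _record("r1", (_cds(0, 30, product="ATP synthase 6"),))
        graph = m.build_term_graph([rec], {"CDS"}, qualifier_mode="gene")
        assert len(graph) == 0

    def test_colocated_gene_feature_contributes_values(self):
        gene_feat = m.Feature("gene", (m.Locus(0, 30),), {"gene": ("MT-ATP6",)})
        rec = _record("r1", (_cds(0, 30, product="ATP synthase 6"), gene_feat))
        graph = m.build_term_graph([rec], {"CDS"})
        assert Term("CDS", "mt-atp6") in graph.terms

    def test_nested_gene_feature_does_not_contribute(self):
        gene_feat = m.Feature("gene", (m.Locus(0, 40),), {"gene": ("MT-ATP6",)})
        rec = _record("r1", (_cds(0, 30, product="ATP synthase 6"), gene_feat))
        graph = m.build_term_graph([rec], {"CDS"})
        assert Term("CDS", "mt-atp6") not in graph.terms

    @given(st.integers(2, 30))
    def test_adding_term_reusing_record_never_lowers_support(self, extra):
        records = [
            _record(f"r{i}", (_cds(0, 30, gene="ATP6", product="ATP synthase 6"),))
            for i in range(extra)
        ]
        before = m.build_term_graph(records[:-1], {"CDS"})
        after = m.build_term_graph(records, {"CDS"})
        for a, b, support in before.edges():
            assert after.support(a, b) >= support


class TestUncertaintyRule:
    def _graph(self, n_a, n_b, bridge_records):
        graph = m.TermGraph()
        for i in range(n_a):
            graph.add_instance(f"a{i}", [Term("CDS", "x")])
        for i in range(n_b):
            graph.add_instance(f"b{i}", [Term("CDS", "y")])
        for rid in bridge_records:
            graph.add_instance(rid, [Term("CDS", "x"), Term("CDS", "y")])
        return graph

    def test_singleton_link_in_deep_sample_is_flagged(self):
        graph = self._graph(999, 799, ["a0"])
        (pair,) = m.detect_uncertain_pairs(graph, rate=0.05, floor=2)
        assert pair.support_count == 1
        assert pair.threshold_used == max(2, -(-5 * 800 // 100))
        assert pair.supporting_record_ids == ("a0",)

    def test_fully_supported_link_not_flagged(self):
        graph = m.TermGraph()
        for i in range(50):
            graph.add_instance(f"r{i}", [Term("CDS", "x"), Term("CDS", "y")])
        assert m.detect_uncertain_pairs(graph) == []

    def test_tiny_sample_full_support_not_flagged(self):
        graph = m.TermGraph()
        for rid in ("r1", "r2"):
            graph.add_instance(rid, [Term("CDS", "x"), Term("CDS", "y")])
        # support 2 is not < max(2, ceil(0.05*2)) = 2
        assert m.detect_uncertain_pairs(graph, rate=0.05, floor=2) == []

    def test_log_serialization_layout(self):
        graph = self._graph(100, 100, ["a0"])
        buf = io.StringIO()
        m.detect_uncertain_pairs(graph, log=buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "CDS:x\tCDS:y\t1"
        assert lines[1] == "\ta0"


class TestPartition:
    def test_clean_panel_counts(self, consistent_panel):
        records, _ = consistent_panel
        assert len(m.partition_genes(records, {"CDS"})) == 13
        assert len(m.partition_genes(records, {"rRNA"})) == 2
        assert len(m.partition_genes(records, {"tRNA"})) == 22

    def test_split_nomenclature_doubles_the_atp_sets(self):
        records, _ = m.make_hmtdna_panel(
            m.PanelSpec(n_records=12, seed=7, nomenclature_profile="split_atp")
        )
        assert len(m.partition_genes(records, {"CDS"})) == 15

    def test_duplicate_trna_names_merge_leu_and_ser(self):
        records, _ = m.make_hmtdna_panel(
            m.PanelSpec(n_records=12, seed=7, duplicate_trna_names=True)
        )
        result = m.partition_genes(records, {"tRNA"})
        assert len(result) == 20
        leu = result.sets["tRNA_trna-leu"]
        ser = result.sets["tRNA_trna-ser"]
        # both loci land in the same set: two fragments per record
        assert len(leu) == 2 * 12 and len(ser) == 2 * 12

    def test_mixed_spellings_still_one_set_per_gene(self):
        records, _ = m.make_hmtdna_panel(
            m.PanelSpec(n_records=12, seed=7, nomenclature_profile="per_record_mix")
        )
        assert len(m.partition_genes(records, {"CDS"})) == 13

    def test_fragments_are_traceable_to_their_records(self, consistent_panel):
        records, _ = consistent_panel
        by_id = {r.id: r for r in records}
        result = m.partition_genes(records, {"CDS"})
        for fragments in result.sets.values():
            for frag in fragments:
                assert by_id[frag.record_id].extract(frag.loci) == frag.residues

    def test_components_partition_the_term_set(self, consistent_panel):
        records, _ = consistent_panel
        graph = m.build_term_graph(records, {"CDS", "tRNA", "rRNA"})
        components = graph.components()
        union = set().union(*components)
        assert union == set(graph.terms)
        assert sum(len(c) for c in components) == len(union)

    def test_set_count_matches_generator_ground_truth(self, consistent_panel):
        records, truth = consistent_panel
        result = m.partition_genes(records, {"CDS"})
        assert len(result) == truth.distinct_names("CDS") == 13

    def test_unannotated_without_refseq_reported_unassignable(self):
        records, truth = m.make_hmtdna_panel(
            m.PanelSpec(n_records=6, seed=3, unannotated_fraction=0.34)
        )
        result = m.partition_genes(records, {"CDS"})
        assert sorted(result.unassignable) == sorted(truth.unannotated_ids)

    def test_unannotated_with_refseq_are_lifted_over(self, refseq):
        records, truth = m.make_hmtdna_panel(
            m.PanelSpec(n_records=6, seed=3, unannotated_fraction=0.34)
        )
        result = m.partition_genes(records, {"CDS"}, refseq=refseq)
        assert result.unassignable == []
        assert len(result) == 13
        for fragments in result.sets.values():
            assert {f.record_id for f in fragments} == {r.id for r in records}

    def test_refseq_without_features_is_an_error(self):
        records, _ = m.make_hmtdna_panel(
            m.PanelSpec(n_records=4, seed=3, unannotated_fraction=0.5)
        )
        bare = m.AnnotatedRecord(id="ref", sequence="ACGT" * 100)
        with pytest.raises(m.ValidationError):
            m.partition_genes(records, {"CDS"}, refseq=bare)

    def test_empty_collection_gives_empty_partition(self):
        assert len(m.partition_genes([], {"CDS"})) == 0

    def test_mislabel_merges_components_until_dropped(self):
        records, truth = m.make_hmtdna_panel(
            m.PanelSpec(n_records=12, seed=11, mislabel_rate=1 / 12)
        )
        assert len(truth.mislabeled) == 1
        merged = m.partition_genes(records, {"CDS"}, drop_uncertain=False)
        cleaned = m.partition_genes(records, {"CDS"}, drop_uncertain=True)
        assert len(merged) == 12  # two genes bridged by the corrupt record
        assert len(cleaned) == 13
        (pair,) = cleaned.uncertain
        assert pair.supporting_record_ids == (truth.mislabeled[0][0],)
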