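from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen.netbuild import (
    EvidenceClass,
    EvidenceFormatError,
    InteractionEvidence,
    PredictionFilterConfig,
    RegulatoryNetwork,
    Source,
    build_reference_network,
    filter_predictions,
    harmonize_mirna_name,
    load_interactions,
    read_edge_list,
    summarize_network,
    write_edge_list,
)

HEADER = (
    "mirna\tgene\tsource\tevidence_class\thoctar_score\texprtarget_score"
    "\tstarbase_readnum\tstarbase_bc\n"
)


def write_evidence(tmp_path, rows):
    path = tmp_path / "evidence.tsv"
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


class TestLoadInteractions:
    def test_well_formed_rows_parse_one_to_one(self, tmp_path):
        path = write_evidence(
            tmp_path,
            [
                "hsa-miR-1\tG1\tmiRTarBase\tvalidated_low_throughput\t\t\t\t",
                "hsa-miR-1\tG2\tHOCTAR\tpredicted\t3.2\t\t\t",
                "hsa-miR-2\tG1\tExprTarget\tpredicted\t\t1.4\t\t",
            ],
        )
        records = load_interactions(path)
        assert len(records) == 3
        assert records[0].source is Source.MIRTARBASE
        assert records[1].hoctar_score == 3.2
        assert records[2].exprtarget_score == 1.4

    def test_unknown_source_names_offending_row(self, tmp_path):
        path = write_evidence(
            tmp_path,
            [
                "hsa-miR-1\tG1\tmiRTarBase\tvalidated_low_throughput\t\t\t\t",
                "hsa-miR-1\tG2\tFooDB\tpredicted\t\t\t\t",
            ],
        )
        with pytest.raises(EvidenceFormatError, match="row 3"):
            load_interactions(path)

    def test_starbase_scores_round_trip(self, tmp_path):
        path = write_evidence(
            tmp_path, ["hsa-miR-1\tG1\tstarBase\tpredicted\t\t\t10\t2"]
        )
        (rec,) = load_interactions(path)
        assert rec.starbase_readnum == 10 and rec.starbase_bc == 2

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mirna\tgene\nhsa-miR-1\tG1\n")
        with pytest.raises(EvidenceFormatError, match="source"):
            load_interactions(path)

    def test_non_numeric_score_names_row(self, tmp_path):
        path = write_evidence(
            tmp_path, ["hsa-miR-1\tG1\tHOCTAR\tpredicted\thigh\t\t\t"]
        )
        with pytest.raises(EvidenceFormatError, match="row 2"):
            load_interactions(path)


class TestHarmonize:
    @pytest.mark.parametrize(
        "name,table,expected",
        [
            ("hsa-mir-378", {"hsa-mir-378": "hsa-miR-378a-3p"}, "hsa-miR-378a-3p"),
            ("hsa-miR-25-3p", {}, "hsa-miR-25-3p"),
            ("HSA-MIR-221-3P", {}, "hsa-miR-221-3p"),
            ("random-id", {}, "random-id"),
        ],
    )
    def test_alias_lookup_and_prefix_normalization(self, name, table, expected):
        assert harmonize_mirna_name(name, table) == expected

    def test_arm_suffix_never_stripped(self):
        assert harmonize_mirna_name("hsa-miR-101-3p", {}).endswith("-3p")


def hoctar(m, g, score):
    return InteractionEvidence(m, g, Source.HOCTAR, EvidenceClass.PREDICTED,
                               hoctar_score=score)


def exprtarget(m, g, score):
    return InteractionEvidence(m, g, Source.EXPRTARGET, EvidenceClass.PREDICTED,
                               exprtarget_score=score)


def starbase(m, g, readnum, bc):
    return InteractionEvidence(m, g, Source.STARBASE, EvidenceClass.PREDICTED,
                               starbase_readnum=readnum, starbase_bc=bc)


class TestFilterPredictions:
    def test_single_tool_agreement_insufficient(self):
        assert filter_predictions([hoctar("m1", "g1", 99.0)]) == set()

    def test_two_tool_agreement_with_passing_scores_included(self):
        ev = [starbase("m1", "g1", 10, 2), exprtarget("m1", "g1", 1.5)]
        assert filter_predictions(ev) == {("m1", "g1")}

    def test_boundary_scores_exprtarget_strict_starbase_inclusive(self):
        # "over 1" is strict, readNUM 9 < 10: neither tool passes
        ev = [exprtarget("m1", "g1", 1.0), starbase("m1", "g1", 9, 5)]
        assert filter_predictions(ev) == set()

    def test_hoctar_top_fraction_by_rank(self):
        ev = [hoctar(f"m{i}", "g", s) for i, s in enumerate([9.0, 7.0, 5.0, 3.0])]
        cfg = PredictionFilterConfig(min_tool_agreement=1)
        kept = filter_predictions(ev, cfg)
        # brute-force rank oracle: descending scores, keep ceil(0.5*4) = 2
        ranked = sorted(ev, key=lambda r: -r.hoctar_score)[:2]
        assert kept == {r.pair for r in ranked}

    def test_empty_evidence_gives_empty_set(self):
        assert filter_predictions([]) == set()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scores=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5),
                      st.floats(0, 10, allow_nan=False),
                      st.floats(0, 3, allow_nan=False),
                      st.integers(0, 30), st.integers(0, 5)),
            min_size=1, max_size=25,
        )
    )
    def test_agreement_and_threshold_monotonicity(self, scores):
        ev = []
        for mi, gi, h, e, rn, bc in scores:
            m, g = f"m{mi}", f"G{gi}"
            ev += [hoctar(m, g, h), exprtarget(m, g, e), starbase(m, g, rn, bc)]
        base = PredictionFilterConfig()
        out2 = filter_predictions(ev, base)
        # agreement monotonicity: 3 ⊆ 2 ⊆ 1
        out3 = filter_predictions(ev, PredictionFilterConfig(min_tool_agreement=3))
        out1 = filter_predictions(ev, PredictionFilterConfig(min_tool_agreement=1))
        assert out3 <= out2 <= out1
        # raising any threshold never adds a pair
        for tighter in (
            PredictionFilterConfig(hoctar_top_fraction=0.25),
            PredictionFilterConfig(exprtarget_min=2.0),
            PredictionFilterConfig(starbase_min_readnum=20),
            PredictionFilterConfig(starbase_min_bc=4),
        ):
            assert filter_predictions(ev, tighter) <= out2


def validated(m, g, cls=EvidenceClass.VALIDATED_LOW_THROUGHPUT):
    return InteractionEvidence(m, g, Source.MIRTARBASE, cls)


class TestBuildReference:
    def test_union_of_validated_and_predicted(self):
        net = build_reference_network([validated("m1", "g1")], {("m1", "g2")})
        assert net.edges == {("m1", "g1"), ("m1", "g2")}
        assert net.mirnas == {"m1"} and net.genes == {"g1", "g2"}

    def test_same_pair_validated_and_predicted_deduplicates(self):
        net = build_reference_network([validated("m1", "g1")], {("m1", "g1")})
        assert net.n_edges == 1

    def test_high_throughput_excluded_by_default(self):
        rec = validated("m1", "g1", EvidenceClass.VALIDATED_HIGH_THROUGHPUT)
        assert build_reference_network([rec], {("m2", "g2")}).edges == {("m2", "g2")}
        kept = build_reference_network([rec], set(), require_low_throughput=False)
        assert kept.edges == {("m1", "g1")}

    def test_conflicting_classes_keep_strongest_with_warning(self):
        recs = [
            validated("m1", "g1", EvidenceClass.VALIDATED_HIGH_THROUGHPUT),
            validated("m1", "g1", EvidenceClass.VALIDATED_LOW_THROUGHPUT),
        ]
        with pytest.warns(UserWarning, match="conflicting"):
            net = build_reference_network(recs, set())
        assert net.edges == {("m1", "g1")}

    def test_bipartite_violation_rejected(self):
        with pytest.raises(ValueError, match="bipartite"):
            RegulatoryNetwork.from_edges([("x", "y"), ("y", "z")])


class TestSummarize:
    def test_star_network(self):
        net = RegulatoryNetwork.from_edges([("m1", f"g{i}") for i in range(5)])
        s = summarize_network(net)
        assert (s.avg_mirna_degree, s.avg_gene_degree) == (5.0, 1.0)

    def test_counts_match_brute_force_recount(self, rng):
        edges = {
            (f"m{rng.integers(6)}", f"g{rng.integers(15)}") for _ in range(40)
        }
        net = RegulatoryNetwork.from_edges(edges)
        s = summarize_network(net)
        assert s.n_edges == len(edges)
        assert s.avg_mirna_degree == pytest.approx(
            np.mean([sum(1 for m, _ in edges if m == mi) for mi in net.mirnas])
        )
        assert s.avg_gene_degree == pytest.approx(
            np.mean([sum(1 for _, g in edges if g == gi) for gi in net.genes])
        )

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            summarize_network(RegulatoryNetwork.from_edges([]))


def test_edge_list_round_trip(tmp_path, rng):
    edges = {(f"m{rng.integers(9)}", f"g{rng.integers(30)}") for _ in range(60)}
    net = RegulatoryNetwork.from_edges(edges)
    path = tmp_path / "edges.tsv"
    write_edge_list(net, path)
    assert read_edge_list(path).edges == net.edges
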