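"""Co-resistance counting, scaling, binning, panel ranking, lineages, networks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coresist.io as cio
from coresist import (
    SensitivityCalls,
    aggregate_partner_frequencies,
    bin_degree,
    build_network,
    coresistance_count,
    enumerate_pairs,
    lineage_relative_frequencies,
    normalize_frequencies,
    panel_coresistance_status,
    rank_drug_in_panel,
)
from coresist.errors import (
    ConfigurationError,
    DegenerateDataError,
    DrugLookupError,
    EmptyPanelError,
)
from tests.conftest import make_calls


def brute_force_pair(calls: SensitivityCalls, a: str, b: str):
    """Independent enumeration over individual cells."""
    co, ev = set(), set()
    for line in calls.cell_line_ids:
        ca, cb = calls.calls.loc[line, a], calls.calls.loc[line, b]
        if pd.isna(ca) or pd.isna(cb):
            continue
        ev.add(line)
        if ca == "resistant" and cb == "resistant":
            co.add(line)
    return co, ev


def brute_force_rank(calls, panel_drug, focal, exclusions=frozenset()):
    panel = {
        cl
        for cl in calls.cell_line_ids
        if calls.calls.loc[cl, panel_drug] == "resistant"
    }
    scored = []
    for d in calls.drug_ids:
        if d == panel_drug or d in exclusions:
            continue
        ev = [cl for cl in panel if not pd.isna(calls.calls.loc[cl, d])]
        res = [cl for cl in ev if calls.calls.loc[cl, d] == "resistant"]
        score = len(res) / len(ev) if ev else 0.0
        scored.append((-score, -len(ev), d))
    scored.sort()
    order = [d for _, _, d in scored]
    return order.index(focal) + 1, order


class TestCount:
    def test_toy_table(self, toy_calls):
        pair = coresistance_count(toy_calls, "d1", "d2")
        assert pair.count == 2
        assert pair.co_resistant_lines == {"c1", "c5"}
        assert pair.evaluable_lines == {"c1", "c2", "c3", "c5"}

    def test_symmetry_on_toy(self, toy_calls):
        ab = coresistance_count(toy_calls, "d1", "d2")
        ba = coresistance_count(toy_calls, "d2", "d1")
        assert ab.count == ba.count
        assert ab.co_resistant_lines == ba.co_resistant_lines

    def test_self_pair_equals_resistant_count(self, toy_calls):
        pair = coresistance_count(toy_calls, "d1", "d1")
        assert pair.count == len(toy_calls.resistant_lines("d1")) == 4

    def test_disjoint_resistant_sets(self):
        calls = make_calls({"c1": ["R", "S"], "c2": ["S", "R"], "c3": ["S", "S"]})
        assert coresistance_count(calls, "d1", "d2").count == 0

    def test_unknown_drug(self, toy_calls):
        with pytest.raises(DrugLookupError):
            coresistance_count(toy_calls, "d1", "nope")

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_property_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 12), rng.integers(2, 6)
        codes = rng.choice(["R", "S", None], size=(n, m), p=[0.4, 0.4, 0.2])
        calls = make_calls({f"c{i}": list(codes[i]) for i in range(n)})
        for a, b in itertools.combinations(calls.drug_ids, 2):
            ab, ba = coresistance_count(calls, a, b), coresistance_count(calls, b, a)
            assert ab.count == ba.count
            assert ab.evaluable_lines == ba.evaluable_lines


class TestNormalizeAndBin:
    def _pairs(self, counts):
        from coresist import CoResistancePair

        return [
            CoResistancePair(
                drug_a=f"a{i}",
                drug_b=f"b{i}",
                co_resistant_lines=frozenset(),
                evaluable_lines=frozenset(),
                count=c,
            )
            for i, c in enumerate(counts)
        ]

    def test_endpoints_and_midpoint(self):
        out = normalize_frequencies(self._pairs([0, 5, 10]))
        assert [p.normalized_frequency for p in out] == [0.0, 0.5, 1.0]

    def test_max_count_always_one(self):
        out = normalize_frequencies(self._pairs([3, 7, 9]))
        assert max(p.normalized_frequency for p in out) == 1.0

    def test_equal_counts_error(self):
        with pytest.raises(DegenerateDataError):
            normalize_frequencies(self._pairs([3, 3, 3]))

    def test_scaling_preserves_count_order(self):
        counts = [4, 0, 9, 2, 9, 1]
        out = normalize_frequencies(self._pairs(counts))
        ranks_counts = np.argsort(np.argsort(counts))
        ranks_freqs = np.argsort(np.argsort([p.normalized_frequency for p in out]))
        assert list(ranks_counts) == list(ranks_freqs)

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "low"),
            (0.0999, "low"),
            (0.10, "mid"),  # half-open convention: 10% belongs to mid
            (0.5999, "mid"),
            (0.60, "high"),  # legend says >= 60%
            (1.0, "high"),
        ],
    )
    def test_degree_bins(self, value, expected):
        assert bin_degree(value) == expected

    @pytest.mark.parametrize("bad", [-0.01, 1.01, 2.0])
    def test_degree_bin_domain(self, bad):
        with pytest.raises(ValueError):
            bin_degree(bad)


class TestRank:
    @pytest.fixture
    def five_drug_calls(self):
        rng = np.random.default_rng(42)
        codes = rng.choice(["R", "S", None], size=(12, 5), p=[0.35, 0.45, 0.2])
        codes[:, 0][:6] = "R"  # ensure a panel exists for d1
        return make_calls({f"c{i:02d}": list(codes[i]) for i in range(12)})

    def test_matches_brute_force_sort(self, five_drug_calls):
        for focal in ("d2", "d3", "d4", "d5"):
            rt = rank_drug_in_panel(five_drug_calls, "d1", focal)
            expected_rank, expected_order = brute_force_rank(five_drug_calls, "d1", focal)
            assert rt.rank == expected_rank
            assert list(rt.order) == expected_order

    def test_deletion_never_worsens_rank(self, five_drug_calls):
        base = rank_drug_in_panel(five_drug_calls, "d1", "d2")
        for removed in ("d3", "d4", "d5"):
            rt = rank_drug_in_panel(five_drug_calls, "d1", "d2", exclusions={removed})
            assert rt.rank <= base.rank

    def test_dominant_focal_ranks_first(self):
        calls = make_calls(
            {f"c{i}": ["R", "R", "S", "S"] for i in range(4)},
            drugs=["panel", "focal", "x", "y"],
        )
        rt = rank_drug_in_panel(calls, "panel", "focal")
        assert rt.rank == 1 and rt.panel_size == 4

    def test_similarity_exclusion(self, five_drug_calls):
        groups = {"d2": "tki", "d3": "tki", "d4": "other", "d5": "other"}
        rt = rank_drug_in_panel(
            five_drug_calls, "d1", "d2", similarity_groups=groups, exclude_similar=True
        )
        assert "d3" in rt.exclusions and "d3" not in rt.scores
        assert rt.rank == brute_force_rank(five_drug_calls, "d1", "d2", {"d3"})[0]

    def test_errors(self, five_drug_calls):
        with pytest.raises(ConfigurationError):
            rank_drug_in_panel(five_drug_calls, "d1", "d1")
        with pytest.raises(ConfigurationError):
            rank_drug_in_panel(five_drug_calls, "d1", "d2", exclusions={"d2"})
        no_panel = make_calls({"c1": ["S", "R"], "c2": ["S", "R"], "c3": ["S", "S"]})
        with pytest.raises(EmptyPanelError):
            rank_drug_in_panel(no_panel, "d1", "d2")


class TestLineage:
    def test_single_lineage_relative_one(self, toy_calls):
        lineage = {cl: "lung" for cl in toy_calls.cell_line_ids}
        prof = lineage_relative_frequencies(toy_calls, lineage, "d1", "d2")
        row = prof.table.set_index("lineage").loc["lung"]
        assert row["relative"] == pytest.approx(1.0)

    def test_double_frequency_lineage(self):
        # lung: 2/2 co-resistant; skin: 1/4 → pan-cancer 3/6 = 0.5, lung relative 2.0
        calls = make_calls(
            {
                "l1": ["R", "R"],
                "l2": ["R", "R"],
                "s1": ["R", "R"],
                "s2": ["R", "S"],
                "s3": ["S", "R"],
                "s4": ["S", "S"],
            }
        )
        lineage = {"l1": "lung", "l2": "lung", "s1": "skin", "s2": "skin", "s3": "skin", "s4": "skin"}
        prof = lineage_relative_frequencies(calls, lineage, "d1", "d2")
        assert prof.pan_cancer_frequency == pytest.approx(0.5)
        tab = prof.table.set_index("lineage")
        assert tab.loc["lung", "relative"] == pytest.approx(2.0)
        assert tab.loc["skin", "relative"] == pytest.approx(0.5)
        assert bool(tab.loc["lung", "flagged"])  # only 2 evaluable lines (< 3)

    def test_empty_lineage_flagged_missing(self, toy_calls):
        lineage = {cl: "lung" for cl in toy_calls.cell_line_ids}
        lineage["c4"] = "brain"  # c4 is non-evaluable for the pair
        prof = lineage_relative_frequencies(toy_calls, lineage, "d1", "d2")
        row = prof.table.set_index("lineage").loc["brain"]
        assert row["n_evaluable"] == 0
        assert np.isnan(row["relative"]) and bool(row["flagged"])


class TestNetwork:
    def test_attributes_and_roundtrip(self, toy_calls, tmp_path):
        calls = make_calls(
            {
                "c1": ["R", "R", "S"],
                "c2": ["R", "R", "R"],
                "c3": ["S", "R", "R"],
                "c4": ["S", "S", "S"],
            }
        )
        pairs = normalize_frequencies(enumerate_pairs(calls))
        g = build_network(pairs, calls, {"d1": "CTD", "d2": "RTK inhibitor"})
        assert g.number_of_edges() == len(pairs)
        for d in g.nodes:
            assert g.nodes[d]["resistant_count"] == len(calls.resistant_lines(d))
        assert g.nodes["d1"]["drug_class"] == "CTD"
        assert g.nodes["d3"]["drug_class"] == "other"

        path = tmp_path / "net.graphml"
        cio.write_network(g, graphml_path=path, edgelist_path=tmp_path / "edges.tsv")
        back = cio.read_network(path)
        assert set(back.nodes) == set(g.nodes)
        for a, b, data in g.edges(data=True):
            assert back.edges[a, b]["normalized_frequency"] == pytest.approx(
                data["normalized_frequency"]
            )
            assert back.edges[a, b]["degree_bin"] == data["degree_bin"]
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(edges) == g.number_of_edges()

    def test_unnormalized_pairs_rejected(self, toy_calls):
        pairs = enumerate_pairs(toy_calls)
        with pytest.raises(ValueError):
            build_network(pairs, toy_calls)


def test_aggregate_partner_frequencies_reports_both_aggregates():
    calls = make_calls(
        {
            "c1": ["R", "R", "R"],
            "c2": ["R", "R", "S"],
            "c3": ["S", "R", "S"],
            "c4": ["S", "S", "S"],
        }
    )
    pairs = normalize_frequencies(enumerate_pairs(calls))
    table = aggregate_partner_frequencies(pairs, calls.drug_ids).set_index("drug")
    for d in calls.drug_ids:
        fs = [p.normalized_frequency for p in pairs if d in (p.drug_a, p.drug_b)]
        assert table.loc[d, "mean_normalized_frequency"] == pytest.approx(np.mean(fs))
        assert table.loc[d, "sum_normalized_frequency"] == pytest.approx(np.sum(fs))


def test_panel_coresistance_status_fraction():
    calls = make_calls(
        {
            "c1": ["R", "R", "R"],
            "c2": ["R", "S", "R"],
            "c3": ["S", "R", "S"],
        },
        drugs=["p1", "p2", "focal"],
    )
    # p1 panel {c1,c2} shares c1,c2 with focal; p2 panel {c1,c3} shares c1
    assert panel_coresistance_status(calls, ["p1", "p2"], "focal") == 1.0
    no_share = make_calls(
        {"c1": ["R", "S"], "c2": ["S", "R"]}, drugs=["p1", "focal"]
    )
    assert panel_coresistance_status(no_share, ["p1"], "focal") == 0.0
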