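"""Synergy Contribution Degree model, HCGSC selection, reference coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synerkit.adme import ComponentRecord
from synerkit.ctnet import build_graph, node_topology
from synerkit.scd import (
    compute_scd,
    coverage_vs_reference,
    herb_balance,
    minmax_norm,
    select_hcgsc,
)

from .conftest import scd_term_by_term


class TestMinMaxNorm:
    def test_linear_example(self):
        assert minmax_norm([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]

    def test_constant_vector_maps_to_ones(self):
        assert minmax_norm([5, 5]).tolist() == [1.0, 1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_norm([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
    def test_extremes_map_to_zero_and_one(self, values):
        out = minmax_norm(values)
        if max(values) > min(values):
            assert out.min() == 0.0 and out.max() == 1.0
        assert ((0 <= out) & (out <= 1)).all()


class TestHerbBalance:
    def test_single_herb_component_scores_one(self):
        assert herb_balance(0.7, 0.2, single_herb=True) == 1.0
        assert herb_balance(0.0, 0.0, single_herb=True) == 1.0

    def test_balanced_two_herb_component_gets_floor(self):
        assert herb_balance(0.4, 0.4, single_herb=False) == 1e-6
        assert herb_balance(0.0, 0.0, single_herb=False) == 1e-6

    def test_hand_arithmetic(self):
        assert herb_balance(0.3, 0.1, single_herb=False) == pytest.approx(0.5)

    def test_negative_centrality_rejected(self):
        with pytest.raises(ValueError):
            herb_balance(-0.1, 0.2, single_herb=False)


def _topology_frame(records):
    rows = []
    for r in records:
        rows.append(
            {
                "node": r["id"],
                "kind": "component",
                "herb": r.get("herb", "A"),
                "degree": r["Ce"],
                "betweenness": r["C"],
                "Ce": r["Ce"],
                "Te": r["Te"],
                "target_betweenness_sum": sum(r["T"]),
                "CB": r.get("CB", 0.0),
                "CK": r.get("CK", 0.0),
                "single_herb": r.get("single_herb", True),
            }
        )
    return pd.DataFrame(rows).set_index("node")


class TestComputeSCD:
    def test_zero_betweenness_equal_doses_reduces_to_target_count(self):
        records = [
            {"id": "c1", "C": 0.0, "Ce": 3, "Te": 5, "T": [0, 0, 0]},
            {"id": "c2", "C": 0.0, "Ce": 1, "Te": 2, "T": [0]},
        ]
        table = compute_scd(_topology_frame(records), {"c1": 2.0, "c2": 2.0})
        assert table.loc["c1", "scd"] == pytest.approx(3.0)
        assert table.loc["c2", "scd"] == pytest.approx(1.0)

    def test_matches_term_by_term_oracle_on_toy_network(self):
        records = [
            {"id": "c1", "C": 0.31, "Ce": 3, "Te": 7, "T": [0.2, 0.05, 0.6],
             "CB": 0.3, "CK": 0.1, "single_herb": False, "balance": 0.5},
            {"id": "c2", "C": 0.12, "Ce": 2, "Te": 9, "T": [0.4, 0.4],
             "CB": 0.0, "CK": 0.0, "single_herb": True, "balance": 1.0},
            {"id": "c3", "C": 0.05, "Ce": 1, "Te": 3, "T": [0.15],
             "CB": 0.2, "CK": 0.2, "single_herb": False, "balance": 1e-6},
        ]
        doses = {"c1": 10.0, "c2": 2.5, "c3": 1.0}
        expected = scd_term_by_term(records, doses)
        table = compute_scd(_topology_frame(records), doses)
        for cid, val in expected.items():
            assert table.loc[cid, "scd"] == pytest.approx(val, abs=1e-9)

    def test_raising_a_mid_range_dose_does_not_decrease_scd(self):
        records = [
            {"id": "lo", "C": 0.1, "Ce": 2, "Te": 4, "T": [0.1, 0.1]},
            {"id": "mid", "C": 0.1, "Ce": 2, "Te": 4, "T": [0.1, 0.1]},
            {"id": "hi", "C": 0.1, "Ce": 2, "Te": 4, "T": [0.1, 0.1]},
        ]
        before = compute_scd(_topology_frame(records), {"lo": 1, "mid": 3, "hi": 10})
        after = compute_scd(_topology_frame(records), {"lo": 1, "mid": 6, "hi": 10})
        assert after.loc["mid", "scd"] >= before.loc["mid", "scd"]

    def test_isolated_component_scores_zero_but_is_retained(self):
        records = [
            {"id": "c1", "C": 0.2, "Ce": 2, "Te": 4, "T": [0.3, 0.1]},
            {"id": "iso", "C": 0.0, "Ce": 0, "Te": 0, "T": []},
        ]
        table = compute_scd(_topology_frame(records), {"c1": 1.0, "iso": 2.0})
        assert table.loc["iso", "scd"] == 0.0
        assert set(table.index) == {"c1", "iso"}

    def test_missing_dose_rejected(self):
        records = [{"id": "c1", "C": 0.1, "Ce": 1, "Te": 1, "T": [0.0]}]
        with pytest.raises(ValueError, match="dose"):
            compute_scd(_topology_frame(records), {})

    def test_shares_sum_to_one_and_cumulative_monotone(self):
        rng = np.random.default_rng(8)
        records = [
            {"id": f"c{i}", "C": float(rng.random()), "Ce": 2, "Te": 6,
             "T": [float(rng.random()), float(rng.random())]}
            for i in range(15)
        ]
        doses = {f"c{i}": float(rng.lognormal()) for i in range(15)}
        table = compute_scd(_topology_frame(records), doses)
        assert table["share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (table["cumulative_share"].diff().dropna() >= -1e-12).all()

    def test_input_order_does_not_change_scores(self):
        records = [
            {"id": "c1", "C": 0.3, "Ce": 2, "Te": 5, "T": [0.2, 0.1]},
            {"id": "c2", "C": 0.1, "Ce": 1, "Te": 2, "T": [0.4]},
            {"id": "c3", "C": 0.2, "Ce": 3, "Te": 9, "T": [0.1, 0.1, 0.1]},
        ]
        doses = {"c1": 5.0, "c2": 1.0, "c3": 2.0}
        a = compute_scd(_topology_frame(records), doses)
        b = compute_scd(_topology_frame(records[::-1]), doses)
        pd.testing.assert_frame_equal(a, b)

    def test_real_graph_scores_are_nonnegative(self):
        comps = [ComponentRecord(id=f"C{i}", herb="AB"[i % 2]) for i in range(6)]
        edges = [(f"C{i}", f"T{(i * 3 + j) % 7}") for i in range(6) for j in range(3)]
        topo = node_topology(build_graph(edges, comps))
        table = compute_scd(topo, {c.id: float(i + 1) for i, c in enumerate(comps)})
        assert (table["scd"] >= 0).all()


class TestSelectHCGSC:
    def _table(self, shares):
        scd = np.asarray(shares, dtype=float)
        df = pd.DataFrame(
            {"herb": "A", "scd": scd}, index=[f"c{i}" for i in range(len(scd))]
        )
        df = df.sort_values("scd", ascending=False)
        df["share"] = df["scd"] / df["scd"].sum()
        df["cumulative_share"] = df["share"].cumsum()
        df["hcgsc"] = False
        return df

    def test_single_dominant_component(self):
        table = self._table([1.0])
        assert select_hcgsc(table, 0.95) == {"c0"}

    def test_cumulative_cut_at_exact_threshold(self):
        table = self._table([0.5, 0.3, 0.15, 0.05])
        assert select_hcgsc(table, 0.95) == {"c0", "c1", "c2"}

    def test_ties_at_the_cut_are_all_included(self):
        table = self._table([0.6, 0.2, 0.2, 0.0])
        # threshold reached at the first 0.2; the tied 0.2 joins it
        assert select_hcgsc(table, 0.8) == {"c0", "c1", "c2"}

    def test_threshold_one_selects_all_nonzero(self):
        table = self._table([0.5, 0.3, 0.2, 0.0])
        assert select_hcgsc(table, 1.0) == {"c0", "c1", "c2"}

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_hcgsc(self._table([1.0]), 0.0)

    def test_flag_forms_a_prefix_of_the_descending_order(self):
        table = self._table([0.4, 0.25, 0.2, 0.1, 0.05])
        select_hcgsc(table, 0.7)
        flags = table["hcgsc"].tolist()
        assert flags == sorted(flags, reverse=True)


class TestCoverage:
    def test_reference_coverage_percentage(self):
        reference = {f"g{i}" for i in range(70)}
        selected = {f"g{i}" for i in range(62)} | {"x1", "x2"}
        pct, hits = coverage_vs_reference(selected, reference)
        assert pct == 88.57
        assert len(hits) == 62

    def test_superset_and_disjoint_cases(self):
        assert coverage_vs_reference({"a", "b", "c"}, {"a", "b"})[0] == 100.00
        assert coverage_vs_reference({"a"}, {"b", "c"})[0] == 0.00

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            coverage_vs_reference({"a"}, set())
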