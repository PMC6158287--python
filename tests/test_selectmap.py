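"""Heatmaps, position classes, switches, pair maps, selectivity products."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sortsel.selectmap import (
    COLD_SPOT,
    HOT_SPOT,
    INSUFFICIENT,
    NEUTRAL,
    classify_positions,
    double_residue_map,
    find_selectivity_switches,
    pairwise_selectivity,
    residue_pair_combination_map,
    single_mut_heatmap,
    total_selectivity,
)


def er_frame(entries, n_mut=1, sort_id="s"):
    return pd.DataFrame(
        [{"variant_key": k, "n_mut": n_mut, "sort_id": sort_id, "ER": er}
         for k, er in entries.items()]
    )


class TestHeatmap:
    def test_er_one_maps_to_zero(self):
        hm = single_mut_heatmap(er_frame({"T11I": 1.0}))
        assert hm.loc["I", 11] == 0.0

    def test_log2_of_table_value(self):
        # ER 12.50 for a switch mutation -> log2 ~ 3.64
        hm = single_mut_heatmap(er_frame({"G17R": 12.50}))
        assert hm.loc["R", 17] == pytest.approx(math.log2(12.50), abs=1e-12)
        assert hm.loc["R", 17] == pytest.approx(3.644, abs=1e-3)

    def test_matrix_matches_direct_recomputation(self, rng):
        ers = {f"T11{aa}": float(rng.uniform(0.05, 20)) for aa in "ACDEFGHIK"}
        hm = single_mut_heatmap(er_frame(ers))
        for key, er in ers.items():
            assert hm.loc[key[-1], 11] == pytest.approx(np.log2(er))

    def test_duplicate_entry_fatal(self):
        df = pd.concat([er_frame({"T11I": 2.0}), er_frame({"T11I": 3.0})])
        with pytest.raises(ValueError, match="duplicate"):
            single_mut_heatmap(df)


class TestClassifyPositions:
    @staticmethod
    def _matrix(n_below, n_above, pos=11):
        ers = {}
        aas = [a for a in "ACDEFGHIKLMNPQRSVWY"]  # 19 non-Thr
        for i in range(n_below):
            ers[f"T{pos}{aas[i]}"] = 0.5
        for i in range(n_above):
            ers[f"T{pos}{aas[n_below + i]}"] = 2.0
        return single_mut_heatmap(er_frame(ers))

    def test_majority_depleted_is_hot_spot(self):
        cls = classify_positions(self._matrix(18, 1))
        assert cls.iloc[0]["label"] == HOT_SPOT

    def test_majority_enriched_is_cold_spot(self):
        cls = classify_positions(self._matrix(3, 16))
        assert cls.iloc[0]["label"] == COLD_SPOT

    def test_sparse_position_insufficient(self):
        cls = classify_positions(self._matrix(3, 0))
        assert cls.iloc[0]["label"] == INSUFFICIENT

    def test_exact_half_is_neutral(self):
        cls = classify_positions(self._matrix(5, 5))
        assert cls.iloc[0]["label"] == NEUTRAL

    def test_er_exactly_one_counts_to_neither_side(self):
        ers = {f"T11{a}": 1.0 for a in "ACDEFGHIK"}
        ers["T11L"] = 0.5
        cls = classify_positions(single_mut_heatmap(er_frame(ers)))
        row = cls.iloc[0]
        assert row["n_observed"] == 10
        assert row["n_ER_below_1"] == 1 and row["n_ER_above_1"] == 0
        assert row["label"] == NEUTRAL


class TestSwitches:
    def test_reciprocal_gate_switches(self):
        gate_meso = er_frame({"T11I": 5.91, "T11H": 0.07, "G17A": 1.0})
        gate_anio = er_frame({"T11I": 0.01, "T11H": 7.39, "G17A": 1.1})
        out = find_selectivity_switches(
            gate_meso, gate_anio, target_a="meso", target_b="anionic"
        )
        by_mut = out.set_index("mutation")
        assert by_mut.loc["T11I", "direction"] == "anionic->meso"
        assert by_mut.loc["T11H", "direction"] == "meso->anionic"
        assert "G17A" not in by_mut.index

    def test_neutral_mutation_not_reported(self):
        a = er_frame({"T11I": 1.0})
        b = er_frame({"T11I": 1.0})
        assert find_selectivity_switches(a, b).empty

    def test_unpaired_mutations_flagged(self):
        a = er_frame({"T11I": 5.0, "G17R": 3.0})
        b = er_frame({"T11I": 0.1})
        out = find_selectivity_switches(a, b)
        assert out.attrs["unpaired"] == ["G17R"]


class TestPairwiseSelectivity:
    def test_table_values_order_of_magnitude(self):
        # rounded printed ER in, ~6.2e4 out (unrounded inputs print 69.22e3)
        a = er_frame({"T11I": 5.91, "T11H": 0.07})
        b = er_frame({"T11I": 0.01, "T11H": 7.39})
        s = pairwise_selectivity("T11H", "T11I", a, b)
        assert s == pytest.approx((5.91 / 0.07) / (0.01 / 7.39))
        assert 1e4 < s < 1e5

    def test_same_mutation_is_unity(self):
        a = er_frame({"T11I": 5.91})
        b = er_frame({"T11I": 0.01})
        assert pairwise_selectivity("T11I", "T11I", a, b) == 1.0

    def test_swapping_targets_inverts(self):
        a = er_frame({"m1": 2.0, "m2": 8.0})
        b = er_frame({"m1": 0.5, "m2": 0.1})
        s = pairwise_selectivity("m1", "m2", a, b)
        assert pairwise_selectivity("m1", "m2", b, a) == pytest.approx(1 / s)

    def test_missing_er_reported_as_nan(self):
        a = er_frame({"m1": 2.0})
        b = er_frame({"m1": 0.5})
        assert math.isnan(pairwise_selectivity("m1", "absent", a, b))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_reciprocity_against_parent(self, er_a, er_b):
        """S(m, parent, A, B) * S(m, parent, B, A) = 1."""
        a = er_frame({"m": er_a})
        b = er_frame({"m": er_b})
        prod = (pairwise_selectivity("m", "parent", a, b)
                * pairwise_selectivity("m", "parent", b, a))
        assert prod == pytest.approx(1.0, abs=1e-9)


class TestDoubleMaps:
    def test_single_double_variant(self):
        df = er_frame({"T11V/G17R": 3.0}, n_mut=2)
        er_mat, n_mat = double_residue_map(df)
        assert er_mat.loc[11, 17] == 3.0 == er_mat.loc[17, 11]
        assert n_mat.loc[11, 17] == 1

    def test_summation_over_variants(self):
        df = er_frame({"T11V/G17R": 1.0, "T11A/G17S": 2.0, "T11P/G17A": 3.0},
                      n_mut=2)
        er_mat, n_mat = double_residue_map(df)
        assert er_mat.loc[11, 17] == 6.0
        assert n_mat.loc[11, 17] == 3

    def test_matches_groupby_oracle(self, ref, rng):
        from sortsel import simgen
        roster = simgen.build_roster(ref, ["A"], seed=9, n_doubles=60)
        doubles = roster[roster["n_mut"] == 2]
        df = er_frame(
            {k: float(rng.uniform(0.1, 5)) for k in doubles["variant_key"]},
            n_mut=2,
        )
        er_mat, n_mat = double_residue_map(df)
        # independent group-and-sum
        from sortsel.variantcall import VariantKey
        groups = {}
        for k, er in zip(df["variant_key"], df["ER"]):
            subs = VariantKey.from_string(k).substitutions
            pair = (subs[0].position, subs[1].position)
            groups.setdefault(pair, []).append(er)
        for (x, y), vals in groups.items():
            assert er_mat.loc[x, y] == pytest.approx(sum(vals))
            assert n_mat.loc[x, y] == len(vals)

    def test_combination_map_cells_and_marginal(self):
        df = er_frame({"T11V/G17R": 1.5, "T11A/G17R": 2.5, "T11V/G17S": 0.5},
                      n_mut=2)
        comb = residue_pair_combination_map(df, 11, 17)
        assert comb.loc["V", "R"] == 1.5
        assert comb.loc["A", "R"] == 2.5
        er_mat, _ = double_residue_map(df)
        assert np.nansum(comb.to_numpy()) == pytest.approx(er_mat.loc[11, 17])

    def test_combination_map_empty_pair(self):
        df = er_frame({"T11V/G17R": 1.5}, n_mut=2)
        comb = residue_pair_combination_map(df, 12, 15)
        assert comb.isna().to_numpy().all()

    def test_same_position_rejected(self):
        with pytest.raises(ValueError):
            residue_pair_combination_map(er_frame({}, n_mut=2), 11, 11)


def test_heatmap_png_rendering(tmp_path):
    hm = single_mut_heatmap(er_frame({"T11I": 2.0, "G17R": 0.5}))
    out = tmp_path / "hm.png"
    from sortsel.selectmap import plot_heatmap
    plot_heatmap(hm, str(out), title="toy")
    assert out.stat().st_size > 0


class TestTotalSelectivity:
    def test_three_component_product(self):
        # ~59e3 x ~364 x ~170 multiplies to ~3.65e9 (rounds to 4e9)
        assert total_selectivity([59e3, 364, 170]) == pytest.approx(3.65e9, rel=0.01)

    def test_unity(self):
        assert total_selectivity([1, 1, 1]) == 1.0

    def test_permutation_invariant(self):
        assert total_selectivity([2, 3, 5]) == total_selectivity([5, 2, 3])

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            total_selectivity([])
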