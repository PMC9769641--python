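"""Set decomposition and percent similarity against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from simmg_eval import REGIONS, decompose_sets, percent_similarity, similarity_change
from simmg_eval.set_comparison import (
    decompose_feature_sets,
    per_sample_similarity,
    similarity_summary,
)


def brute_force_regions(mg: set, mt: set, sim: set) -> dict[str, int]:
    """Enumerate every feature and bin it by exact membership pattern."""
    counts = {r: 0 for r in REGIONS}
    names = {
        (True, False, False): "MG-only",
        (False, True, False): "MT-only",
        (False, False, True): "sim-only",
        (True, True, False): "MG∩MT-only",
        (True, False, True): "MG∩sim-only",
        (False, True, True): "MT∩sim-only",
        (True, True, True): "MG∩MT∩sim",
    }
    for f in mg | mt | sim:
        counts[names[(f in mg, f in mt, f in sim)]] += 1
    return counts


def dice_percent(x: set, y: set) -> float:
    if not x and not y:
        return math.nan
    return 2 * len(x & y) / (len(x) + len(y)) * 100.0


def _presence(sets_per_sample: list[tuple[set, set, set]], universe: list):
    samples = [f"S{i}" for i in range(len(sets_per_sample))]
    mats = []
    for k in range(3):
        df = pd.DataFrame(
            {
                s: [f in sets_per_sample[i][k] for f in universe]
                for i, s in enumerate(samples)
            },
            index=universe,
        )
        mats.append(df)
    return mats


class TestDecompose:
    def test_worked_example(self):
        mg, mt, sim = {"a", "b", "c"}, {"b", "c", "d"}, {"c", "d", "e"}
        expected = {
            "MG-only": 1,
            "MT-only": 0,
            "sim-only": 1,
            "MG∩MT-only": 1,
            "MG∩sim-only": 0,
            "MT∩sim-only": 1,
            "MG∩MT∩sim": 1,
        }
        assert decompose_feature_sets(mg, mt, sim) == expected
        assert expected == brute_force_regions(mg, mt, sim)
        mats = _presence([(mg, mt, sim)], sorted(mg | mt | sim))
        d = decompose_sets(*mats)
        assert d.per_sample.iloc[0].to_dict() == expected

    def test_empty_and_identical_sets(self):
        assert all(v == 0 for v in decompose_feature_sets(set(), set(), set()).values())
        s = {"x", "y", "z"}
        d = decompose_feature_sets(s, s, s)
        assert d["MG∩MT∩sim"] == 3 and sum(d.values()) == 3

    def test_sample_mismatch_raises(self):
        a = pd.DataFrame([[True]], index=["f"], columns=["S1"])
        b = pd.DataFrame([[True]], index=["f"], columns=["S2"])
        with pytest.raises(ValueError, match="sample"):
            decompose_sets(a, a, b)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.sets(st.integers(0, 19)),
            st.sets(st.integers(0, 19)),
            st.sets(st.integers(0, 19)),
        )
    )
    def test_matches_brute_force_and_conserves_union(self, triple):
        mg, mt, sim = triple
        d = decompose_feature_sets(mg, mt, sim)
        assert d == brute_force_regions(mg, mt, sim)
        assert sum(d.values()) == len(mg | mt | sim)


class TestPercentSimilarity:
    def test_identity_and_disjoint(self):
        counts = dict.fromkeys(REGIONS, 0)
        counts["MG∩MT∩sim"] = 5
        assert percent_similarity(counts, "simMG:MG") == 100.0
        counts = dict.fromkeys(REGIONS, 0)
        counts["MG-only"], counts["sim-only"] = 3, 4
        assert percent_similarity(counts, "simMG:MG") == 0.0

    def test_worked_pair(self):
        # |A∩B| = 3, one feature private to each side -> 2*3/(6+2) = 75%
        counts = dict.fromkeys(REGIONS, 0)
        counts["MG∩MT-only"] = 3
        counts["MG-only"] = 1
        counts["MT-only"] = 1
        assert percent_similarity(counts, "MG:MT") == 75.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.sets(st.integers(0, 15)),
            st.sets(st.integers(0, 15)),
            st.sets(st.integers(0, 15)),
        )
    )
    def test_pairwise_equals_dice_on_raw_sets(self, triple):
        mg, mt, sim = triple
        counts = decompose_feature_sets(mg, mt, sim)
        pairs = {"simMG:MG": (sim, mg), "simMG:MT": (sim, mt), "MG:MT": (mg, mt)}
        for cmp, (x, y) in pairs.items():
            if not x and not y:
                with pytest.warns(UserWarning):
                    assert math.isnan(percent_similarity(counts, cmp))
            else:
                assert percent_similarity(counts, cmp) == pytest.approx(
                    dice_percent(x, y)
                )

    def test_pairwise_symmetry(self):
        counts = dict(zip(REGIONS, [3, 1, 4, 1, 5, 9, 2]))
        a = percent_similarity(counts, "MG:MT")
        swapped = dict(counts)
        swapped["MG-only"], swapped["MT-only"] = counts["MT-only"], counts["MG-only"]
        swapped["MG∩sim-only"], swapped["MT∩sim-only"] = (
            counts["MT∩sim-only"],
            counts["MG∩sim-only"],
        )
        assert percent_similarity(swapped, "MG:MT") == pytest.approx(a)

    def test_three_way_uses_all_regions(self):
        counts = dict(zip(REGIONS, [1, 1, 1, 1, 1, 1, 6]))
        assert percent_similarity(counts, "simMG:MG:MT") == pytest.approx(
            2 * 6 / (2 * 6 + 6) * 100
        )

    def test_triple_universe_variant_penalizes_third_method(self):
        counts = dict.fromkeys(REGIONS, 0)
        counts["MG∩MT-only"] = 3
        counts["sim-only"] = 2
        assert percent_similarity(counts, "MG:MT") == 100.0
        assert percent_similarity(counts, "MG:MT", pairwise_universe="triple") < 100.0

    def test_averaging_order_default_vs_per_sample(self):
        universe = list(range(6))
        sets1 = ({0, 1, 2}, {1, 2, 3}, {2, 3})
        sets2 = ({0, 1}, {0, 1}, {0})
        mats = _presence([sets1, sets2], universe)
        d = decompose_sets(*mats)
        avg_first = percent_similarity(d, "MG:MT")
        per_sample = per_sample_similarity(d, "MG:MT")
        assert per_sample.shape == (2,)
        # averaging region counts first is not the same as averaging similarities
        assert avg_first != pytest.approx(per_sample.mean())


class TestSimilarityChange:
    @pytest.mark.parametrize(
        "total,prok,expected",
        [
            (76.21, 81.05, 4.84),
            (68.13, 67.73, -0.40),
            (55.12, 63.46, 8.34),
        ],
    )
    def test_signed_deltas_in_points(self, total, prok, expected):
        deltas = similarity_change({"c": total}, {"c": prok})
        assert deltas["c"] == pytest.approx(expected)

    def test_identical_summaries_give_zero(self):
        vals = {"simMG:MG": 70.0, "MG:MT": 60.0}
        assert all(v == 0 for v in similarity_change(vals, dict(vals)).values())

    def test_missing_comparison_is_keyed_error(self):
        with pytest.raises(KeyError):
            similarity_change({"a": 1.0}, {"b": 1.0})


def test_summary_covers_all_comparisons(small_noiseless_study):
    from simmg_eval import binarize

    pms = {m: binarize(p) for m, p in small_noiseless_study.profiles.items()}
    d = decompose_sets(pms["MG"], pms["MT"], pms["simMG"])
    summary = similarity_summary(d)
    assert set(summary.comparisons) == {"simMG:MG", "simMG:MT", "MG:MT", "simMG:MG:MT"}
    assert all(0 <= v <= 100 for v in summary.comparisons.values())
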