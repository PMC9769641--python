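"""Gene-set prevalence, majority filtering, and the reporting statistics."""

import pandas as pd
import pytest

from simmg_eval import (
    GeneSet,
    binarize,
    coverage_fraction,
    majority_filter,
    percent_more,
    prevalence,
    scfa_presence,
)
from simmg_eval.synthetic_data import (
    AMR_CLASS_SIZES,
    amr_geneset,
    cazy_geneset,
    scfa_geneset,
)
from tests_helpers_profiles import three_method_profiles


@pytest.fixture()
def simple_presences():
    profiles = three_method_profiles(
        mg={"K99000": [1] * 9, "K99001": [1, 1, 1, 1, 1, 0, 0, 0, 0]},
        mt={"K99001": [1, 0, 0, 0, 0, 0, 0, 0, 0]},
        sim={"K99000": [1] * 9, "K99002": [0, 1, 1, 1, 1, 1, 0, 0, 0]},
    )
    return {m: binarize(p) for m, p in profiles.items()}


class TestPrevalence:
    def test_counts_and_zero_rows(self, simple_presences):
        gs = GeneSet("AMR", {"K99000": ("vancomycin",), "K99999": ("phenicol",)})
        table = prevalence(simple_presences, gs)
        assert table.counts.loc["K99000", "MG"] == 9
        assert (table.counts.loc["K99999"] == 0).all()

    def test_scaling_invariance(self, simple_presences):
        profiles = three_method_profiles(
            mg={"K99000": [1] * 9}, mt={}, sim={"K99000": [1] * 9}
        )
        scaled = {
            m: binarize(
                type(p)(p.method_label, p.level, p.abundance * 1000.0)
            )
            for m, p in profiles.items()
        }
        gs = GeneSet("AMR", {"K99000": ("vancomycin",)})
        base = prevalence({m: binarize(p) for m, p in profiles.items()}, gs)
        big = prevalence(scaled, gs)
        pd.testing.assert_frame_equal(base.counts, big.counts)

    def test_planted_per_method_counts(self, small_noiseless_study):
        study = small_noiseless_study
        pms = {m: binarize(p) for m, p in study.profiles.items()}
        fid = next(f for f, r in study.truth.items() if r == "MG∩sim-only")
        gs = GeneSet("probe", {fid: ("x",)})
        table = prevalence(pms, gs)
        n = study.config.n_samples
        assert table.counts.loc[fid].to_dict() == {"MG": n, "MT": 0, "simMG": n}


class TestMajorityFilter:
    def test_boundary_five_or_more(self, simple_presences):
        gs = GeneSet(
            "AMR",
            {"K99000": ("a",), "K99001": ("b",), "K99002": ("c",)},
        )
        table = prevalence(simple_presences, gs)
        kept = majority_filter(table, threshold=5)
        # K99001 peaks at 5 samples (boundary, kept); K99002 peaks at 5
        assert set(kept.counts.index) == {"K99000", "K99001", "K99002"}
        kept6 = majority_filter(table, threshold=6)
        assert set(kept6.counts.index) == {"K99000"}

    def test_threshold_extremes(self, simple_presences):
        gs = GeneSet("AMR", {"K99000": ("a",), "K99001": ("b",), "K99404": ("c",)})
        table = prevalence(simple_presences, gs)
        anywhere = majority_filter(table, threshold=1)
        assert set(anywhere.counts.index) == {"K99000", "K99001"}
        everywhere = majority_filter(table, threshold=9)
        assert set(everywhere.counts.index) == {"K99000"}

    def test_out_of_range_threshold(self, simple_presences):
        gs = GeneSet("AMR", {"K99000": ("a",)})
        table = prevalence(simple_presences, gs)
        with pytest.raises(ValueError):
            majority_filter(table, threshold=10)


class TestReportingStats:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(82, 66, 24.24), (82, 20, 310.0), (5, 5, 0.0), (3, 6, -50.0)],
    )
    def test_percent_more(self, a, b, expected):
        assert percent_more(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "shared,ref,expected", [(44, 73, 60.27), (0, 10, 0.0), (7, 8, 87.5)]
    )
    def test_coverage_fraction(self, shared, ref, expected):
        assert coverage_fraction(shared, ref) == pytest.approx(expected)

    def test_percent_more_is_not_coverage(self):
        # the two statistics answer different questions: percent_more
        # compares two repertoires (either may be larger), coverage is a
        # recovered-subset share and refuses n_shared > n_reference
        assert percent_more(82, 66) == 24.24
        with pytest.raises(ValueError):
            coverage_fraction(82, 66)

    def test_zero_reference_is_an_error(self):
        with pytest.raises(ValueError):
            percent_more(5, 0)
        with pytest.raises(ValueError):
            coverage_fraction(0, 0)


class TestFixtures:
    def test_scfa_product_multiplicities(self):
        gs = scfa_geneset()
        assert len(gs.members) == 16
        tally = {}
        for labels in gs.members.values():
            for lab in labels:
                tally[lab] = tally.get(lab, 0) + 1
        assert tally == {"acetate": 6, "butyrate": 7, "lactate": 5, "propionate": 3}
        n_assignments = sum(len(v) for v in gs.members.values())
        assert n_assignments - len(gs.members) == 5  # 5 multi-product pathways

    def test_amr_fixture_structure(self):
        gs = amr_geneset()
        assert len(gs.members) == 162
        assert len(gs.class_labels) == 11
        tally = {}
        for labels in gs.members.values():
            for lab in labels:
                tally[lab] = tally.get(lab, 0) + 1
        assert tally == AMR_CLASS_SIZES

    def test_cazy_placeholder(self):
        gs = cazy_geneset()
        assert len(gs.members) == 102
        assert set(gs.class_labels) == {"GH5", "GH6", "GH7"}

    def test_geneset_tsv_round_trip(self, tmp_path):
        gs = scfa_geneset()
        p = tmp_path / "scfa.tsv"
        gs.to_tsv(p)
        back = GeneSet.from_tsv(p)
        assert back.members == gs.members


class TestScfaPresence:
    def test_full_presence_and_absent_pathway(self):
        samples = 3
        gs = GeneSet("SCFA", {"P161-PWY": ("acetate",), "PROPFERM-PWY": ("propionate",)})
        profiles = three_method_profiles(
            mg={"P161-PWY": [1] * samples, "PROPFERM-PWY": [1] * samples},
            mt={"P161-PWY": [1] * samples},
            sim={"P161-PWY": [1] * samples},
            level="pathway",
        )
        res = scfa_presence({m: binarize(p) for m, p in profiles.items()}, gs)
        assert res.pathway_counts.loc["P161-PWY", "MG"] == samples
        assert res.pathway_counts.loc["PROPFERM-PWY", "MT"] == 0
        assert res.product_rollup.loc["propionate", "simMG"] == 0

    def test_simulated_recovers_14_of_16_mg_pathways(self):
        """Presence patterns where the simulated data miss exactly the two
        fermentation pathways absent from every simulated sample."""
        gs = scfa_geneset()
        n = 9
        mg = {p: [1] * n for p in gs.members}
        missing_in_sim = {"GLUDEG-II-PWY", "PROPFERM-PWY"}
        sim = {p: ([0] * n if p in missing_in_sim else [1] * n) for p in gs.members}
        mt = {p: [1] * n for p in gs.members}
        profiles = three_method_profiles(mg=mg, mt=mt, sim=sim, level="pathway")
        res = scfa_presence({m: binarize(p) for m, p in profiles.items()}, gs)
        mg_detected = (res.pathway_counts["MG"] >= 1)
        sim_detected = (res.pathway_counts["simMG"] >= 1)
        assert int(mg_detected.sum()) == 16
        assert int((mg_detected & sim_detected).sum()) == 14

    def test_requires_pathway_level(self, simple_presences):
        with pytest.raises(ValueError, match="pathway"):
            scfa_presence(simple_presences, scfa_geneset())
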