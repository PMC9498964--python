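"""Unit tests for sgRNA representation analysis."""

import numpy as np
import pandas as pd
import pytest

from mitoscreen import screen
from mitoscreen.screen import (
    GuideAnnotation,
    aggregate_representation,
    control_normalized_frequency,
    load_count_table,
    metastasis_analysis,
    rank_depletion,
    representation_percent,
    timepoint_dynamics,
    write_count_table,
)
from mitoscreen.simulate import ScreenSimConfig, simulate_screen_counts
from mitoscreen.stats import group_compare


class TestLoading:
    def test_round_trip_preserves_counts_and_metadata(self, tmp_path):
        table, annotation, _ = simulate_screen_counts(ScreenSimConfig(n_guides=40, seed=3))
        paths = write_count_table(table, annotation, tmp_path)
        reloaded, re_ann = load_count_table(
            paths["counts"],
            paths["annotation"],
            pd.read_csv(paths["samples"], sep="\t", index_col=0),
        )
        pd.testing.assert_frame_equal(reloaded.counts, table.counts)
        pd.testing.assert_frame_equal(re_ann.table, annotation.table)

    def test_library_composition_one_fifth_controls(self):
        _, annotation, _ = simulate_screen_counts(ScreenSimConfig(seed=0))
        comp = annotation.composition()
        assert comp.sum() == 400
        assert comp["nontargeting"] == 80
        assert comp["nontargeting"] / comp.sum() == pytest.approx(0.2)

    def test_negative_count_names_offending_cell(self, tiny_annotation):
        counts = pd.DataFrame({"s1": [1, 2, -3, 4, 5]}, index=tiny_annotation.guide_ids)
        meta = pd.DataFrame(
            {"context": ["in_vitro_day0"]}, index=pd.Index(["s1"], name="sample_id")
        )
        with pytest.raises(ValueError, match="g3.*s1"):
            screen.CountTable(counts, meta)

    def test_non_integer_count_rejected(self, tmp_path, tiny_annotation):
        (tmp_path / "c.tsv").write_text("guide_id\ts1\ng1\t1.5\n")
        tiny_annotation.table.drop(columns="macro_class").rename_axis("guide_id").to_csv(
            tmp_path / "a.tsv", sep="\t"
        )
        with pytest.raises(ValueError, match="non-integer"):
            load_count_table(tmp_path / "c.tsv", tmp_path / "a.tsv")

    def test_missing_annotation_lists_guides(self, tmp_path, tiny_annotation):
        (tmp_path / "c.tsv").write_text("guide_id\ts1\ng1\t1\nrogue\t2\n")
        tiny_annotation.table.drop(columns="macro_class").rename_axis("guide_id").to_csv(
            tmp_path / "a.tsv", sep="\t"
        )
        with pytest.raises(ValueError, match="rogue"):
            load_count_table(tmp_path / "c.tsv", tmp_path / "a.tsv")


class TestFrequencies:
    def test_hand_computed_frequency(self, tiny_annotation, make_counts):
        table = make_counts({"s1": [10, 0, 0, 50, 50]}, tiny_annotation.guide_ids)
        f = control_normalized_frequency(table, tiny_annotation, pseudocount=0)
        assert f.loc["g1", "s1"] == pytest.approx(0.10)

    def test_scale_invariance(self, tiny_annotation, make_counts):
        t1 = make_counts({"s1": [10, 4, 6, 50, 50]}, tiny_annotation.guide_ids)
        t2 = make_counts({"s1": [20, 8, 12, 100, 100]}, tiny_annotation.guide_ids)
        f1 = control_normalized_frequency(t1, tiny_annotation)
        f2 = control_normalized_frequency(t2, tiny_annotation)
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_control_sum_names_sample(self, tiny_annotation, make_counts):
        table = make_counts({"bad": [10, 4, 6, 0, 0]}, tiny_annotation.guide_ids)
        with pytest.raises(ValueError, match="bad"):
            control_normalized_frequency(table, tiny_annotation, pseudocount=0)
        # a positive pseudocount rescues the sample
        f = control_normalized_frequency(table, tiny_annotation, pseudocount=1)
        assert (f["bad"] > 0).all()


class TestRepresentation:
    def test_identity_when_tumor_equals_reference(self, tiny_annotation, make_counts):
        table = make_counts(
            {"ref": [10, 4, 6, 50, 50], "tum": [10, 4, 6, 50, 50]},
            tiny_annotation.guide_ids,
        )
        f = control_normalized_frequency(table, tiny_annotation)
        rep = representation_percent(f[["tum"]], f[["ref"]], tiny_annotation)
        assert np.allclose(rep.representation["tum"], 100.0)

    def test_hand_computed_ratio(self, tiny_annotation):
        f_ref = pd.DataFrame({"ref": [0.10]}, index=["g1"])
        f_tum = pd.DataFrame({"tum": [0.05]}, index=["g1"])
        rep = representation_percent(f_tum, f_ref, tiny_annotation)
        assert rep.representation.loc["g1", "tum"] == pytest.approx(50.0)

    def test_guide_absent_from_reference_errors(self, tiny_annotation):
        f_ref = pd.DataFrame({"ref": [0.1]}, index=["g1"])
        f_tum = pd.DataFrame({"tum": [0.1, 0.2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="absent"):
            representation_percent(f_tum, f_ref, tiny_annotation)

    def test_zero_reference_instructs_pseudocount(self, tiny_annotation):
        f_ref = pd.DataFrame({"ref": [0.0]}, index=["g1"])
        f_tum = pd.DataFrame({"tum": [0.1]}, index=["g1"])
        with pytest.raises(ValueError, match="pseudocount"):
            representation_percent(f_tum, f_ref, tiny_annotation)


class TestAggregation:
    def test_two_experiment_mean(self, tiny_annotation):
        rep = screen.RepresentationTable(
            pd.DataFrame(
                {"t1": [40.0] * 5, "t2": [60.0] * 5}, index=tiny_annotation.guide_ids
            ),
            tiny_annotation,
            samples=pd.DataFrame(
                {"experiment_id": ["exp1", "exp2"]},
                index=pd.Index(["t1", "t2"], name="sample_id"),
            ),
        )
        agg = aggregate_representation(rep, by="experiment_then_guide")
        assert np.allclose(agg.per_guide["mean"], 50.0)

    def test_single_sample_sem_zero(self, tiny_annotation):
        rep = screen.RepresentationTable(
            pd.DataFrame({"t1": [40.0] * 5}, index=tiny_annotation.guide_ids),
            tiny_annotation,
        )
        agg = aggregate_representation(rep, by="pooled")
        assert np.allclose(agg.per_guide["mean"], 40.0)
        assert np.allclose(agg.per_guide["sem"], 0.0)

    def test_group_means_by_macro_class(self, tiny_annotation):
        rep = screen.RepresentationTable(
            pd.DataFrame({"t1": [40.0, 60.0, 80.0, 100.0, 120.0]}, index=tiny_annotation.guide_ids),
            tiny_annotation,
        )
        agg = aggregate_representation(rep, by="pooled")
        assert agg.group_means["mito_respiratory"] == pytest.approx(50.0)
        assert agg.group_means["glycolytic"] == pytest.approx(80.0)
        assert agg.group_means["control"] == pytest.approx(110.0)


class TestGroupCompare:
    def test_identical_groups_null(self):
        res = group_compare({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert all(p > 0.99 for _, _, p in res.pairwise)

    def test_shifted_group_detected(self):
        res = group_compare({"a": [1, 2, 3], "b": [1, 2, 3], "c": [11, 12, 13]})
        assert res.p_value < 1e-4
        adj = {frozenset((x, y)): p for x, y, p in res.pairwise}
        assert adj[frozenset(("a", "b"))] > 0.9
        assert adj[frozenset(("a", "c"))] < 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            group_compare({"a": [1, 2], "b": []})

    def test_two_sample_methods(self):
        t = group_compare({"a": [1, 2, 3, 4], "b": [5, 6, 7, 8]}, method="t_test")
        u = group_compare({"a": [1, 2, 3, 4], "b": [5, 6, 7, 8]}, method="mann_whitney")
        assert t.p_value < 0.05
        assert u.p_value < 0.05
        assert t.pairwise == [] and u.pairwise == []


class TestTimepoints:
    def test_identical_counts_give_100_percent(self, tiny_annotation, make_counts):
        row = [10, 4, 6, 50, 50]
        table = make_counts(
            {"d0a": row, "d0b": row, "d4a": row, "d4b": row},
            tiny_annotation.guide_ids,
            contexts={"d0a": "in_vitro_day0", "d0b": "in_vitro_day0", "d4a": "flank", "d4b": "flank"},
            day={"d0a": 0, "d0b": 0, "d4a": 4, "d4b": 4},
        )
        out = timepoint_dynamics(table, tiny_annotation, days=[4])
        R = out[4]["representation"].representation
        assert np.allclose(R, 100.0)

    def test_doubled_frequency_gives_200_percent(self, tiny_annotation, make_counts):
        table = make_counts(
            {"d0": [10, 4, 6, 50, 50], "d4": [20, 4, 6, 50, 50]},
            tiny_annotation.guide_ids,
            contexts={"d0": "in_vitro_day0", "d4": "flank"},
            day={"d0": 0, "d4": 4},
        )
        out = timepoint_dynamics(table, tiny_annotation, days=[4])
        assert out[4]["representation"].representation.loc["g1", "d4"] == pytest.approx(200.0)

    def test_missing_day0_errors(self, tiny_annotation, make_counts):
        table = make_counts(
            {"d4": [10, 4, 6, 50, 50]},
            tiny_annotation.guide_ids,
            contexts={"d4": "flank"},
            day={"d4": 4},
        )
        with pytest.raises(ValueError, match="day-0"):
            timepoint_dynamics(table, tiny_annotation, days=[4])


class TestMetastases:
    def test_identity_and_hand_ratio(self, tiny_annotation):
        freq = pd.DataFrame(
            {"primary": [0.1, 0.2, 0.3, 0.4, 0.5], "met": [0.2, 0.2, 0.3, 0.4, 0.5]},
            index=tiny_annotation.guide_ids,
        )
        out = metastasis_analysis(freq, tiny_annotation, pairs=[("met", "primary")])
        R = out["representation"].representation
        assert R.loc["g1", "met"] == pytest.approx(200.0)
        assert R.loc["g3", "met"] == pytest.approx(100.0)

    def test_unmatched_metastasis_errors(self, tiny_annotation):
        freq = pd.DataFrame({"met": [0.1] * 5}, index=tiny_annotation.guide_ids)
        with pytest.raises(ValueError, match="matched primary"):
            metastasis_analysis(freq, tiny_annotation, pairs=[("met", None)])

    def test_cross_metastasis_correlation_per_class(self):
        rng = np.random.default_rng(5)
        n = 8
        ann = GuideAnnotation(
            pd.DataFrame(
                {
                    "target_gene": [f"G{i}" for i in range(n)] + [None] * n,
                    "functional_class": ["respiratory_chain"] * n + ["nontargeting"] * n,
                },
                index=pd.Index([f"g{i}" for i in range(2 * n)], name="guide_id"),
            )
        )
        base = rng.uniform(0.01, 0.2, size=2 * n)
        freq = pd.DataFrame(
            {
                "prim": base,
                "metA": base * rng.lognormal(0, 0.05, 2 * n),
                "metB": base * rng.lognormal(0, 0.05, 2 * n),
            },
            index=ann.guide_ids,
        )
        out = metastasis_analysis(
            freq, ann, pairs=[("metA", "prim"), ("metB", "prim")],
            correlation_pairs=[("metA", "metB")],
        )
        corr = out["correlations"][("metA", "metB")]
        assert set(corr["functional_class"]) == {"respiratory_chain", "nontargeting"}
        assert (corr["n"] == n).all()
        assert corr["p"].between(0, 1).all()


class TestRanking:
    def test_tie_break_is_lexicographic(self, tiny_annotation):
        rep = screen.RepresentationTable(
            pd.DataFrame({"t": [100.0] * 5}, index=["g3", "g1", "nt2", "g2", "nt1"]),
            tiny_annotation,
        )
        ranked = rank_depletion(rep)
        assert list(ranked.index) == ["g1", "g2", "g3", "nt1", "nt2"]

    def test_orders_by_depletion(self, tiny_annotation):
        rep = screen.RepresentationTable(
            pd.DataFrame(
                {"t": [90.0, 10.0, 50.0, 100.0, 100.0]}, index=tiny_annotation.guide_ids
            ),
            tiny_annotation,
        )
        ranked = rank_depletion(rep)
        assert list(ranked.index[:3]) == ["g2", "g3", "g1"]
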