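"""ppm annotation, ROI aggregation and the transition-area screens."""

import numpy as np
import pandas as pd
import pytest

from pyrtrace.chem import parse_formula
from pyrtrace.msi import (
    LipidRecord,
    annotate_species,
    genotype_ratio_heatmap,
    ppm_match,
    remove_multicandidate,
    roi_aggregate,
    screen_top10_down_in_oe,
    screen_top10_up_in_oe,
)


@pytest.fixture(scope="module")
def ps_record():
    f = parse_formula("C40H76NO10P")   # PS 34:1, [M-H]- 760.5134
    return LipidRecord("PS 34:1", "PS", f, 760.51341)


class TestPpmMatch:
    def test_annotated_species_matches(self, ps_record):
        assert ppm_match(760.513, [ps_record], 5.0) == [ps_record]

    def test_8ppm_away_no_match(self, ps_record):
        assert ppm_match(760.520, [ps_record], 5.0) == []

    def test_empty_database(self):
        assert ppm_match(760.513, [], 5.0) == []

    def test_widening_tolerance_is_monotone(self, ps_record):
        for q in (760.510, 760.513, 760.517, 760.523):
            narrow = set(id(r) for r in ppm_match(q, [ps_record], 3.0))
            wide = set(id(r) for r in ppm_match(q, [ps_record], 10.0))
            assert narrow <= wide

    def test_ref_mz_must_agree_with_formula(self):
        with pytest.raises(ValueError):
            LipidRecord("bogus", "PS", parse_formula("C40H76NO10P"), 760.60)


class TestRemoveMulticandidate:
    def test_keeps_only_single_candidates(self, ps_record):
        ann = pd.DataFrame([
            {"mz": 760.513, "n_candidates": 1, "candidates": ("PS 34:1",)},
            {"mz": 766.539, "n_candidates": 2,
             "candidates": ("PE 38:4", "PE O-38:5;O")},
            {"mz": 555.5, "n_candidates": 0, "candidates": ()},
        ])
        kept = remove_multicandidate(ann)
        assert list(kept["mz"]) == [760.513]


def roi_table(values_by_cell, mz=700.0):
    rows = []
    for (region, genotype), vals in values_by_cell.items():
        for i, v in enumerate(vals):
            rows.append((mz, region, genotype, i // 3 + 1, i % 3 + 1, v))
    return pd.DataFrame(rows, columns=["mz", "region", "genotype",
                                       "section", "roi", "intensity"])


class TestRoiAggregate:
    def test_constant_rois(self):
        roi = roi_table({("cortex", "control"): [5.0] * 9})
        agg = roi_aggregate(roi)
        assert agg["mean_intensity"].iloc[0] == 5.0
        assert agg["n_roi"].iloc[0] == 9

    def test_arithmetic_mean(self):
        roi = roi_table({("cortex", "control"): list(range(1, 10))})
        assert roi_aggregate(roi)["mean_intensity"].iloc[0] == 5.0

    def test_missing_region_raises(self):
        roi = pd.concat([
            roi_table({("cortex", "control"): [1.0] * 9,
                       ("cortex", "KSPAKO"): [1.0] * 9}, mz=700.0),
            roi_table({("cortex", "control"): [1.0] * 9}, mz=800.0),
        ])
        with pytest.raises(ValueError, match="800"):
            roi_aggregate(roi)


def means_frame(entries):
    return pd.DataFrame(entries, columns=["mz", "region", "genotype",
                                          "mean_intensity", "n_roi"])


class TestRatioHeatmap:
    def test_identical_genotypes_unity(self):
        rows = [(700.0, r, g, 10.0, 9) for r in ("cortex", "transition")
                for g in ("control", "KSPAKO", "KSPAPN")]
        species, _ = genotype_ratio_heatmap(means_frame(rows))
        assert (species["KSPAKO/control"] == 1.0).all()
        assert (species["KSPAPN/control"] == 1.0).all()

    def test_uniform_doubling_gives_class_ratio_two(self):
        rows = []
        for mz in (700.0, 710.0):
            for r in ("cortex",):
                rows += [(mz, r, "control", 10.0, 9),
                         (mz, r, "KSPAKO", 20.0, 9),
                         (mz, r, "KSPAPN", 10.0, 9)]
        ann = pd.DataFrame([
            {"mz": 700.0, "n_candidates": 1, "candidates": ("A",),
             "lipid_class": "PS"},
            {"mz": 710.0, "n_candidates": 1, "candidates": ("B",),
             "lipid_class": "PS"},
        ])
        _, classes = genotype_ratio_heatmap(means_frame(rows), ann)
        assert classes.loc[0, "KSPAKO/control"] == 2.0

    def test_global_rescaling_invariant(self):
        rows = [(700.0, "cortex", g, v, 9) for g, v in
                [("control", 10.0), ("KSPAKO", 15.0), ("KSPAPN", 30.0)]]
        a, _ = genotype_ratio_heatmap(means_frame(rows))
        scaled = means_frame([(mz, r, g, 7.5 * v, n) for mz, r, g, v, n
                              in rows])
        b, _ = genotype_ratio_heatmap(scaled)
        assert a["KSPAKO/control"].iloc[0] == \
            pytest.approx(b["KSPAKO/control"].iloc[0], abs=1e-12)

    def test_zero_control_excluded_and_reported(self):
        rows = [(700.0, "cortex", "control", 0.0, 9),
                (700.0, "cortex", "KSPAKO", 5.0, 9),
                (700.0, "cortex", "KSPAPN", 5.0, 9),
                (710.0, "cortex", "control", 1.0, 9),
                (710.0, "cortex", "KSPAKO", 5.0, 9),
                (710.0, "cortex", "KSPAPN", 5.0, 9)]
        species, _ = genotype_ratio_heatmap(means_frame(rows))
        assert list(species["mz"]) == [710.0]
        assert species.attrs["excluded_zero_control"] == [700.0]


def screen_fixture():
    """Hand-built transition-area table with known screen outcomes."""
    rows, ratios = [], []
    spec = [
        # mz, fold_oe, fold_ko, oe_mean
        (600.0, 3.0, 0.5, 500.0),    # up-screen hit
        (610.0, 2.0, 0.5, 500.0),    # up-screen hit, ranked second
        (620.0, 3.5, 0.5, 50.0),     # fails the intensity floor
        (630.0, 3.0, 0.9, 500.0),    # KO not below 0.75
        (640.0, 0.4, 2.5, 500.0),    # down-screen hit
        (650.0, 0.6, 2.5, 500.0),    # down-screen hit, ranked second
        (660.0, 0.4, 1.5, 500.0),    # KO not above 2
    ]
    for mz, oe, ko, mean in spec:
        for region in ("cortex", "transition"):
            rows += [(mz, region, "control", mean / oe, 9),
                     (mz, region, "KSPAKO", mean / oe * ko, 9),
                     (mz, region, "KSPAPN", mean, 9)]
    return means_frame(rows)


class TestScreens:
    def test_up_screen_filters_and_ranking(self):
        means = screen_fixture()
        species, _ = genotype_ratio_heatmap(means)
        up = screen_top10_up_in_oe(species, means)
        assert list(up["mz"]) == [600.0, 610.0]
        assert (up["fold_oe"] > 1).all() and (up["fold_ko"] < 0.75).all()
        assert (up["mean_intensity"] > 100).all()

    def test_down_screen_filters_and_ranking(self):
        means = screen_fixture()
        species, _ = genotype_ratio_heatmap(means)
        down = screen_top10_down_in_oe(species, means)
        assert list(down["mz"]) == [640.0, 650.0]

    def test_empty_input_gives_empty_result(self):
        means = means_frame([(700.0, "transition", g, 10.0, 9)
                             for g in ("control", "KSPAKO", "KSPAPN")])
        species, _ = genotype_ratio_heatmap(means)
        assert screen_top10_up_in_oe(species, means).empty
        assert screen_top10_down_in_oe(species, means).empty

    def test_tie_break_by_ascending_mz(self):
        rows = []
        for mz in (820.0, 810.0):
            rows += [(mz, "transition", "control", 100.0, 9),
                     (mz, "transition", "KSPAKO", 50.0, 9),
                     (mz, "transition", "KSPAPN", 300.0, 9)]
        means = means_frame(rows)
        species, _ = genotype_ratio_heatmap(means)
        up = screen_top10_up_in_oe(species, means)
        assert list(up["mz"]) == [810.0, 820.0]


class TestAnnotateSpecies:
    def test_counts_and_class_label(self, ps_record):
        dup = LipidRecord("PS 18:0/16:1", "PS", ps_record.formula,
                          ps_record.ref_mz)
        ann = annotate_species([760.513, 900.0], [ps_record, dup])
        assert ann.loc[0, "n_candidates"] == 2
        assert ann.loc[1, "n_candidates"] == 0
        single = annotate_species([760.513], [ps_record])
        assert single.loc[0, "lipid_class"] == "PS"
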