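"""ROI composition estimators, tissue summaries and bulk arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopixel import (
    ControlReference,
    IonCountStack,
    ROISet,
    SceneConfig,
    TileGrid,
    excess_15n_mass,
    mixing_fraction,
    roi_composition,
    simulate_counts,
    solution_molarity,
    tissue_summary,
)
from isopixel.roi import isotope_weighted_molar_mass, roi_composition_mean_of_ratios
from isopixel.scene import homogeneous_scene, truth_to_roiset


def stack_with_cn(n15: np.ndarray, n14: np.ndarray) -> IonCountStack:
    shape = np.asarray(n15).shape
    counts = {
        "12C15N": np.asarray(n15, dtype=np.uint32),
        "12C14N": np.asarray(n14, dtype=np.uint32),
        "13C12C": np.full(shape, 100, dtype=np.uint32),
        "12C12C": np.full(shape, 10000, dtype=np.uint32),
    }
    return IonCountStack(counts=counts, pixel_size_um=1.0)


def one_roi(shape, tissue="HE", compartment="CW"):
    labels = np.ones(shape, dtype=np.uint16)
    ann = pd.DataFrame({"id": [1], "tissue": [tissue], "compartment": [compartment]})
    return ROISet(labels=labels, annotations=ann)


class TestROIComposition:
    def test_uniform_roi_equals_pixel_ratio(self):
        stack = stack_with_cn(np.full((4, 4), 50), np.full((4, 4), 950))
        tab = roi_composition(stack, one_roi((4, 4)))
        assert tab.at15n_pct[0] == pytest.approx(5.0)

    def test_ratio_of_sums_differs_from_mean_of_ratios(self):
        # pixels (10, 90) and (90, 110): ratio of sums 100/300 = 33.33 at%,
        # mean of per-pixel ratios (10 + 45)/2 = 27.5 at%
        stack = stack_with_cn(np.array([[10, 90]]), np.array([[90, 110]]))
        rois = one_roi((1, 2))
        ros = roi_composition(stack, rois)
        mor = roi_composition_mean_of_ratios(stack, rois)
        assert ros.at15n_pct[0] == pytest.approx(100 * 100 / 300, abs=1e-9)
        assert mor.at15n_pct[0] == pytest.approx(27.5, abs=1e-9)
        # equal-denominator case: the two estimators coincide
        stack2 = stack_with_cn(np.array([[0, 100]]), np.array([[100, 0]]))
        assert roi_composition(stack2, rois).at15n_pct[0] == pytest.approx(50.0)
        assert roi_composition_mean_of_ratios(stack2, rois).at15n_pct[0] == \
            pytest.approx(50.0)

    def test_simulated_uniform_scene_recovered_within_3se(self):
        truth = homogeneous_scene(config=SceneConfig(shape=(80, 80), seed=5), ape15n=4.63)
        tiles = simulate_counts(truth, TileGrid(1, 1, 80), seed=6)
        labels = np.ones((80, 80), dtype=np.uint16)
        rois = ROISet(labels=labels, annotations=pd.DataFrame(
            {"id": [1], "tissue": ["PC"], "compartment": ["L"]}))
        tab = roi_composition(tiles[0], rois)
        n15 = tiles[0].counts["12C15N"].sum()
        n14 = tiles[0].counts["12C14N"].sum()
        se = 100 * np.sqrt(n15 * n14 / (n15 + n14) ** 3)
        assert abs(tab.at15n_pct[0] - 5.0) < 3 * se

    def test_merge_additivity(self, rng):
        # pooling two ROIs re-derives the composition from summed intensities
        from conftest import make_stack

        stack = make_stack(rng, shape=(8, 8))
        labels = np.zeros((8, 8), dtype=np.uint16)
        labels[:, :3] = 1
        labels[:, 3:] = 2
        two = ROISet(labels=labels, annotations=pd.DataFrame(
            {"id": [1, 2], "tissue": ["HE", "HE"], "compartment": ["CW", "CW"]}))
        merged = ROISet(labels=(labels > 0).astype(np.uint16),
                        annotations=pd.DataFrame(
                            {"id": [1], "tissue": ["HE"], "compartment": ["CW"]}))
        t2 = roi_composition(stack, two)
        t1 = roi_composition(stack, merged)
        for ch, num_sp, den_extra in (("at15n_pct", "12C15N", "12C14N"),):
            s15 = (t2["mean_12C15N"] * t2["n_px"]).sum()
            s14 = (t2["mean_12C14N"] * t2["n_px"]).sum()
            assert t1[ch][0] == pytest.approx(100 * s15 / (s15 + s14), rel=1e-12)
        assert t1["n_px"][0] == t2["n_px"].sum()

    def test_ape_uses_control(self, control):
        stack = stack_with_cn(np.full((4, 4), 50), np.full((4, 4), 950))
        tab = roi_composition(stack, one_roi((4, 4)), control=control)
        assert tab.ape15n_pct[0] == pytest.approx(5.0 - 0.37)

    def test_empty_roi_rejected(self):
        stack = stack_with_cn(np.full((4, 4), 5), np.full((4, 4), 95))
        labels = np.ones((4, 4), dtype=np.uint16)
        labels[0, 0] = 2
        rois = ROISet.__new__(ROISet)  # bypass validation to hit the guard
        rois.labels = labels * (labels == 1)
        rois.annotations = pd.DataFrame(
            {"id": [1, 2], "tissue": ["HE", "HE"], "compartment": ["CW", "L"]})
        with pytest.raises(Exception, match="(?i)mismatch|empty"):
            roi_composition(stack, rois)


class TestTissueSummary:
    def test_basic_statistics(self):
        tab = pd.DataFrame({
            "tissue": ["HE"] * 3, "compartment": ["CW"] * 3,
            "at13c_pct": [1.0, 2.0, 3.0], "at15n_pct": [1.0, 2.0, 3.0],
        })
        s = tissue_summary(tab)
        assert s.n[0] == 3
        assert s.at13c_mean[0] == 2.0
        assert s.at13c_rsd[0] == pytest.approx(0.5)  # sample SD 1 / mean 2
        assert (s.at13c_min[0], s.at13c_max[0]) == (1.0, 3.0)

    def test_single_roi_group_rsd_zero(self):
        tab = pd.DataFrame({"tissue": ["VT"], "compartment": ["L"],
                            "at13c_pct": [1.14], "at15n_pct": [1.56]})
        s = tissue_summary(tab)
        assert s.at13c_rsd[0] == 0.0
        assert s.at13c_min[0] == s.at13c_mean[0] == s.at13c_max[0]

    def test_simulated_scene_has_configured_categories(self, small_scene):
        truth, grid, tiles = small_scene
        from isopixel.mosaic import MosaicLayout, assemble_mosaic

        layout = MosaicLayout.from_grid(grid, truth.config.pixel_size_um)
        canvas, _ = assemble_mosaic(tiles, layout)
        rois = truth_to_roiset(truth)
        s = tissue_summary(roi_composition(canvas, rois))
        groups = set(zip(s.tissue, s.compartment))
        tissues = {t for t, _ in groups}
        assert tissues == {"HE", "HM", "HN", "PC", "E", "VT"}
        comps = {c for _, c in groups}
        assert comps == {"CW", "L"}


class TestMixingFraction:
    def test_one_fifth_replacement(self):
        # observed 20 at% vs a 99 at% source over 0.37 at% background
        f = mixing_fraction(20.0, 99.0, 0.37)
        assert f == pytest.approx(0.199, abs=0.0005)

    def test_end_members(self):
        assert mixing_fraction(0.37, 99.0, 0.37) == 0.0
        assert mixing_fraction(99.0, 99.0, 0.37) == 1.0

    def test_degenerate_source_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mixing_fraction(5.0, 0.37, 0.37)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert mixing_fraction(0.1, 99.0, 0.37) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.37, 99.0), st.floats(0.37, 99.0))
    def test_strictly_increasing_in_observed(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert mixing_fraction(lo, 99.0, 0.37) <= mixing_fraction(hi, 99.0, 0.37)


class TestSolutionArithmetic:
    def test_labelled_ammonium_chloride_is_one_millimolar(self):
        # 98 at% 15N-NH4Cl at 54.5 mg/l -> ~1 mM N
        m = isotope_weighted_molar_mass("NH4Cl", label_at_pct=98.0)
        assert m == pytest.approx(54.46, abs=0.05)
        mm = solution_molarity(54.5, formula="NH4Cl", label_at_pct=98.0)
        assert mm == pytest.approx(1.0, abs=0.01)

    def test_amino_acid_mix_assumed_molar_mass(self):
        # 140 mg/l at an assumed 140 g/mol with one N per molecule -> 1 mM N
        assert solution_molarity(140.0, molar_mass=140.0, n_label_atoms=1) == \
            pytest.approx(1.0, abs=1e-12)

    def test_zero_concentration(self):
        assert solution_molarity(0.0, formula="NH4Cl") == 0.0

    def test_unknown_formula_rejected(self):
        with pytest.raises(ValueError):
            solution_molarity(10.0, formula="Xx9")


class TestExcessMass:
    def test_zero_ape_gives_zero(self):
        assert excess_15n_mass(0.0, 100.0)["excess_15n_ug"] == 0.0

    def test_linear_in_total_mass(self):
        a = excess_15n_mass(2.0, 100.0)["excess_15n_ug"]
        b = excess_15n_mass(2.0, 200.0)["excess_15n_ug"]
        assert b == pytest.approx(2 * a)

    def test_conventions_differ_by_isotope_mass_ratio(self):
        atomic = excess_15n_mass(3.0, 50.0, convention="atomic")["excess_15n_ug"]
        mass = excess_15n_mass(3.0, 50.0, convention="mass")["excess_15n_ug"]
        assert atomic / mass == pytest.approx(15.000109 / 14.007, rel=1e-9)
        assert mass == pytest.approx(50.0 * 0.03)
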