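"""Densitometry: formula examples, naive-loop oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import naive_oracles as oracle
from pulmoquant import (
    AerationRanges,
    CTVolume,
    LungMask,
    air_volume,
    classify_aeration,
    compartment_fractions,
    functional_biomarkers,
    hu_histogram,
    lung_volume,
    mean_lung_attenuation,
    region_select,
)
from pulmoquant.errors import EmptyRegionError


def vol_of(data, voxel=0.05, phase="P02"):
    return CTVolume(np.asarray(data, dtype=np.float32), voxel, phase, "S", 21)


def full_sel(shape):
    return np.ones(shape, dtype=bool)


class TestLungVolume:
    def test_thousand_voxels_at_50um(self):
        data = np.zeros((10, 10, 10), dtype=np.float32)
        assert lung_volume(vol_of(data), full_sel((10, 10, 10))) == pytest.approx(0.125)

    def test_single_unit_voxel(self):
        assert lung_volume(vol_of(np.zeros((1, 1, 1)), voxel=1.0), full_sel((1, 1, 1))) == 1.0

    def test_full_8cube(self):
        assert lung_volume(vol_of(np.zeros((8, 8, 8))), full_sel((8, 8, 8))) == pytest.approx(
            512 * 1.25e-4
        )

    def test_empty_selection(self):
        with pytest.raises(EmptyRegionError):
            lung_volume(vol_of(np.zeros((2, 2, 2))), np.zeros((2, 2, 2), dtype=bool))


class TestMeanLungAttenuation:
    def test_constant(self):
        assert mean_lung_attenuation(vol_of(np.full((3, 3, 3), -1000.0)), full_sel((3, 3, 3))) == -1000.0

    def test_two_voxel_symmetry(self):
        sel = np.array([[[True, True]]])
        assert mean_lung_attenuation(vol_of([[[-800.0, -400.0]]]), sel) == -600.0

    def test_matches_naive_sum(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(-1000, 200, size=(5, 5, 5)).astype(np.float32)
        labels = np.ones((5, 5, 5), dtype=np.uint8)
        got = mean_lung_attenuation(vol_of(data), full_sel((5, 5, 5)))
        want = oracle.naive_mla(data.tolist(), labels.tolist(), {1})
        assert got == pytest.approx(want, rel=1e-12)


class TestAirVolume:
    @pytest.mark.parametrize(
        "v,mla,expected",
        [(0.125, -1000.0, 0.125), (0.125, 0.0, 0.0), (100.0, -500.0, 50.0)],
    )
    def test_formula(self, v, mla, expected):
        assert air_volume(v, mla) == pytest.approx(expected)

    def test_negative_not_clipped(self):
        assert air_volume(1.0, 200.0) == pytest.approx(-0.2)


class TestClassifyAeration:
    @pytest.mark.parametrize(
        "hu,expected",
        [
            (-860.0, "normo"),   # closed lower bound of the normo window
            (-435.0, "normo"),   # closed upper bound: tie goes to normo
            (-434.9, "hypo"),
            (-121.1, "hypo"),
            (-121.0, "non"),     # closed lower bound: tie goes to non
            (121.0, "non"),
            (-900.0, "other"),   # hyper-aerated, below every printed window
            (122.0, "other"),
            (-860.1, "other"),
        ],
    )
    def test_bracket_convention(self, hu, expected):
        assert classify_aeration(hu) == expected

    @given(st.floats(min_value=-1200, max_value=400, allow_nan=False))
    def test_agrees_with_naive_everywhere(self, hu):
        assert classify_aeration(hu) == oracle.naive_classify(hu)


class TestCompartmentFractions:
    def test_eight_voxel_toy_field(self):
        data = np.array([-900.0, -800.0, -700.0, -500.0, -300.0, -200.0, -100.0, 0.0])
        v = vol_of(data.reshape(2, 2, 2))
        fr = compartment_fractions(v, full_sel((2, 2, 2)))
        assert fr == pytest.approx((37.5, 25.0, 25.0, 12.5))

    def test_constant_normo(self):
        fr = compartment_fractions(vol_of(np.full((3, 3, 3), -600.0)), full_sel((3, 3, 3)))
        assert fr == pytest.approx((100.0, 0.0, 0.0, 0.0))

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(11)
        data = rng.uniform(-1100, 300, size=(7, 7, 7)).astype(np.float32)
        fr = compartment_fractions(vol_of(data), full_sel((7, 7, 7)))
        assert sum(fr) == pytest.approx(100.0, abs=1e-9)


class TestOracleEquivalence:
    """Exact agreement with the naive loop on many random small fields."""

    @pytest.mark.parametrize("trial", range(100))
    def test_fractions_and_mla_match_naive(self, trial):
        rng = np.random.default_rng(1000 + trial)
        shape = tuple(rng.integers(3, 10, size=3))
        data = rng.uniform(-1100, 300, size=shape).astype(np.float32)
        labels = rng.integers(0, 3, size=shape).astype(np.uint8)
        if not labels.any():
            labels[0, 0, 0] = 1
        vol = vol_of(data)
        mask = LungMask(labels)
        sel = region_select(mask, "whole")
        got_fr = compartment_fractions(vol, sel)
        want_fr = oracle.naive_fractions(data.tolist(), labels.tolist(), {1, 2})
        assert got_fr == pytest.approx(want_fr, abs=0)  # exact
        got_mla = mean_lung_attenuation(vol, sel)
        want_mla = oracle.naive_mla(data.tolist(), labels.tolist(), {1, 2})
        assert got_mla == pytest.approx(want_mla, rel=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_histogram_matches_naive(self, trial):
        rng = np.random.default_rng(2000 + trial)
        data = rng.uniform(-1000, 100, size=(6, 6, 6)).astype(np.float32)
        vol = vol_of(data)
        width = float(rng.choice([10.0, 50.0, 137.0]))
        h = hu_histogram(vol, full_sel((6, 6, 6)), bin_width=width)
        edges, counts = oracle.naive_histogram(
            [float(x) for x in data.ravel()], width
        )
        np.testing.assert_allclose(h.bin_edges, edges, rtol=0, atol=1e-9)
        assert h.counts.tolist() == counts
        assert h.n == data.size


class TestHistogram:
    def test_four_voxel_brute_force(self):
        v = vol_of(np.array([-1000.0, -1000.0, -500.0, 0.0]).reshape(1, 2, 2))
        h = hu_histogram(v, full_sel((1, 2, 2)), bin_width=500.0)
        assert h.counts.tolist() == [2, 2]
        np.testing.assert_allclose(h.bin_edges, [-1000.0, -500.0, 0.0])

    def test_constant_field_single_bin(self):
        v = vol_of(np.full((4, 4, 4), -647.5))
        h = hu_histogram(v, full_sel((4, 4, 4)), bin_width=10.0)
        assert len(h.counts) == 1 and h.counts[0] == 64

    def test_counts_sum_to_selection_size(self, small_phantom):
        pair, _ = small_phantom
        v, m = pair.p02
        sel = region_select(m, "left")
        h = hu_histogram(v, sel, bin_width=10.0, region="left")
        assert h.n == int(sel.sum())


class TestFunctionalBiomarkers:
    def test_worked_two_phase_example(self, pair_factory):
        # P01 fully aerated at -1000 HU, P02 at -500 HU, volumes 0.2 / 0.1 mm^3
        voxel = 0.05
        n01 = int(round(0.2 / voxel**3))  # 1600 voxels
        n02 = int(round(0.1 / voxel**3))  # 800 voxels
        d01 = np.full((n01, 1, 1), -1000.0)
        d02 = np.full((n02, 1, 1), -500.0)
        pair = pair_factory(d01, d02)
        rec = functional_biomarkers(pair, "whole")
        assert rec.air == pytest.approx(0.2)
        assert rec.frc == pytest.approx(0.05)
        assert rec.tv == pytest.approx(0.15)
        assert rec.tissue == pytest.approx(0.05)
        assert rec.pct_gas_p01 == pytest.approx(100.0)
        assert rec.pct_gas_p02 == pytest.approx(50.0)

    def test_identical_phases_zero_tidal_volume(self, pair_factory):
        rng = np.random.default_rng(5)
        data = rng.uniform(-900, 0, size=(6, 6, 6))
        pair = pair_factory(data, data)
        rec = functional_biomarkers(pair, "whole")
        assert rec.tv == pytest.approx(0.0, abs=1e-12)

    def test_gas_fraction_equals_minus_mla_over_ten(self, small_phantom):
        pair, _ = small_phantom
        for region in ("whole", "left", "right"):
            rec = functional_biomarkers(pair, region)
            assert rec.pct_gas_p01 == pytest.approx(-rec.mla_p01 / 10.0, rel=1e-9)
            assert rec.pct_gas_p02 == pytest.approx(-rec.mla_p02 / 10.0, rel=1e-9)

    def test_conservation_identities(self, small_phantom):
        pair, _ = small_phantom
        for region in ("whole", "left", "right"):
            rec = functional_biomarkers(pair, region)
            assert rec.tissue + rec.frc == pytest.approx(rec.v_p02, rel=1e-12)
            assert rec.tv == pytest.approx(rec.air - rec.frc, rel=1e-12)
            assert rec.v_p01 == pytest.approx(rec.n_p01 * 0.05**3, rel=1e-12)
            assert rec.v_p02 == pytest.approx(rec.n_p02 * 0.05**3, rel=1e-12)

    def test_negative_frc_flagged(self, pair_factory):
        pair = pair_factory(np.full((4, 4, 4), -500.0), np.full((4, 4, 4), 60.0))
        rec = functional_biomarkers(pair, "whole")
        assert rec.frc < 0
        assert "negative_frc" in rec.flags


class TestMonotonicity:
    @given(st.integers(min_value=0, max_value=124), st.floats(min_value=1.0, max_value=400.0))
    def test_raising_a_voxel_raises_mla_and_lowers_air(self, flat_idx, bump):
        rng = np.random.default_rng(99)
        data = rng.uniform(-1000, 100, size=(5, 5, 5)).astype(np.float32)
        vol_a = vol_of(data)
        sel = full_sel((5, 5, 5))
        data_b = data.copy()
        data_b.ravel()[flat_idx] += bump
        vol_b = vol_of(data_b)
        mla_a = mean_lung_attenuation(vol_a, sel)
        mla_b = mean_lung_attenuation(vol_b, sel)
        assert mla_b >= mla_a
        v = lung_volume(vol_a, sel)
        assert air_volume(v, mla_b) <= air_volume(v, mla_a)


def test_custom_ranges_must_be_ordered():
    with pytest.raises(ValueError):
        AerationRanges(normo=(-435.0, -860.0))
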