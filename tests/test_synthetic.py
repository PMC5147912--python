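"""Generator contracts: determinism, planted-signal fidelity, dose model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foxscreen as fx
from foxscreen.core import PlateLayout
from foxscreen.synthetic import (
    CellSpec,
    PlacementError,
    PlateGroundTruth,
    rasterize_cell,
)


class TestRenderWell:
    def test_empty_field_is_pure_background(self):
        spec = fx.WellSpec(n_cells=0, image_shape=(128, 128),
                           noise=fx.NoiseSpec(background_level=100.0, read_noise_sd=2.0))
        pair, truth = fx.render_well(spec)
        assert len(truth) == 0
        assert abs(float(pair.dapi.mean()) - 100.0) < 1.0
        assert abs(float(pair.gfp.mean()) - 100.0) < 1.0

    def test_same_seed_bit_identical(self):
        spec = fx.WellSpec(n_cells=30, image_shape=(256, 256),
                           translocation_fraction=0.5, seed=9)
        p1, t1 = fx.render_well(spec)
        p2, t2 = fx.render_well(spec)
        assert np.array_equal(p1.dapi, p2.dapi)
        assert np.array_equal(p1.gfp, p2.gfp)
        assert t1.cells == t2.cells

    def test_different_seed_differs(self):
        spec = fx.WellSpec(n_cells=30, image_shape=(256, 256), seed=1)
        other = dataclasses.replace(spec, seed=2)
        assert not np.array_equal(fx.render_well(spec)[0].gfp, fx.render_well(other)[0].gfp)

    def test_planted_ratio_exact_on_clean_image(self, clean_well):
        """Planted masks on a noise-free render return nc_ratio_true (2.5)."""
        spec, pair, truth = clean_well
        for cell in truth.cells:
            nuc, cyt = rasterize_cell(cell, spec.image_shape)
            ratio = pair.gfp[nuc].mean() / pair.gfp[cyt].mean()
            assert ratio == pytest.approx(2.5, abs=0.05)
            assert ratio == pytest.approx(cell.nc_ratio_true, rel=0.02)

    def test_gfp_conserved_over_cell(self, clean_well):
        """Summed GFP over the planted compartments equals gfp_total up to
        16-bit quantization (all pixels of a compartment share one value, so
        the rounding error is at most half a count per pixel)."""
        spec, pair, truth = clean_well
        for cell in truth.cells:
            nuc, cyt = rasterize_cell(cell, spec.image_shape)
            n_pixels = int(nuc.sum() + cyt.sum())
            total = float(pair.gfp[nuc].sum() + pair.gfp[cyt].sum())
            assert total == pytest.approx(cell.gfp_total, abs=0.5 * n_pixels + 1)

    def test_placement_failure_names_density(self):
        spec = fx.WellSpec(n_cells=50, image_shape=(80, 80), seed=0)
        with pytest.raises(PlacementError, match="density"):
            fx.render_well(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            fx.WellSpec(n_cells=-1)
        with pytest.raises(ValueError):
            fx.WellSpec(translocation_fraction=1.5)
        with pytest.raises(ValueError):
            fx.NoiseSpec(background_level=-1)
        with pytest.raises(ValueError):
            CellSpec((10, 10), (2, 5), 0.0, 100.0, 1000.0, 1.0, False)
        with pytest.raises(ValueError):
            CellSpec((10, 10), (5, 5), 0.0, 100.0, -1.0, 1.0, False)


class TestDoseModel:
    def test_midpoint_and_limits(self):
        m = fx.TranslocationDoseModel(bottom_fraction=0.1, top_fraction=0.9,
                                      ec50=1.5, hill=1.3)
        assert fx.translocation_fraction_at(m, 1.5) == pytest.approx(0.5)
        assert fx.translocation_fraction_at(m, 0.0) == 0.1
        with pytest.raises(ValueError):
            fx.translocation_fraction_at(m, -1.0)

    def test_direct_evaluation(self):
        # bottom=0, top=1, hill=1, ec50=1.5 at conc 4.5: 1/(1 + 1.5/4.5) = 0.75
        m = fx.TranslocationDoseModel(bottom_fraction=0.0, top_fraction=1.0,
                                      ec50=1.5, hill=1.0)
        assert fx.translocation_fraction_at(m, 4.5) == pytest.approx(0.75)

    @settings(max_examples=50, deadline=None)
    @given(
        c1=st.floats(0.0, 100.0),
        c2=st.floats(0.0, 100.0),
        hill=st.floats(0.2, 4.0),
        ec50=st.floats(0.01, 50.0),
    )
    def test_monotone_in_concentration(self, c1, c2, hill, ec50):
        m = fx.TranslocationDoseModel(bottom_fraction=0.05, top_fraction=0.95,
                                      ec50=ec50, hill=hill)
        lo, hi = sorted((c1, c2))
        assert fx.translocation_fraction_at(m, lo) <= fx.translocation_fraction_at(m, hi) + 1e-12

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            fx.TranslocationDoseModel(bottom_fraction=0.9, top_fraction=0.1)
        with pytest.raises(ValueError):
            fx.TranslocationDoseModel(ec50=0.0)


class TestRenderPlate:
    base = fx.WellSpec(n_cells=15, image_shape=(256, 256))

    def test_empty_layout(self):
        layout = PlateLayout.from_entries([], plate_id="empty")
        pairs, truth = fx.render_plate(layout, fx.TranslocationDoseModel(), self.base, seed=0)
        assert pairs == {}
        assert truth.to_frame().empty

    def test_planted_fractions_monotone_in_dose(self):
        concs = 50.0 / 2.0 ** np.arange(8)
        layout = PlateLayout.dose_response("cpd", concs, n_negative=2, n_positive=2)
        model = fx.TranslocationDoseModel(ec50=1.5)
        _, truth = fx.render_plate(layout, model, self.base, seed=4)
        by_conc = sorted(
            (e.conc, truth.planted_fractions[e.well])
            for e in layout.entries(roles=["compound"])
        )
        fracs = [f for _, f in by_conc]
        assert fracs == sorted(fracs)

    def test_controls_use_model_extremes(self):
        layout = PlateLayout.from_entries(
            [("A01", "negative", None, None, None), ("A12", "positive", None, None, None)]
        )
        model = fx.TranslocationDoseModel(bottom_fraction=0.1, top_fraction=0.8)
        _, truth = fx.render_plate(layout, model, self.base, seed=1)
        assert truth.planted_fractions["A01"] == 0.1
        assert truth.planted_fractions["A12"] == 0.8

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown well role"):
            PlateLayout.from_entries([("A01", "mystery", None, None, None)])

    def test_per_well_seeds_are_deterministic_and_distinct(self):
        layout = PlateLayout.from_entries(
            [("A01", "negative", None, None, None), ("B01", "negative", None, None, None)]
        )
        model = fx.TranslocationDoseModel()
        p1, _ = fx.render_plate(layout, model, self.base, seed=7)
        p2, _ = fx.render_plate(layout, model, self.base, seed=7)
        assert np.array_equal(p1["A01"].gfp, p2["A01"].gfp)
        assert not np.array_equal(p1["A01"].gfp, p1["B01"].gfp)


class TestMttTable:
    def test_structure_and_determinism(self):
        concs = 50.0 / 2.0 ** np.arange(20)
        t1 = fx.simulate_mtt_table(0.64, concs, seed=3)
        t2 = fx.simulate_mtt_table(0.64, concs, seed=3)
        assert t1.equals(t2)
        assert set(t1["role"]) == {"vehicle", "blank", "treated"}
        assert (t1["absorbance"] >= 0).all()
        assert t1[t1.role == "treated"].groupby("conc").size().eq(3).all()
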