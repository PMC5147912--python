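"""Dilution series arithmetic, 4PL fitting, viability normalization."""

import numpy as np
import pandas as pd
import pytest

import foxscreen as fx
from foxscreen.dose_response import ec50_from_plate, fit_4pl
from foxscreen.quantification import WellSummary
from foxscreen.core import PlateLayout
from conftest import grid_4pl_oracle


def _4pl(c, bottom, top, mid, hill):
    return bottom + (top - bottom) / (1.0 + (mid / np.asarray(c)) ** hill)


class TestDilutionSeries:
    def test_eight_point_twofold_endpoint(self):
        s = fx.make_dilution_series(50.0, 2, 8)
        assert s.concentrations[0] == 50.0
        assert s.concentrations[-1] == pytest.approx(0.390625)
        assert round(s.concentrations[-1], 2) == 0.39

    def test_twenty_point_twofold_endpoint_in_pM(self):
        s = fx.make_dilution_series(50.0, 2, 20)  # uM
        last_pM = s.concentrations[-1] * 1e6
        assert last_pM == pytest.approx(95.367, abs=1e-3)
        assert round(last_pM) == 95

    def test_single_point(self):
        assert fx.make_dilution_series(7.0, 2, 1).concentrations.tolist() == [7.0]

    def test_strictly_decreasing(self):
        s = fx.make_dilution_series(10.0, 3, 9)
        assert (np.diff(s.concentrations) < 0).all()

    @pytest.mark.parametrize("args", [(0, 2, 8), (10, 1.0, 8), (10, 2, 0)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            fx.make_dilution_series(*args)


class TestFit4PL:
    conc8 = fx.make_dilution_series(50.0, 2, 8).concentrations

    def test_noiseless_self_consistency(self):
        y = _4pl(self.conc8, 0.0, 100.0, 1.5, 1.0)
        f = fit_4pl(self.conc8, y)
        assert f.converged
        assert f.midpoint == pytest.approx(1.5, rel=1e-6)
        assert f.bottom == pytest.approx(0.0, abs=1e-4)
        assert f.top == pytest.approx(100.0, abs=1e-4)
        assert f.hill == pytest.approx(1.0, rel=1e-4)

    def test_constant_response_not_converged(self):
        f = fit_4pl(self.conc8, np.full(8, 42.0))
        assert not f.converged
        assert np.isnan(f.midpoint)
        assert np.isinf(f.rss)

    def test_noisy_recovery_and_grid_oracle_agreement(self):
        rng = np.random.default_rng(123)
        y = _4pl(self.conc8, 0.0, 100.0, 1.5, 1.0) + rng.normal(0, 5, 8)
        f = fit_4pl(self.conc8, y)
        assert f.converged
        assert f.midpoint == pytest.approx(1.5, rel=0.2)
        rss_o, mid_o, _ = grid_4pl_oracle(self.conc8, y)
        assert f.rss <= rss_o * 1.01  # optimizer at least matches the grid
        assert f.midpoint == pytest.approx(mid_o, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rss_within_one_percent_of_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        conc = fx.make_dilution_series(50.0, 2, 12).concentrations
        y = _4pl(conc, 10.0, 90.0, 2.0, 1.3) + rng.normal(0, 5, conc.size)
        f = fit_4pl(conc, y)
        rss_o, _, _ = grid_4pl_oracle(conc, y)
        assert f.rss <= rss_o * 1.01

    def test_decreasing_direction(self):
        y = _4pl(self.conc8, 100.0, 5.0, 2.0, 1.0)  # viability-style, falls with dose
        f = fit_4pl(self.conc8, y, direction="decreasing")
        assert f.converged and f.hill < 0
        assert f.midpoint == pytest.approx(2.0, rel=1e-5)

    def test_concentration_rescaling_rescales_midpoint(self):
        y = _4pl(self.conc8, 0.0, 100.0, 1.5, 1.2)
        f1 = fit_4pl(self.conc8, y)
        f2 = fit_4pl(self.conc8 * 1000.0, y)  # e.g. uM -> nM relabeling
        assert f2.midpoint == pytest.approx(f1.midpoint * 1000.0, rel=1e-6)

    def test_parameter_recovery_over_many_noisy_datasets(self):
        """Median relative midpoint error < 10% over 50 simulated series at
        response noise sd 5 (triplicate wells per dose, the assay's design)."""
        conc = np.repeat(fx.make_dilution_series(50.0, 2, 12).concentrations, 3)
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            y = _4pl(conc, 0.0, 100.0, 1.5, 1.0) + rng.normal(0, 5, conc.size)
            f = fit_4pl(conc, y)
            assert f.converged
            errs.append(abs(f.midpoint - 1.5) / 1.5)
        assert np.median(errs) < 0.10

    def test_absolute_fifty_crossing_reported(self):
        y = _4pl(self.conc8, 20.0, 80.0, 2.0, 1.0)
        f = fit_4pl(self.conc8, y)
        # bottom 20 / top 80 bracket 50, and by symmetry the crossing is at
        # the relative midpoint itself
        assert f.midpoint_abs == pytest.approx(2.0, rel=1e-5)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_4pl([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="> 0"):
            fit_4pl([0, 1, 2, 4, 8], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="finite"):
            fit_4pl([1, 2, 4, 8, 16], [1, 2, np.nan, 4, 5])


class TestViability:
    def _table(self, treated):
        rows = [("vehicle", None, a) for a in (1.0, 1.0)] + [
            ("blank", None, a) for a in (0.1, 0.1)
        ]
        rows += [("treated", conc, a) for conc, a in treated]
        return pd.DataFrame(rows, columns=["role", "conc", "absorbance"])

    def test_anchor_points(self):
        v = fx.viability_from_absorbance(self._table([(1.0, 1.0), (2.0, 0.1)]))
        by = dict(zip(v["conc"], v["viability_mean"]))
        assert by[1.0] == pytest.approx(100.0)
        assert by[2.0] == pytest.approx(0.0)

    def test_halfway_example(self):
        v = fx.viability_from_absorbance(self._table([(1.0, 0.55)]))
        assert v["viability_mean"].iloc[0] == pytest.approx(50.0)

    def test_replicates_averaged_with_sd(self):
        v = fx.viability_from_absorbance(self._table([(1.0, 0.5), (1.0, 0.6)]))
        assert len(v) == 1
        assert v["n"].iloc[0] == 2
        assert v["viability_sd"].iloc[0] > 0

    def test_degenerate_controls_rejected(self):
        rows = [("vehicle", None, 0.5), ("blank", None, 0.5), ("treated", 1.0, 0.4)]
        with pytest.raises(ValueError):
            fx.viability_from_absorbance(pd.DataFrame(rows, columns=["role", "conc", "absorbance"]))

    def test_missing_controls_rejected(self):
        rows = [("treated", 1.0, 0.4)]
        with pytest.raises(ValueError):
            fx.viability_from_absorbance(pd.DataFrame(rows, columns=["role", "conc", "absorbance"]))


class TestEc50FromPlate:
    def _summaries_layout(self, concs, pcts, replicates=1):
        layout = PlateLayout.dose_response("cpd", concs, n_negative=2, n_positive=2,
                                           replicates=replicates)
        summaries = {}
        wells = layout.wells("compound")
        pcts_rep = np.repeat(pcts, replicates)
        for w, p in zip(wells, pcts_rep):
            summaries[w] = WellSummary(w, 150, float(p), 40.0, [])
        for w in layout.wells("negative"):
            summaries[w] = WellSummary(w, 150, 5.0, 40.0, [])
        for w in layout.wells("positive"):
            summaries[w] = WellSummary(w, 150, 85.0, 40.0, [])
        return summaries, layout

    def test_recovers_planted_midpoint(self):
        concs = fx.make_dilution_series(50.0, 2, 12).concentrations
        pcts = 5.0 + 80.0 * (1.0 / (1.0 + 1.5 / concs))
        summaries, layout = self._summaries_layout(concs, pcts)
        controls = fx.ControlStats(85.0, 2.0, 5.0, 2.0, 2, 2)
        fits = ec50_from_plate(summaries, layout, controls)
        assert fits["cpd"].converged
        assert fits["cpd"].midpoint == pytest.approx(1.5, rel=1e-5)

    def test_duplicate_wells_equal_averaging_first(self):
        concs = fx.make_dilution_series(50.0, 2, 8).concentrations
        rng = np.random.default_rng(5)
        pcts = 5.0 + 80.0 / (1.0 + 1.5 / concs) + rng.normal(0, 2, 8)
        controls = fx.ControlStats(85.0, 2.0, 5.0, 2.0, 2, 2)
        s_dup, l_dup = self._summaries_layout(concs, pcts, replicates=2)
        fit_dup = ec50_from_plate(s_dup, l_dup, controls)["cpd"]
        s_avg, l_avg = self._summaries_layout(concs, pcts, replicates=1)
        fit_avg = ec50_from_plate(s_avg, l_avg, controls)["cpd"]
        assert fit_dup.midpoint == pytest.approx(fit_avg.midpoint, rel=1e-4)
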