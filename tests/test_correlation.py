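"""Size-energy correlation fitting, inversion and dispersion statistics."""

import numpy as np
import pytest

import nanomill as nm
from nanomill.errors import ExtrapolationWarning, FitError
from nanomill.io import BatchRecord


def table_from_law(E_values, a=1000.0, b=-0.25, noise=None, rng=None):
    records = []
    for i, E in enumerate(E_values, start=1):
        x = a * E**b
        if noise:
            x *= 1.0 + noise * rng.standard_normal()
        records.append(
            BatchRecord(str(i), 5.0, 100.0, 1050.0, 16.0, 9.0, 21.0, float(E), 0.88,
                        50.0, float(x), 0.11)
        )
    return records


class TestFitSizeEnergy:
    def test_exact_power_law_recovery(self):
        records = table_from_law(np.linspace(500, 4000, 12))
        corr = nm.fit_size_energy(records)
        assert corr.exponent == pytest.approx(-0.25, abs=1e-9)
        assert corr.intercept == pytest.approx(1000.0, rel=1e-9)

    def test_two_points_fit_exactly(self):
        records = table_from_law([600.0, 2400.0])
        corr = nm.fit_size_energy(records)
        for r in records:
            assert nm.predict_size(corr, r.E_M_kJ_kg) == pytest.approx(
                r.x_PCS_nm, rel=1e-12
            )

    def test_single_energy_value_is_degenerate(self):
        records = table_from_law([2000.0, 2000.0, 2000.0])
        with pytest.raises(FitError):
            nm.fit_size_energy(records)

    def test_reference_fit_has_negative_exponent(self, fitted_corr):
        assert fitted_corr.exponent < 0

    def test_order_invariance_and_unit_rescaling(self, reference_records):
        corr = nm.fit_size_energy(reference_records)
        shuffled = list(reference_records)[::-1]
        corr2 = nm.fit_size_energy(shuffled)
        assert corr2.exponent == pytest.approx(corr.exponent, rel=1e-12)
        # rescaling E by c leaves the exponent unchanged, intercept -> a*c^-b
        import dataclasses

        c = 3.7
        scaled = [
            dataclasses.replace(r, E_M_kJ_kg=r.E_M_kJ_kg * c)
            for r in reference_records
        ]
        corr3 = nm.fit_size_energy(scaled)
        assert corr3.exponent == pytest.approx(corr.exponent, rel=1e-9)
        assert corr3.intercept == pytest.approx(
            corr.intercept * c**-corr.exponent, rel=1e-9
        )

    def test_grinding_limit_form_recovery(self):
        E = np.linspace(400, 4000, 15)
        records = []
        for i, e in enumerate(E):
            x = 80.0 + 900.0 * e**-0.4
            records.append(
                BatchRecord(str(i), 5.0, 100.0, 1050.0, 16.0, 9.0, 21.0, float(e),
                            0.88, 50.0, float(x), 0.11)
            )
        corr = nm.fit_size_energy(records, form="grinding-limit")
        assert corr.x_lim_nm == pytest.approx(80.0, rel=1e-4)
        assert corr.exponent == pytest.approx(-0.4, rel=1e-4)


class TestPredictAndInverse:
    def test_inverse_round_trip(self, fitted_corr):
        for x in (125.0, 150.0, 170.0):
            E = nm.inverse_energy(fitted_corr, x)
            assert nm.predict_size(fitted_corr, E) == pytest.approx(x, rel=1e-9)

    def test_monotone_decreasing_over_grid(self, fitted_corr):
        grid = np.linspace(600.0, 4000.0, 50)
        pred = nm.predict_size(fitted_corr, grid)
        assert np.all(np.diff(pred) < 0)

    def test_nonpositive_energy_rejected(self, fitted_corr):
        with pytest.raises(ValueError):
            nm.predict_size(fitted_corr, -5.0)

    def test_prediction_at_2150_in_reference_bracket(self, fitted_corr):
        assert 120.0 <= nm.predict_size(fitted_corr, 2150.0) <= 135.0

    def test_inverse_monotone_decreasing(self, fitted_corr):
        assert nm.inverse_energy(fitted_corr, 120.0) > nm.inverse_energy(
            fitted_corr, 170.0
        )

    def test_extrapolation_warns_and_gross_target_raises(self, fitted_corr):
        with pytest.warns(ExtrapolationWarning):
            nm.inverse_energy(fitted_corr, 180.0)
        with pytest.raises(ValueError):
            nm.inverse_energy(fitted_corr, 500.0)


class TestGroupedStatistics:
    def test_identical_values_have_zero_rsd(self):
        records = table_from_law([1000.0, 1000.0 + 1e-9, 1000.0 + 2e-9])
        stats = nm.grouped_rsd(records, "E_M", {"g": ["1", "2", "3"]})
        assert stats.max_rsd_pct == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_formula(self, reference_records):
        ids = [str(i) for i in range(4, 13)]
        stats = nm.grouped_rsd(reference_records, "E_M", {"cluster": ids})
        vals = [r.x_PCS_nm for r in reference_records if r.experiment in ids]
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert stats.table.loc[0, "rsd_pct"] == pytest.approx(100 * sd / mean)

    def test_missing_experiment_raises_key_error(self, reference_records):
        with pytest.raises(KeyError):
            nm.grouped_rsd(reference_records, "N", {"g": ["1", "99"]})

    def test_single_member_groups_excluded(self, reference_records):
        stats = nm.grouped_rsd(reference_records, "N", {"solo": ["1"], "pair": ["9", "10"]})
        assert list(stats.table["group"]) == ["pair"]


class TestScalarStatistics:
    def test_constant_pdi_has_zero_sd(self):
        records = table_from_law([600.0, 1200.0, 2400.0])
        mean, sd, rsd = nm.pdi_statistics(records)
        assert mean == pytest.approx(0.11) and sd == 0.0

    def test_temperature_span_permutation_invariant(self, reference_records):
        span = nm.outlet_temperature_span(reference_records)
        assert span == nm.outlet_temperature_span(list(reference_records)[::-1])

    def test_identical_temperatures_span_zero(self):
        records = table_from_law([600.0, 1200.0])
        assert nm.outlet_temperature_span(records) == 0.0
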