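"""Tests for G x E matrices and seed-selection optimization."""
import numpy as np
import pytest

from ddcrop.calibration import CalibrationResult, weighted_rmse
from ddcrop.errors import InvalidInputError
from ddcrop.scenarios import (
    gxe_matrix,
    select_seed_known_weather,
    select_seed_unknown_weather,
    yield_gain_summary,
)
from ddcrop.simulator import simulate_season


@pytest.fixture(scope="module")
def truth_calib(clean_dataset):
    """A calibration result holding the generating ground truth: its fitted
    yields reproduce the (noise-free) observations exactly."""
    ds = clean_dataset
    fitted = {
        k: simulate_season(ds.weather[k], ds.management[k], ds.soil[k[1]],
                           ds.true_genotypes[k], ds.true_soil_params[k[1]])
        for k in ds.keys()
    }
    obs = [ds.observed_yields[k] for k in ds.keys()]
    areas = [ds.area(k) for k in ds.keys()]
    return CalibrationResult(
        genotypes=dict(ds.true_genotypes),
        soil_params=dict(ds.true_soil_params),
        objective=weighted_rmse(obs, list(fitted.values()), areas),
        fitted_yields=fitted,
        trace=[],
    )


class TestGxEMatrix:
    def test_diagonal_equals_fitted_training_aggregates(self, truth_calib, clean_dataset):
        mat = gxe_matrix(truth_calib, clean_dataset)
        for t in mat.years:
            keys = [k for k in clean_dataset.keys() if k[0] == t]
            w = np.array([clean_dataset.area(k) for k in keys])
            expected = float(np.average(
                [truth_calib.fitted_yields[k] for k in keys], weights=w
            ))
            assert mat.values.loc[t, t] == pytest.approx(expected, abs=1e-10)

    def test_offdiagonals_match_direct_crossed_simulations(self, truth_calib, clean_dataset):
        """Each off-diagonal cell of a 3x3 single-county matrix equals an
        independent simulator call with crossed genotype/environment years."""
        county = clean_dataset.counties()[0]
        mat = gxe_matrix(truth_calib, clean_dataset, county_set=[county])
        for t1 in mat.years:
            for t2 in mat.years:
                direct = simulate_season(
                    clean_dataset.weather[(t2, county)],
                    clean_dataset.management[(t2, county)],
                    clean_dataset.soil[county],
                    truth_calib.genotypes[(t1, county)],
                    truth_calib.soil_params[county],
                )
                assert mat.values.loc[t1, t2] == pytest.approx(direct, abs=1e-12)

    def test_identical_genotypes_and_weather_give_constant_matrix(self, truth_calib, clean_dataset):
        ds = clean_dataset
        county = ds.counties()[0]
        base_year = ds.years()[0]
        weather = {(t, county): ds.weather[(base_year, county)] for t in ds.years()}
        frozen = ds.subset([(t, county) for t in ds.years()])
        frozen.weather.update(weather)
        mat = gxe_matrix(truth_calib, frozen, county_set=[county])
        vals = mat.values.to_numpy()
        assert np.allclose(vals, vals[0, 0])


class TestSeedSelection:
    def test_pool_of_one_returns_it(self, truth_calib, clean_dataset):
        c, t = clean_dataset.counties()[0], clean_dataset.years()[-1]
        res = select_seed_known_weather(c, t, truth_calib, clean_dataset,
                                        pool=[(2001, 1)])
        assert (res.source_year, res.source_county) == (2001, 1)

    def test_known_weather_argmax_matches_enumeration(self, truth_calib, clean_dataset):
        c, t = clean_dataset.counties()[0], clean_dataset.years()[-1]
        res = select_seed_known_weather(c, t, truth_calib, clean_dataset)
        vals = {}
        for (r, d) in sorted(truth_calib.genotypes):
            if r <= t:
                vals[(r, d)] = simulate_season(
                    clean_dataset.weather[(t, c)], clean_dataset.management[(t, c)],
                    clean_dataset.soil[c], truth_calib.genotypes[(r, d)],
                    truth_calib.soil_params[c],
                )
        best = max(vals.values())
        assert res.predicted == pytest.approx(best, abs=1e-12)
        # tie-break: earliest source year, then smallest county
        winners = sorted(k for k, v in vals.items() if v == best)
        assert (res.source_year, res.source_county) == winners[0]

    def test_self_inclusion_makes_known_gain_nonnegative(self, truth_calib, clean_dataset):
        for c in clean_dataset.counties():
            t = clean_dataset.years()[-1]
            res = select_seed_known_weather(c, t, truth_calib, clean_dataset)
            assert res.gain >= -1e-12
            assert res.predicted >= res.reference - 1e-12

    def test_unknown_weather_argmax_matches_hand_average(self, truth_calib, clean_dataset):
        c = clean_dataset.counties()[1]
        t = clean_dataset.years()[-1]
        pool = [(2001, 0), (2002, 2)]
        res = select_seed_unknown_weather(c, t, truth_calib, clean_dataset, pool=pool)
        history = [tau for tau in clean_dataset.years() if tau < t]
        means = {}
        for (r, d) in pool:
            g = truth_calib.genotypes[(r, d)]
            means[(r, d)] = np.mean([
                simulate_season(clean_dataset.weather[(tau, c)],
                                clean_dataset.management[(tau, c)],
                                clean_dataset.soil[c], g,
                                truth_calib.soil_params[c])
                for tau in history
            ])
        best_rd = min(means, key=lambda k: (-means[k], k[0], k[1]))
        assert (res.source_year, res.source_county) == best_rd
        assert res.criterion == pytest.approx(means[best_rd])

    def test_stationary_weather_reduces_unknown_to_known(self, truth_calib, clean_dataset):
        """If every historical year has the target year's weather, foresight
        carries no extra information and both scenarios pick the same seed."""
        ds = clean_dataset
        c, t = ds.counties()[0], ds.years()[-1]
        frozen = ds.subset(ds.keys())
        for tau in ds.years():
            frozen.weather[(tau, c)] = ds.weather[(t, c)]
            frozen.management[(tau, c)] = ds.management[(t, c)]
        pool = [(r, d) for (r, d) in sorted(truth_calib.genotypes) if r <= t]
        known = select_seed_known_weather(c, t, truth_calib, frozen, pool=pool)
        unknown = select_seed_unknown_weather(c, t, truth_calib, frozen, pool=pool)
        assert (known.source_year, known.source_county) == (
            unknown.source_year, unknown.source_county
        )

    def test_pool_monotonicity(self, truth_calib, clean_dataset):
        """Enlarging the candidate pool never lowers the known-weather optimum."""
        c, t = clean_dataset.counties()[0], clean_dataset.years()[-1]
        full_pool = [(r, d) for (r, d) in sorted(truth_calib.genotypes) if r <= t]
        prev = -np.inf
        for n in range(1, len(full_pool) + 1):
            res = select_seed_known_weather(c, t, truth_calib, clean_dataset,
                                            pool=full_pool[:n])
            assert res.predicted >= prev - 1e-12
            prev = res.predicted

    def test_value_of_information_nonnegative(self, truth_calib, clean_dataset):
        """The known-weather optimum is at least the unknown-weather choice
        evaluated under the realized weather."""
        pool = [(r, d) for (r, d) in sorted(truth_calib.genotypes)
                if r <= clean_dataset.years()[-1]]
        t = clean_dataset.years()[-1]
        for c in clean_dataset.counties():
            known = select_seed_known_weather(c, t, truth_calib, clean_dataset, pool=pool)
            unknown = select_seed_unknown_weather(c, t, truth_calib, clean_dataset, pool=pool)
            assert known.predicted >= unknown.predicted - 1e-12

    def test_first_year_unknown_weather_rejected(self, truth_calib, clean_dataset):
        with pytest.raises(InvalidInputError):
            select_seed_unknown_weather(
                clean_dataset.counties()[0], clean_dataset.years()[0],
                truth_calib, clean_dataset,
            )


class TestYieldGainSummary:
    def test_own_genotype_selection_has_zero_gain(self, truth_calib, clean_dataset):
        t = clean_dataset.years()[-1]
        results = [
            select_seed_known_weather(c, t, truth_calib, clean_dataset,
                                      pool=[(t, c)])
            for c in clean_dataset.counties()
        ]
        summary = yield_gain_summary(results, clean_dataset)
        assert summary["gain_vs_predicted"] == pytest.approx(0.0, abs=1e-12)

    def test_percent_gain_arithmetic(self, truth_calib, clean_dataset):
        """A 0.38 Mg/ha gain over a 9.72 Mg/ha observed mean is 3.91%."""
        t = clean_dataset.years()[-1]
        results = [
            select_seed_known_weather(c, t, truth_calib, clean_dataset,
                                      pool=[(t, c)])
            for c in clean_dataset.counties()
        ]
        # rescale observations so the area-weighted mean is exactly 9.72 and
        # shift every selected yield up by 0.38
        ds = clean_dataset.subset(clean_dataset.keys())
        w = np.array([ds.area((t, c)) for c in ds.counties()])
        obs = np.array([ds.observed_yields[(t, c)] for c in ds.counties()])
        scale = 9.72 / np.average(obs, weights=w)
        for c in ds.counties():
            ds.observed_yields[(t, c)] *= scale
        shifted = [
            type(r)(**{**r.__dict__,
                       "predicted": ds.observed_yields[(r.year, r.county)] + 0.38})
            for r in results
        ]
        summary = yield_gain_summary(shifted, ds)
        assert summary["gain_vs_observed"] == pytest.approx(0.38, abs=1e-9)
        assert summary["gain_vs_observed_pct"] == pytest.approx(3.91, abs=0.005)

    def test_empty_results_rejected(self, clean_dataset):
        with pytest.raises(InvalidInputError):
            yield_gain_summary([], clean_dataset)
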