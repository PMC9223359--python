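"""Synthetic panel generator: determinism, round trips, fixture bundle."""

import numpy as np
import pytest

import riverhealth as rh
from riverhealth.synthetic import SyntheticScenario, generate_panel


class TestDeterminism:
    def test_same_seed_identical_output(self, registry):
        scenario = SyntheticScenario(seed=42)
        obs1, frame1 = generate_panel(scenario, registry)
        obs2, frame2 = generate_panel(scenario, registry)
        assert obs1 == obs2
        assert frame1.equals(frame2)

    def test_different_seeds_differ(self, registry):
        _, a = generate_panel(SyntheticScenario(seed=1), registry)
        _, b = generate_panel(SyntheticScenario(seed=2), registry)
        assert not a.equals(b)

    def test_substreams_stable_under_indicator_removal(self, registry):
        """Dropping an indicator from the registry leaves the draws of the
        remaining indicators untouched."""
        scenario = SyntheticScenario(seed=5)
        _, full = generate_panel(scenario, registry)
        reduced = rh.IndicatorRegistry(
            d for d in registry if d.indicator_id != "C7"
        )
        _, partial = generate_panel(scenario, reduced)
        common = [c for c in partial.columns]
        assert full[common].equals(partial[common])


class TestRoundTrip:
    def test_scores_recovered_to_1e9(self, registry, default_panel):
        _, observations, intended = default_panel
        matrix = rh.build_score_matrix(observations, registry)
        assert (matrix - intended).abs().to_numpy().max() < 1e-9

    def test_perfect_scenario_yields_perfect_river(self, registry):
        scenario = SyntheticScenario(indicator_means=1.0, spread=0.0, seed=0)
        observations, _ = generate_panel(scenario, registry)
        matrix = rh.build_score_matrix(observations, registry)
        assert np.allclose(matrix.to_numpy(), 1.0)
        # downstream of scoring, entropy weights are undefined for a
        # constant matrix; the coordination chain itself gives a perfect
        # river for any weight split
        result = rh.assess_functions(1.0, 1.0, 0.67, 0.33)
        assert result.composite == result.development == 1.0


class TestScenarioStructure:
    def test_default_panel_shape(self, registry, default_panel):
        _, observations, intended = default_panel
        assert intended.shape == (12, 16)
        stations = {o.station for o in observations}
        assert stations == {"Pangduo", "Tanggya", "Lhasa"}
        years = {o.year for o in observations}
        assert years == {2011, 2012, 2013, 2014}

    def test_integer_station_count(self, registry):
        scenario = SyntheticScenario(stations=5, years=(2020,), seed=3)
        _, frame = generate_panel(scenario, registry)
        assert frame.shape == (5, 16)

    def test_station_gradient_declines_downstream(self, registry):
        scenario = SyntheticScenario(
            stations=("up", "mid", "down"),
            station_gradient=-0.15,
            spread=0.0,
            indicator_means=0.8,
            seed=0,
        )
        _, frame = generate_panel(scenario, registry)
        # C14 has a fully invertible benefit ladder over [0.5, 0.8]
        by_station = frame["C14"].groupby(level="station").mean()
        assert by_station["up"] > by_station["mid"] > by_station["down"]

    def test_dispersion_drives_weight_to_natural(self, registry):
        """High natural-score dispersion and near-constant social scores
        push the subsystem weight toward the natural functions."""
        spread = {f"C{i}": (0.25 if i <= 10 else 0.01) for i in range(1, 17)}
        means = {f"C{i}": 0.5 for i in range(1, 17)}
        scenario = SyntheticScenario(
            stations=6, years=tuple(range(2011, 2019)),
            indicator_means=means, spread=spread, seed=11,
        )
        observations, _ = generate_panel(scenario, registry)
        matrix = rh.build_score_matrix(observations, registry)
        weights = rh.entropy_weights(matrix, registry)
        assert weights.w_natural > weights.w_social

    def test_distributional_contract(self, registry):
        """Empirical mean of generated scores within 3 standard errors of
        the scenario mean at n = 1000 (one fully invertible indicator)."""
        scenario = SyntheticScenario(
            stations=10, years=tuple(range(1901, 2001)),
            indicator_means=0.6, spread=0.1, seed=123,
        )
        _, frame = generate_panel(scenario, registry)
        col = frame["C14"].to_numpy()  # invertible everywhere in [0, 1]
        n = col.size
        assert n == 1000
        # truncation at [0, 1] barely moves the mean for sd = 0.1 at 0.6
        se = col.std(ddof=1) / np.sqrt(n)
        assert abs(col.mean() - 0.6) < 3 * se + 0.005

    def test_unattainable_targets_snap_with_warning(self, registry):
        ladder = registry["C2"].ladders["EF1"]
        with pytest.warns(UserWarning, match="nearest attainable"):
            value = ladder.invert(0.1)  # inside the 0-0.2 step
        assert ladder.score(value) in (0.0, 0.2)


class TestFixtureBundle:
    def test_published_values(self, fixture_bundle):
        assert fixture_bundle.T_by_year[2011] == 0.639
        assert fixture_bundle.D_spatial["upstream"] == 0.821
        assert fixture_bundle.weights == (0.67, 0.33)
        assert fixture_bundle.years == (2011, 2012, 2013, 2014)
        assert fixture_bundle.main_stem_km == 551

    def test_implied_quantities(self, fixture_bundle):
        assert fixture_bundle.f_by_year(2011) == pytest.approx(0.625 * 1.034)
        assert fixture_bundle.g_spatial_implied("upstream") == pytest.approx(
            0.664 / 0.954
        )
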