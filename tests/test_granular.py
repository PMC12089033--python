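import numpy as np
import pytest
from scipy import special

import microzone as mz
from microzone._rng import substream
from microzone.granular import (
    FiringRule,
    GolgiParams,
    GranularError,
    InhibitionField,
    assemble_file_codes,
    calibrate_inhibition_scale,
    compute_field_inhibition,
    evaluate_granule_firing,
)
from microzone.mossy import FieldRates, RankInputSpec


def make_field(rates, rank=0, field=0):
    rates = np.asarray(rates, dtype=float)
    return FieldRates(rank, field, rates, np.arange(rates.size))


def exact_fire_probability(rates, inh_values, rule: FiringRule) -> float:
    """Closed-form oracle for the granule firing fraction.

    A dendrite pairs a uniformly chosen terminal rate with a uniformly
    chosen glomerular inhibition, so its win probability is the fraction of
    (rate, inhibition) pairs with rate > inhibition; the cell fires on at
    least ``min_wins`` of ``n_dendrites`` independent dendrites.
    """
    p = np.mean(rates[:, None] > inh_values[None, :])
    n = rule.n_dendrites
    return float(
        sum(
            special.comb(n, w) * p**w * (1 - p) ** (n - w)
            for w in range(rule.min_wins, n + 1)
        )
    )


class TestFieldInhibition:
    def test_constant_rates_give_scaled_constant(self, rng):
        field = make_field(np.full(100, 50.0))
        inh = compute_field_inhibition(field, GolgiParams(), scale=1.4, rng=rng,
                                       n_glomeruli=30)
        np.testing.assert_allclose(inh.values, 1.4 * 50.0)

    def test_zero_scale_zero_inhibition(self, rng):
        field = make_field(rng.uniform(0, 250, 500))
        inh = compute_field_inhibition(field, GolgiParams(), scale=0.0, rng=rng,
                                       n_glomeruli=50)
        assert np.all(inh.values == 0.0)

    def test_offset_adds_and_floors_at_zero(self, rng):
        field = make_field(np.full(100, 50.0))
        inh = compute_field_inhibition(field, GolgiParams(), scale=1.0, rng=rng,
                                       n_glomeruli=30, offset=-200.0)
        assert np.all(inh.values == 0.0)

    def test_mean_of_means_narrows_spread(self, rng):
        """Monte-Carlo check of the two-stage averaging chain.

        With uniform(0, 250) terminal rates the glomerular inhibition stays
        centred near 125 Hz but its spread shrinks, in line with the
        central-limit narrowing of a mean of means (oracle: direct
        simulation of the chain at the configured sample sizes).
        """
        rates = rng.uniform(0, 250, 5000)
        field = make_field(rates)
        golgi = GolgiParams(n_golgi=200)
        inh = compute_field_inhibition(field, golgi, scale=1.0, rng=rng,
                                       n_glomeruli=20_000)
        assert inh.values.mean() == pytest.approx(125.0, abs=10.0)
        assert inh.values.std() < rates.std()

        # independent oracle: a glomerular value is a mean of 4 Golgi values,
        # each a mean of 4 terminal rates
        oracle_rng = np.random.default_rng(7)
        glom = rates[oracle_rng.integers(0, rates.size, (100_000, 4, 4))].mean(axis=(1, 2))
        assert inh.values.std() == pytest.approx(glom.std(), rel=0.05)

    def test_empty_field_rejected(self, rng):
        with pytest.raises(GranularError, match="no terminals"):
            compute_field_inhibition(make_field([]), GolgiParams(), 1.0, rng)


class TestGranuleFiring:
    def test_overwhelming_inhibition_silences(self, rng):
        field = make_field(rng.uniform(0, 250, 700))
        inh = InhibitionField(0, 0, np.full(100, 1e6), 1.0, 0.0)
        act = evaluate_granule_firing(field, inh, FiringRule(), 1000, rng)
        assert act.fraction_active == 0.0

    def test_zero_inhibition_all_fire_at_dendritic_mean(self, rng):
        field = make_field(rng.uniform(10, 250, 700))
        inh = InhibitionField(0, 0, np.zeros(100), 1.0, 0.0)
        act = evaluate_granule_firing(field, inh, FiringRule(), 1000, rng)
        assert act.fraction_active == 1.0
        assert act.active_rates.min() >= field.rates.min()
        assert act.active_rates.max() <= field.rates.max()

    @pytest.mark.parametrize("bad_wins", [0, 5])
    def test_invalid_min_wins(self, rng, bad_wins):
        field = make_field(np.ones(10))
        inh = InhibitionField(0, 0, np.zeros(5), 1.0, 0.0)
        with pytest.raises(GranularError, match="min_wins"):
            evaluate_granule_firing(field, inh, FiringRule(min_wins=bad_wins), 10, rng)

    def test_fraction_matches_exact_oracle(self, rng):
        """Simulated firing fraction agrees with the closed-form probability
        on a miniature instance (20 terminal rates, 10 glomeruli)."""
        rule = FiringRule()
        rates = rng.uniform(0, 250, 20)
        field = make_field(rates)
        inh = InhibitionField(0, 0, rng.uniform(50, 200, 10), 1.0, 0.0)
        n = 50_000
        act = evaluate_granule_firing(field, inh, rule, n, rng)
        p = exact_fire_probability(rates, inh.values, rule)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(act.fraction_active - p) <= 3 * se

    def test_winners_rate_mode_uses_winning_dendrites(self, rng):
        rates = np.array([10.0, 200.0])
        field = make_field(rates)
        inh = InhibitionField(0, 0, np.full(4, 100.0), 1.0, 0.0)
        act = evaluate_granule_firing(
            field, inh, FiringRule(min_wins=1, rate_mode="winners"), 2000, rng
        )
        # winning dendrites always carry the 200 Hz signal
        assert np.all(act.active_rates == 200.0)


class TestCalibration:
    def test_reaches_sparse_target(self, mid_run):
        cal = mid_run.calibration
        assert cal.converged
        assert 0.0045 <= cal.achieved_fraction <= 0.0055

    def test_reaches_dense_target(self, mid_config):
        layer = mz.build_input_layer(
            mid_config.rank_specs(), mid_config.geometry, seed=5
        )
        cal = calibrate_inhibition_scale(layer, target=0.30, tol=0.05, seed=5)
        assert cal.converged
        assert cal.achieved_fraction == pytest.approx(0.30, rel=0.05)

    def test_monotone_in_constant(self, mid_config):
        """Under common random numbers the active fraction is non-increasing
        in the inhibition constant."""
        from microzone.granular import _field_fraction

        layer = mz.build_input_layer(
            mid_config.rank_specs(), mid_config.geometry, seed=6
        )
        field = layer.field(3, 3)
        fracs = [
            _field_fraction(field, 1.0, c, GolgiParams(), FiringRule(), 500,
                            mid_config.geometry.glomeruli_per_field, seed=6)
            for c in (-50.0, 0.0, 50.0, 100.0, 150.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_shift_equivariance_exact(self, mid_config):
        """A uniform shift of all mossy rates leaves the firing pattern
        identical under a common seed: win margins are unchanged because
        inhibition tracks the local mean additively."""
        from microzone.granular import run_granular_layer

        geom = mid_config.geometry
        layer = mz.build_input_layer(mid_config.rank_specs(), geom, seed=8)
        acts = run_granular_layer(layer, 1.0, 90.0, seed=8)
        acts_shifted = run_granular_layer(layer.shifted(15.0), 1.0, 90.0, seed=8)
        for row, row_s in zip(acts, acts_shifted):
            for a, b in zip(row, row_s):
                np.testing.assert_array_equal(a.active_ids, b.active_ids)
                np.testing.assert_allclose(b.active_rates, a.active_rates + 15.0)

    def test_unreachable_target_below_boundary_warns(self, mid_geom):
        specs = [RankInputSpec.normal(mean=0, sd=0)] * mid_geom.n_ranks
        layer = mz.build_input_layer(specs, mid_geom, seed=1)
        with pytest.warns(UserWarning, match="boundary"):
            cal = calibrate_inhibition_scale(
                layer, target=0.5, mode="scale", subsample_fraction=0.02
            )
        assert cal.scale == 0.0
        assert not cal.converged

    def test_bad_target_rejected(self, mid_run):
        with pytest.raises(GranularError, match="target"):
            calibrate_inhibition_scale(mid_run.layer, target=1.5)


class TestFileCodes:
    def test_counts_and_conservation(self, mid_run):
        geom = mid_run.geom
        files = mid_run.files
        assert len(files) == geom.n_sectors
        for j, fc in enumerate(files[:5]):
            n_active = sum(
                len(mid_run.activities[r][j].active_ids) for r in range(geom.n_ranks)
            )
            assert len(fc.pf_rates) == n_active
            assert fc.density == pytest.approx(
                n_active / (geom.n_ranks * geom.granule_per_field)
            )

    def test_file_density_tighter_than_field(self, mid_run):
        table = mz.density_regulation_table(mid_run.activities, mid_run.files)
        assert table.sd_file < table.sd_field

    def test_incomplete_grid_rejected(self, mid_run):
        with pytest.raises(GranularError, match="incomplete"):
            assemble_file_codes(mid_run.activities[:-1], mid_run.geom)

    def test_identical_fields_give_identical_densities(self, mid_geom):
        from microzone.granular import FieldActivity

        act = FieldActivity(0, 0, 100, np.arange(5), np.full(5, 80.0))
        grid = [
            [
                FieldActivity(r, f, 100, act.active_ids, act.active_rates)
                for f in range(mid_geom.fields_per_rank)
            ]
            for r in range(mid_geom.n_ranks)
        ]
        files = assemble_file_codes(grid, mid_geom)
        densities = {fc.density for fc in files}
        assert len(densities) == 1
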