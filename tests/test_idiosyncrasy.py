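import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alsim.idiosyncrasy import (
    HEMIBRAIN_VOLUME_SYNAPSE_MODEL,
    VolumeSynapseModel,
    bootstrap_population,
    fit_volume_synapse_model,
    make_idiosyncratic,
    pn_input_totals,
    resample_synapse_density,
)

from conftest import toy_roster


class TestBootstrap:
    def test_pool_sizes_preserved_per_glomerulus(self, fixture_parts):
        roster, counts, _ = fixture_parts
        boot, _ = bootstrap_population(roster, counts, "ORN", seed=0)
        for g in roster.glomeruli:
            assert len(boot.index_of("ORN", g)) == len(roster.index_of("ORN", g))
        assert boot.class_counts() == roster.class_counts()

    def test_single_member_pool_maps_to_itself(self):
        roster = toy_roster(
            [("o1", "ORN", "DA1", 1.0), ("p1", "uPN", "DA1", 1.0)]
        )
        counts = np.array([[0.0, 3.0], [0.0, 0.0]])
        boot, c = bootstrap_population(roster, counts, "ORN", seed=5)
        assert list(boot.ids) == ["o1", "p1"]
        assert np.array_equal(c, counts)

    def test_exclusion_probability_matches_theory(self):
        n = 12
        roster = toy_roster(
            [(f"o{i}", "ORN", "DA1", 1.0) for i in range(n)] + [("p", "uPN", "DA1", 1.0)]
        )
        counts = np.zeros((n + 1, n + 1))
        absent = []
        n_seeds = 1000
        for s in range(n_seeds):
            boot, _ = bootstrap_population(roster, counts, "ORN", seed=s)
            kept = {i.split("#")[0] for i in boot.ids}
            absent.append(n - sum(1 for i in range(n) if f"o{i}" in kept))
        p_absent = (1 - 1 / n) ** n  # -> e^-1 for large n
        se = np.sqrt(p_absent * (1 - p_absent) * n / n_seeds) / n
        assert abs(np.mean(absent) / n - p_absent) < 3 * se

    def test_no_new_pairs_connected(self, fixture_parts):
        roster, counts, _ = fixture_parts
        connected = {
            (roster.ids[i], roster.ids[j]) for i, j in zip(*np.nonzero(counts))
        }
        boot, c = bootstrap_population(roster, counts, "LN", seed=3)
        for i, j in zip(*np.nonzero(c)):
            pair = (boot.ids[i].split("#")[0], boot.ids[j].split("#")[0])
            assert pair in connected

    def test_empty_pool_raises(self):
        roster = toy_roster([("o", "ORN", "DA1", 1.0)])
        with pytest.raises(ValueError, match="pool"):
            bootstrap_population(roster, np.zeros((1, 1)), "LN", seed=0)


class TestVolumeSynapseFit:
    def test_noiseless_exact_recovery(self):
        v = np.geomspace(100, 10_000, 20)
        s = 5.5 * v**0.8
        m = fit_volume_synapse_model(v, s)
        assert m.a == pytest.approx(5.5, rel=1e-9)
        assert m.d == pytest.approx(0.8, rel=1e-9)
        assert m.sigma == pytest.approx(0.0, abs=1e-9)

    def test_mle_equals_log_log_least_squares(self):
        rng = np.random.default_rng(0)
        v = np.exp(rng.uniform(3, 10, 50))
        s = np.exp(rng.uniform(2, 8, 50))
        m = fit_volume_synapse_model(v, s)
        slope, intercept = np.polyfit(np.log(v), np.log(s), 1)
        assert m.d == pytest.approx(slope)
        assert np.log(m.a) == pytest.approx(intercept)

    def test_recovers_printed_parameters_from_synthetic_glomeruli(self):
        rng = np.random.default_rng(7)
        truth = HEMIBRAIN_VOLUME_SYNAPSE_MODEL
        v = np.exp(rng.uniform(np.log(1e3), np.log(1e5), 500))
        s = truth.sample_counts(v, rng)
        m = fit_volume_synapse_model(v, s)
        se_d = truth.sigma / (np.sqrt(500) * np.std(np.log(v)))
        assert abs(m.d - 0.73) < 3 * se_d
        assert abs(m.sigma - 0.38) < 3 * truth.sigma / np.sqrt(2 * 500)

    def test_nonpositive_input_raises(self):
        with pytest.raises(ValueError):
            fit_volume_synapse_model([1.0, 2.0, 0.0], [10.0, 20.0, 30.0])


class TestDensityResampling:
    def test_zero_sigma_hits_power_law_exactly(self, fixture_parts):
        roster, counts, volumes = fixture_parts
        m = VolumeSynapseModel(a=8.98, d=0.73, sigma=0.0)
        c = resample_synapse_density(roster, counts, volumes, m, seed=0)
        totals = pn_input_totals(roster, c)
        for g in roster.glomeruli:
            assert totals[g] == pytest.approx(8.98 * volumes[g] ** 0.73, rel=1e-9)

    def test_within_glomerulus_ratios_preserved(self, fixture_parts):
        roster, counts, volumes = fixture_parts
        c = resample_synapse_density(roster, counts, volumes, seed=1)
        for g in roster.glomeruli:
            cols = roster.index_of("uPN", g)
            before = counts[:, cols][counts[:, cols] > 0]
            after = c[:, cols][counts[:, cols] > 0]
            ratio = after / before
            assert np.allclose(ratio, ratio[0])

    def test_log_residuals_are_normal(self, fixture_parts):
        roster, counts, volumes = fixture_parts
        m = HEMIBRAIN_VOLUME_SYNAPSE_MODEL
        g = roster.glomeruli[0]
        rng = np.random.default_rng(0)
        resid = []
        for _ in range(1000):
            c = resample_synapse_density(roster, counts, volumes, m, seed=rng)
            total = pn_input_totals(roster, c)[g]
            resid.append(np.log(total) - np.log(m.a * volumes[g] ** m.d))
        z = np.asarray(resid) / m.sigma
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_refit_closure(self, fixture_parts):
        # resampling from a fitted model then refitting recovers it
        roster, counts, volumes = fixture_parts
        totals = pn_input_totals(roster, counts)
        m0 = fit_volume_synapse_model(volumes.loc[totals.index], totals)
        rng = np.random.default_rng(2)
        d_hats, s_hats = [], []
        for _ in range(200):
            c = resample_synapse_density(roster, counts, volumes, m0, seed=rng)
            t = pn_input_totals(roster, c)
            m1 = fit_volume_synapse_model(volumes.loc[t.index], t)
            d_hats.append(m1.d)
            s_hats.append(m1.sigma)
        assert abs(np.mean(d_hats) - m0.d) < 0.2
        assert abs(np.mean(s_hats) - m0.sigma) < 0.15

    def test_identity_mode_returns_source(self, fixture_parts):
        roster, counts, _ = fixture_parts
        r, c = make_idiosyncratic(roster, counts, "poisson", seed=0)
        assert r is roster and np.array_equal(c, counts)
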