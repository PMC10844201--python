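"""Landing-level estimation, bucket method, comparison, precision experiment."""

import numpy as np
import pytest

from ednabycatch.io import load_bundled_method_estimates
from ednabycatch.landings import (
    LandingDataset,
    bucket_estimate,
    compare_methods,
    estimate_landing,
    estimate_per_tank,
    precision_experiment,
    recombine_per_tank,
)
from ednabycatch.synthetic import simulate_landing
from tests.conftest import make_model


def _dataset(factory=None, ship=None, total=None, tank_weights=None):
    return LandingDataset(
        landing_id="L1",
        total_landed_weight=total,
        ship_samples=ship or {},
        factory_samples=factory or {},
        tank_weights=tank_weights,
    )


class TestEstimateLanding:
    def test_constant_replicates_match_hand_arithmetic(self, identity_model):
        # 8 samples all at fraction 0.275, total 1361 t -> 374.275 t, SE 0
        ds = _dataset(factory={f"i{k}": (0.275,) * 3 for k in range(8)}, total=1361.0)
        est = estimate_landing(ds, identity_model, "factory")
        assert est.fraction == pytest.approx(0.275)
        assert est.bycatch_tonnes == pytest.approx(0.275 * 1361.0)
        assert est.se_tonnes == pytest.approx(0.0, abs=1e-9)
        assert est.n == 8

    def test_two_sample_se(self, identity_model):
        ds = _dataset(factory={"a": (0.2,) * 3, "b": (0.4,) * 3}, total=1000.0)
        est = estimate_landing(ds, identity_model, "factory")
        assert est.bycatch_tonnes == pytest.approx(300.0)
        # sample means {0.2, 0.4}: sd (ddof=1) = 0.1*sqrt(2); SE = sd/sqrt(2) = 0.1
        assert est.se_tonnes == pytest.approx(100.0)

    def test_replicates_averaged_before_sample_se(self, identity_model):
        # replicate scatter inside a sample must not inflate the SE
        ds = _dataset(factory={"a": (0.1, 0.3, 0.2), "b": (0.2, 0.2, 0.2)}, total=100.0)
        est = estimate_landing(ds, identity_model, "factory")
        assert est.fraction == pytest.approx(0.2)
        assert est.se_tonnes == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance_and_weight_scaling(self, identity_model):
        samples = {"a": (0.1, 0.2, 0.3), "b": (0.4, 0.3, 0.2), "c": (0.15, 0.25, 0.35)}
        ds1 = _dataset(factory=samples, total=500.0)
        ds2 = _dataset(factory=dict(reversed(list(samples.items()))), total=500.0)
        e1 = estimate_landing(ds1, identity_model, "factory")
        e2 = estimate_landing(ds2, identity_model, "factory")
        assert e1.fraction == pytest.approx(e2.fraction)
        ds3 = _dataset(factory=samples, total=1000.0)
        e3 = estimate_landing(ds3, identity_model, "factory")
        assert e3.bycatch_tonnes == pytest.approx(2 * e1.bycatch_tonnes)
        assert e3.se_tonnes == pytest.approx(2 * e1.se_tonnes)

    def test_missing_total_weight_gives_fraction_only(self, identity_model):
        ds = _dataset(factory={"a": (0.2,) * 3, "b": (0.3,) * 3})
        est = estimate_landing(ds, identity_model, "factory")
        assert est.bycatch_tonnes is None
        assert est.fraction == pytest.approx(0.25)

    def test_empty_stream_rejected(self, identity_model):
        with pytest.raises(ValueError, match="no factory samples"):
            estimate_landing(_dataset(ship={"t1": (0.2,) * 3}), identity_model, "factory")

    def test_nonidentity_model_inverts_replicates(self):
        model = make_model(alpha=0.5, beta_slope=1.0, water_type="factory")
        from ednabycatch.calibration import invert

        ds = _dataset(factory={"a": (0.3,) * 3}, total=100.0)
        est = estimate_landing(ds, model, "factory")
        assert est.fraction == pytest.approx(invert(model, 0.3)[0])


class TestPerTank:
    def test_constant_tank(self, identity_model):
        model = make_model(alpha=0.0, beta_slope=1.0, water_type="ship")
        ds = _dataset(ship={"t1": (0.6, 0.6, 0.6)})
        out = estimate_per_tank(ds, model)
        assert out["t1"][0] == pytest.approx(0.6)
        assert out["t1"][1] == pytest.approx(0.0, abs=1e-12)

    def test_weighted_recombination_equals_landing_estimate_for_equal_weights(self):
        model = make_model(alpha=-0.2, beta_slope=1.1, water_type="ship")
        ship = {f"t{k}": tuple(0.1 + 0.08 * k + d for d in (0.0, 0.01, -0.01)) for k in range(6)}
        ds = _dataset(ship=ship, total=1200.0)
        per_tank = estimate_per_tank(ds, model)
        recombined = recombine_per_tank(per_tank, {t: 200.0 for t in ship})
        landing = estimate_landing(ds, model, "ship")
        assert recombined == pytest.approx(landing.fraction, abs=1e-12)

    def test_per_tank_recovery_on_simulated_landings(self):
        """Per-tank MAE < 0.02 with replicate noise at precision phi=200.

        Expected MAE is sqrt(mu(1-mu)/(1+phi)/3)*sqrt(2/pi) ~ 0.016 at these
        mixtures; averaging over 60 tanks concentrates it below 0.02.
        """
        rng = np.random.default_rng(17)
        model = make_model(alpha=0.0, beta_slope=1.0, phi=200.0, water_type="ship")
        errors = []
        for _ in range(10):
            truths = {f"t{k}": rng.uniform(0.1, 0.6) for k in range(6)}
            ship = {
                t: tuple(rng.beta(f * 200.0, (1 - f) * 200.0, 3)) for t, f in truths.items()
            }
            out = estimate_per_tank(_dataset(ship=ship), model)
            errors.extend(abs(out[t][0] - truths[t]) for t in truths)
        assert np.mean(errors) < 0.02

    def test_unknown_tank_weight_rejected(self):
        with pytest.raises(ValueError, match="unknown tank"):
            recombine_per_tank({"t1": (0.2, 0.0)}, {"t2": 100.0})


class TestBucketEstimate:
    def test_constant_subsamples(self):
        # 15 subsamples at 0.348, total 1357 t -> 472.236 t, SE 0
        est = bucket_estimate([0.348] * 15, 1357.0)
        assert est.bycatch_tonnes == pytest.approx(0.348 * 1357.0)
        assert est.se_tonnes == pytest.approx(0.0, abs=1e-9)
        assert est.n == 15

    def test_symmetric_extremes(self):
        est = bucket_estimate([0.0, 1.0], 100.0)
        assert est.bycatch_tonnes == pytest.approx(50.0)
        # sd(0,1 ddof=1)=0.7071; se=0.5 -> 50 t
        assert est.se_tonnes == pytest.approx(50.0)

    def test_single_subsample_has_undefined_se(self):
        est = bucket_estimate([0.3], 100.0)
        assert est.se_tonnes is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bucket_estimate([], 100.0)


class TestCompareMethods:
    def test_bundled_table_contrasts(self):
        """The four-landing comparison table reproduces the reported
        ship/factory and visual-method contrasts in whole tonnes."""
        table = compare_methods(load_bundled_method_estimates())

        def diff(landing, a, b):
            rows = table[table.landing_id == landing]
            hit = rows[
                ((rows.method_a == a) & (rows.method_b == b))
                | ((rows.method_a == b) & (rows.method_b == a))
            ]
            assert len(hit) == 1
            return int(hit.diff_tonnes.iloc[0])

        assert diff("1", "ship_pw", "factory_pw") == 30
        assert diff("1", "logbook", "third_party") == 150
        assert diff("1", "fisheries_control", "third_party") == 52
        assert diff("2", "logbook", "third_party") == 68
        assert diff("3", "ship_pw", "factory_pw") == 292
        assert diff("4", "ship_pw", "factory_pw") == 547

    def test_difference_symmetric_in_method_order(self):
        a = bucket_estimate([0.3, 0.32], 1000.0, landing_id="x", method="logbook")
        b = bucket_estimate([0.2, 0.22], 1000.0, landing_id="x", method="third_party")
        t_ab = compare_methods([a, b])
        t_ba = compare_methods([b, a])
        assert t_ab.diff_tonnes.iloc[0] == t_ba.diff_tonnes.iloc[0]
        same = bucket_estimate([0.3, 0.32], 1000.0, landing_id="x", method="ship_pw")
        t_self = compare_methods([a, same])
        assert t_self.diff_tonnes.iloc[0] == 0

    def test_lowest_se_method_flagged(self):
        table = compare_methods(load_bundled_method_estimates())
        flags = table.groupby("landing_id").lowest_se_method.unique()
        assert list(flags["1"]) == ["factory_pw"]
        assert list(flags["4"]) == ["factory_pw"]

    def test_single_estimate_rejected(self):
        est = bucket_estimate([0.3, 0.4], 100.0, landing_id="solo")
        with pytest.raises(ValueError, match="at least 2"):
            compare_methods([est])


class TestPrecisionExperiment:
    def test_fully_mixed_noise_free_is_unbiased(self):
        landing = simulate_landing(6, [200.0] * 6, 0.2, seed=1, mixing_flag="fully_mixed")
        out = precision_experiment(
            landing,
            edna_config={"n_samples": 6, "n_replicates": 1, "phi": None},
            bucket_config={"n_buckets": 6},
            n_trials=50,
            seed=3,
        )
        assert out["edna_bias"] == pytest.approx(0.0, abs=1e-12)
        assert out["bucket_bias"] == pytest.approx(0.0, abs=1e-12)

    def test_edna_beats_buckets_on_heterogeneous_tanks(self):
        """Well-mixed water integrates tank heterogeneity (sd 0.15) that 15
        buckets cannot: the eDNA SE is lower in >= 90% of trials."""

        def landing_factory(rng):
            law = lambda r, n: np.clip(r.normal(0.25, 0.15, n), 0.01, 0.99)
            return simulate_landing(6, [200.0] * 6, law, seed=int(rng.integers(2**31)))

        out = precision_experiment(
            landing_factory,
            edna_config={"n_samples": 8, "n_replicates": 3, "phi": 200.0},
            bucket_config={"n_buckets": 15},
            n_trials=100,
            seed=29,
        )
        assert out["edna_se_lower_share"] >= 0.90
        assert out["edna_empirical_sd"] < out["bucket_empirical_sd"]

    def test_truncated_ship_sampling_biases_estimate(self):
        """Sampling before the last haul (skipping a bycatch-rich tank)
        biases the per-tank eDNA estimate."""
        tanks = [0.1, 0.1, 0.1, 0.1, 0.1, 0.7]  # last haul is bycatch-rich
        landing = simulate_landing(6, [200.0] * 6, lambda r, n: np.array(tanks), seed=5)
        truncated = precision_experiment(
            landing,
            edna_config={
                "n_samples": 5,
                "n_replicates": 3,
                "phi": None,
                "mode": "per_tank",
                "tanks": [f"tank{i}" for i in range(1, 6)],
            },
            bucket_config={"n_buckets": 15},
            n_trials=20,
            seed=7,
        )
        assert truncated["edna_bias"] == pytest.approx(0.1 - landing.true_fraction, abs=1e-9)
        assert truncated["edna_bias"] < -0.05
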