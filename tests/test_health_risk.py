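"""Exposure sampling, dose equations and the Monte Carlo risk engine."""

import numpy as np
import pandas as pd
import pytest

from soilrisk import (
    DistributionSpec,
    ExposureModel,
    ToxicityReference,
    compute_add,
    compute_cr_tcr,
    compute_hq_hi,
    panel_from_arrays,
    run_monte_carlo,
    sample_parameter,
)
from soilrisk.core_data import ValidationError
from soilrisk.health_risk import PATHWAYS, sample_exposure


class TestSampleParameter:
    def test_point_returns_constant(self):
        draws = sample_parameter(DistributionSpec("point", (350.0,)), 3, seed=0)
        assert (draws == 350.0).all()

    def test_uniform_mean(self):
        draws = sample_parameter(DistributionSpec("uniform", (0, 50)), 100_000, 1)
        assert draws.mean() == pytest.approx(25.0, rel=0.02)
        assert (draws > 0).all()  # open at the lower bound

    def test_triangular_mean(self):
        draws = sample_parameter(
            DistributionSpec("triangular", (14, 30, 52)), 100_000, 2
        )
        assert draws.mean() == pytest.approx((14 + 30 + 52) / 3, rel=0.02)

    def test_lognormal_geometric_mean(self):
        draws = sample_parameter(
            DistributionSpec("lognormal", (16.68, 1.48)), 100_000, 3
        )
        assert np.exp(np.log(draws).mean()) == pytest.approx(16.68, rel=0.01)
        assert np.exp(np.log(draws).std()) == pytest.approx(1.48, rel=0.01)

    def test_truncnormal_nonnegative(self):
        draws = sample_parameter(
            DistributionSpec("truncnormal", (0.49, 0.54)), 50_000, 4
        )
        assert (draws >= 0).all()

    def test_reproducible_under_seed(self):
        spec = DistributionSpec("lognormal", (57.03, 1.18))
        a = sample_parameter(spec, 1000, 7)
        b = sample_parameter(spec, 1000, 7)
        assert (a == b).all()


class TestComputeAdd:
    DRAWS = {
        "R_ingest": np.array([100.0]),
        "EF": np.array([350.0]),
        "ED": np.array([10.0]),
        "R_inhal": np.array([10.0]),
        "PEF": np.array([1.0e9]),
        "BW": np.array([20.0]),
        "AT": np.array([3650.0]),
        "SA": np.array([1000.0]),
        "AF": np.array([0.2]),
        "ABF": np.array([0.001]),
    }

    def test_hand_calculated_ingestion_dose(self):
        # EF·ED = 3500 exposure days over AT = 3650 days
        add = compute_add(100.0, self.DRAWS)
        expected = 100.0 * 100.0 * 350.0 * 10.0 / (20.0 * 3650.0) * 1e-6
        assert add["ingestion"][0] == pytest.approx(expected, rel=1e-12)
        assert add["ingestion"][0] == pytest.approx(4.795e-4, rel=1e-3)

    def test_hand_calculated_dermal_and_inhalation(self):
        add = compute_add(100.0, self.DRAWS)
        dermal = 100.0 * 1000.0 * 0.2 * 0.001 * 3500.0 / (20.0 * 3650.0) * 1e-6
        inhal = 100.0 * 10.0 * 3500.0 / (1.0e9 * 20.0 * 3650.0)
        assert add["dermal"][0] == pytest.approx(dermal, rel=1e-12)
        assert add["inhalation"][0] == pytest.approx(inhal, rel=1e-12)

    def test_zero_concentration_zeroes_all_pathways(self):
        add = compute_add(0.0, self.DRAWS)
        assert all(add[p][0] == 0.0 for p in PATHWAYS)

    def test_homogeneity_in_concentration(self):
        a1 = compute_add(50.0, self.DRAWS)
        a2 = compute_add(100.0, self.DRAWS)
        for p in PATHWAYS:
            assert a2[p][0] == pytest.approx(2 * a1[p][0], rel=1e-12)

    def test_nonpositive_body_weight_rejected(self):
        bad = dict(self.DRAWS, BW=np.array([0.0]))
        with pytest.raises(ValidationError):
            compute_add(1.0, bad)


class TestHazardAndCancerIndices:
    def test_ratio_identity(self):
        tox = ToxicityReference.default()
        add = {"As": {"ingestion": np.array([3e-4]),
                      "dermal": np.array([0.0]),
                      "inhalation": np.array([0.0])}}
        hq, hi = compute_hq_hi(add, tox)
        assert hq["As"][0] == pytest.approx(1.0)
        assert hi[0] == pytest.approx(1.0)

    def test_additivity_over_elements(self):
        tox = ToxicityReference.default()
        add = {
            "As": {"ingestion": np.array([0.3 * 3e-4])},
            "Cd": {"ingestion": np.array([0.7 * 1e-3])},
        }
        _, hi = compute_hq_hi(add, tox)
        assert hi[0] == pytest.approx(1.0)

    def test_cr_product_and_missing_sf_skipped(self):
        tox = ToxicityReference.default()
        add = {
            "As": {"ingestion": np.array([1e-5])},
            "Cu": {p: np.array([1e-3]) for p in PATHWAYS},     # no SF at all
            "Cd": {"dermal": np.array([1.0]),                  # dermal SF absent
                   "ingestion": np.array([1e-6])},
        }
        cr, tcr = compute_cr_tcr(add, tox)
        assert cr["As"][0] == pytest.approx(1.5e-5)
        assert "Cu" not in cr
        assert cr["Cd"][0] == pytest.approx(6.1 * 1e-6)  # dermal excluded
        assert tcr[0] == pytest.approx(1.5e-5 + 6.1e-6)


def _point_model(receptor="child"):
    vals = {
        "R_ingest": 100.0, "EF": 350.0, "ED": 10.0, "R_inhal": 10.0,
        "PEF": 1.0e9, "BW": 20.0, "AT": 3650.0, "SA": 1000.0, "AF": 0.2,
        "ABF": 0.001,
    }
    return ExposureModel(
        receptor=receptor,
        parameters={k: DistributionSpec("point", (v,)) for k, v in vals.items()},
    )


class TestMonteCarlo:
    def test_degenerate_run_equals_closed_form(self):
        """With every parameter a point mass and one sample, the Monte Carlo
        collapses to the deterministic dose equations (hand oracle)."""
        C = 80.0
        panel = panel_from_arrays(np.array([[C]]), elements=("As",))
        res = run_monte_carlo(
            panel, _point_model(), iterations=1000, seed=0
        )
        days, denom = 350.0 * 10.0, 20.0 * 3650.0
        ing = C * 100.0 * days / denom * 1e-6
        derm = C * 1000.0 * 0.2 * 0.001 * days / denom * 1e-6
        inh = C * 10.0 * days / (1.0e9 * denom)
        hq = ing / 3.00e-4 + derm / 1.23e-4 + inh / 1.23e-4
        cr = ing * 1.5 + derm * 3.66 + inh * 1.51
        for stat in ("mean", "p5", "median", "p95"):
            assert res.hq.loc["As", stat] == pytest.approx(hq, rel=1e-12)
            assert res.cr.loc["As", stat] == pytest.approx(cr, rel=1e-12)
            assert res.hi[stat] == pytest.approx(hq, rel=1e-12)
            assert res.tcr[stat] == pytest.approx(cr, rel=1e-12)

    def test_same_seed_bitwise_identical(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        model = ExposureModel.default("adult")
        a = run_monte_carlo(panel, model, iterations=2000, seed=11)
        b = run_monte_carlo(panel, model, iterations=2000, seed=11)
        pd.testing.assert_frame_equal(a.cr, b.cr, check_exact=True)
        pd.testing.assert_frame_equal(a.hq, b.hq, check_exact=True)
        pd.testing.assert_series_equal(a.tcr, b.tcr, check_exact=True)

    def test_children_exceed_adults_for_arsenic_cr(self):
        panel = panel_from_arrays(np.full((1, 8), 20.0))
        child = run_monte_carlo(
            panel, ExposureModel.default("child"), iterations=10_000, seed=5
        )
        adult = run_monte_carlo(
            panel, ExposureModel.default("adult"), iterations=10_000, seed=5
        )
        assert child.cr.loc["As", "mean"] > adult.cr.loc["As", "mean"]
        assert (
            child.add.loc[("As", "ingestion"), "mean"]
            > adult.add.loc[("As", "ingestion"), "mean"]
        )

    def test_mean_tcr_linear_in_concentration_scale(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        scaled = panel_from_arrays(
            panel.values() * 10.0, elements=panel.elements
        )
        model = ExposureModel.default("adult")
        base = run_monte_carlo(panel, model, iterations=10_000, seed=3)
        x10 = run_monte_carlo(scaled, model, iterations=10_000, seed=3)
        assert x10.tcr["mean"] == pytest.approx(10 * base.tcr["mean"], rel=1e-9)

    def test_increasing_concentration_never_decreases_risk(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        bumped = panel_from_arrays(
            panel.values() * 1.5, elements=panel.elements
        )
        model = ExposureModel.default("child")
        a = run_monte_carlo(panel, model, iterations=5000, seed=9)
        b = run_monte_carlo(bumped, model, iterations=5000, seed=9)
        assert b.hi["mean"] >= a.hi["mean"]
        assert b.tcr["mean"] >= a.tcr["mean"]

    def test_percentile_stability_across_seeds(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        model = ExposureModel.default("child")
        runs = [
            run_monte_carlo(panel, model, iterations=10_000, seed=s)
            for s in (21, 22, 23)
        ]
        means = np.array([r.tcr["mean"] for r in runs])
        p95s = np.array([r.tcr["p95"] for r in runs])
        assert means.max() / means.min() - 1 < 0.10
        assert p95s.max() / p95s.min() - 1 < 0.20

    def test_quantile_ordering(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        res = run_monte_carlo(
            panel, ExposureModel.default("adult"), iterations=5000, seed=1
        )
        for df in (res.hq, res.cr):
            assert (df["p5"] <= df["median"]).all()
            assert (df["median"] <= df["p95"]).all()

    def test_zero_iterations_rejected(self, synthetic_survey):
        panel, _, _ = synthetic_survey
        with pytest.raises(ValidationError):
            run_monte_carlo(panel, ExposureModel.default("child"), iterations=0)


class TestExposurePopulation:
    def test_joint_draw_moments(self):
        from soilrisk import generate_exposure_population

        pop = generate_exposure_population(
            ExposureModel.default("child"), 100_000, seed=6
        )
        assert np.exp(np.log(pop["BW"]).mean()) == pytest.approx(16.68, rel=0.01)
        assert (pop["EF"] == 350.0).all()
        assert pop["ED"].mean() == pytest.approx(5.0, rel=0.02)
        adult = generate_exposure_population(
            ExposureModel.default("adult"), 100_000, seed=6
        )
        assert adult["ED"].mean() == pytest.approx(25.0, rel=0.02)
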