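"""Case suite construction, orchestration and configuration round trips."""

import numpy as np
import pytest

from stenoflow.cases import (
    REFERENCE_ETAS,
    CaseSpec,
    build_reference_cases,
    grid_convergence_study,
    run_suite,
)
from stenoflow.config import case_from_config
from stenoflow.errors import ConfigurationError
from stenoflow.rheology import RheologyModel
from stenoflow.solver import NumericsConfig


class TestBuildReferenceCases:
    def test_ten_cases_five_degrees_two_rheologies(self):
        specs = build_reference_cases()
        assert len(specs) == 10
        assert sorted({s.eta for s in specs}) == sorted(REFERENCE_ETAS)
        assert {s.rheology.kind for s in specs} == {"newtonian", "carreau"}

    def test_reynolds_number_is_300(self):
        for s in build_reference_cases():
            assert s.reynolds() == pytest.approx(300.0, rel=0.01)

    def test_shared_reference_conditions(self):
        for s in build_reference_cases():
            assert s.R == 5e-3
            assert s.Ls_over_R == 4.0
            assert s.Q == pytest.approx(0.465e-3 / 60.0)
            assert s.rho == 1050.0
            assert s.mean_velocity() == pytest.approx(0.0986, abs=2e-4)

    def test_severe_case_throat_radius(self):
        spec = next(s for s in build_reference_cases() if s.eta == 0.75)
        assert spec.geometry().Rt == pytest.approx(2.5e-3)

    def test_labels_are_unique_and_descriptive(self):
        labels = [s.label for s in build_reference_cases()]
        assert len(set(labels)) == 10
        assert "eta0.75_carreau" in labels


class TestRunSuite:
    def test_empty_suite(self):
        result = run_suite([])
        assert len(result) == 0
        assert result.to_frame().empty

    def test_failures_recorded_not_dropped(self, tmp_path):
        ok = CaseSpec(eta=0.0, rheology=RheologyModel.newtonian(),
                      n_axial=48, n_radial=10,
                      numerics=NumericsConfig(max_iter=500))
        bad = CaseSpec(eta=0.0, rheology=RheologyModel.newtonian(),
                       n_axial=48, n_radial=10, label="starved",
                       numerics=NumericsConfig(max_iter=2))
        result = run_suite([ok, bad], out_dir=tmp_path)
        assert len(result) == 2
        assert result.results[0].ok
        assert not result.results[1].ok
        assert "ConvergenceError" in result.results[1].error
        assert (tmp_path / "suite_summary.csv").exists()
        assert (tmp_path / ok.label / "wss_profile.csv").exists()

    def test_rerun_reproduces_bit_identical_summary(self):
        spec = CaseSpec(eta=0.0, rheology=RheologyModel.newtonian(),
                        n_axial=48, n_radial=10,
                        numerics=NumericsConfig(max_iter=500))
        r1 = run_suite([spec]).results[0].summary
        r2 = run_suite([spec]).results[0].summary
        assert r1.delta_p == r2.delta_p
        assert r1.wss_peak == r2.wss_peak
        assert np.array_equal(r1.wss_profile, r2.wss_profile)


class TestGridConvergenceStudy:
    def test_identical_levels_zero_change(self):
        spec = CaseSpec(eta=0.0, rheology=RheologyModel.newtonian(),
                        n_axial=48, n_radial=10,
                        numerics=NumericsConfig(max_iter=500))
        df = grid_convergence_study(spec, refinements=(1, 1), warm_start=False)
        assert df.shape[0] == 2
        assert df["rel_change_delta_p_Pa"].iloc[-1] == 0.0
        assert df["rel_change_wss_peak_Pa"].iloc[-1] == 0.0

    def test_needs_two_levels(self):
        spec = CaseSpec(eta=0.0, rheology=RheologyModel.newtonian())
        with pytest.raises(ConfigurationError):
            grid_convergence_study(spec, refinements=(1,))


class TestConfig:
    def test_full_config_round_trip(self):
        cfg = {
            "geometry": {"R_mm": 5.0, "eta": 0.625, "Ls_over_R": 4.0,
                         "x_inlet_over_R": -6.0, "x_outlet_over_R": 30.0},
            "grid": {"n_axial": 120, "n_radial": 24, "radial_beta": 2.0},
            "flow": {"Q_L_per_min": 0.465, "rho": 1050.0},
            "rheology": {"model": "carreau"},
            "numerics": {"relax_u": 0.7, "relax_p": 0.3, "max_iter": 1234},
        }
        spec = case_from_config(cfg)
        assert spec.eta == 0.625
        assert spec.n_axial == 120 and spec.n_radial == 24
        assert spec.clustering.radial_beta == 2.0
        assert spec.numerics.max_iter == 1234
        assert spec.rheology.kind == "carreau"
        assert spec.Q == pytest.approx(0.465e-3 / 60.0)

    def test_throat_radius_alternative(self):
        spec = case_from_config({"geometry": {"R_mm": 5.0, "Rt_mm": 2.5},
                                 "rheology": {"model": "newtonian"}})
        assert spec.eta == pytest.approx(0.75)

    def test_eta_and_rt_mutually_exclusive(self):
        with pytest.raises(ConfigurationError):
            case_from_config({"geometry": {"R_mm": 5.0, "eta": 0.5, "Rt_mm": 2.5}})

    def test_rheology_overrides(self):
        spec = case_from_config({"rheology": {"model": "carreau", "lambda_t": 1.0}})
        assert spec.rheology.lambda_t == 1.0
        assert spec.rheology.mu_0 == 0.056

    def test_yaml_file_loading(self, tmp_path):
        from stenoflow.config import load_case

        path = tmp_path / "case.yaml"
        path.write_text(
            "geometry: {R_mm: 5.0, eta: 0.25}\n"
            "rheology: {model: newtonian}\n"
            "grid: {n_axial: 64, n_radial: 16}\n"
        )
        spec = load_case(path, label="mycase")
        assert spec.eta == 0.25
        assert spec.label == "mycase"
        assert spec.n_axial == 64
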