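import numpy as np
import pytest
import yaml

from rbpm_cea.errors import ConfigError, ValidationError
from rbpm_cea.parameters import (
    DistributionSpec,
    ParameterSet,
    ParameterSpec,
    load_parameters,
    make_distribution,
    per_patient_nurse_cost,
    sample,
)


class TestLoadParameters:
    def test_defaults_match_published_base_case(self, params):
        assert params.p_sev == 0.008
        assert params.c_readm == 17549.0
        assert params.ack_sev_rbpm == 0.86
        assert params.p_readm_uc == 0.05
        assert params.wtp == 100000.0

    def test_config_override_keeps_other_defaults(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"c_cuff": {"base": 150}}))
        p = load_parameters(cfg)
        assert p.c_cuff == 150.0  # Bluetooth-cuff scenario
        assert p.c_program == 139.0

    def test_scenario_block(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump(
            {"scenarios": {"bluetooth_cuff": {"c_cuff": {"base": 150}}}}
        ))
        assert load_parameters(cfg).c_cuff == 50.0
        assert load_parameters(cfg, scenario="bluetooth_cuff").c_cuff == 150.0
        with pytest.raises(ConfigError, match="unknown scenario"):
            load_parameters(cfg, scenario="nope")

    def test_probability_bound_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"p_sev": {"base": 1.2, "high": 1.2}}))
        with pytest.raises(ValidationError, match="p_sev"):
            load_parameters(cfg)

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"p_made_up": 0.5}))
        with pytest.raises(ConfigError, match="p_made_up"):
            load_parameters(cfg)

    def test_malformed_yaml_names_line(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("p_sev: {base: 0.008\nc_cuff: 50\n")
        with pytest.raises(ConfigError, match="line"):
            load_parameters(cfg)

    def test_round_trip(self, params, tmp_path):
        cfg = tmp_path / "dump.yaml"
        cfg.write_text(yaml.safe_dump(params.to_config_dict()))
        assert load_parameters(cfg) == params

    def test_bp_probabilities_renormalized_simplex(self, params):
        bp = params.bp_probabilities()
        assert bp.sum() == pytest.approx(1.0, abs=1e-12)
        # the published values overshoot 1 by 8.9e-5; p_norm absorbs it
        assert bp[0] == pytest.approx(0.962 - 8.9e-5, abs=1e-9)
        assert bp[2] == 0.008


class TestNurseCost:
    @pytest.mark.parametrize(
        "annual,volume,expected",
        [(127374, 900, 141.53), (127374, 1, 127374.00), (101400, 900, 112.67),
         (156000, 900, 173.33)],
    )
    def test_published_per_patient_figures(self, annual, volume, expected):
        assert per_patient_nurse_cost(annual, volume) == expected

    def test_zero_volume_rejected(self):
        with pytest.raises(ValidationError):
            per_patient_nurse_cost(127374, 0)


class TestDistributions:
    def test_moment_fit_pins_mean_for_all_parameters(self, params):
        for spec in params:
            dist = make_distribution(spec)
            assert dist.mean() == pytest.approx(spec.base, abs=1e-6), spec.name

    def test_cost_spec_gamma_moments(self, params):
        dist = make_distribution(params.spec("c_readm"))
        assert dist.family == "gamma"
        assert dist.mean() == pytest.approx(17549.0, abs=1e-6)
        # sd = (17734 - 17364) / 3.92
        assert dist.sd() == pytest.approx(370.0 / 3.92, abs=1e-9)

    def test_probability_spec_is_beta_with_support(self, params):
        dist = make_distribution(params.spec("ack_sev_rbpm"))
        assert dist.family == "beta"
        draws = dist.sample(np.random.default_rng(0), size=100_000)
        assert np.all((draws >= 0) & (draws <= 1))
        se = dist.sd() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.86) < 4 * se

    def test_empirical_mean_recovery(self, params):
        rng = np.random.default_rng(3)
        for spec in params:
            if not spec.varied_in_psa:
                continue
            dist = make_distribution(spec)
            draws = np.atleast_1d(dist.sample(rng, size=100_000))
            lo, hi = dist.support
            assert np.all((draws >= lo) & (draws <= hi)), spec.name
            se = dist.sd() / np.sqrt(draws.size)
            assert abs(draws.mean() - spec.base) <= max(4 * se, 1e-12), spec.name

    def test_degenerate_when_range_collapses(self):
        spec = ParameterSpec("x", 0.5, 0.5, 0.5, "probability", "")
        dist = make_distribution(spec)
        assert dist.family == "degenerate"
        assert sample(dist, np.random.default_rng(0)) == 0.5

    def test_infeasible_beta_variance_clamped(self, caplog):
        # variance from the range exceeds mean(1-mean): fit must clamp, not fail
        spec = ParameterSpec("x", 0.001, 0.0, 0.9, "probability", "")
        with caplog.at_level("WARNING"):
            dist = make_distribution(spec)
        assert dist.family == "beta"
        assert dist.mean() == pytest.approx(0.001, abs=1e-9)
        assert dist.sd() ** 2 <= 0.991 * 0.001 * 0.999

    def test_sampling_is_reproducible(self, params):
        dist = make_distribution(params.spec("p_sev"))
        a = sample(dist, np.random.default_rng(11))
        b = sample(dist, np.random.default_rng(11))
        assert a == b

    def test_minmax_convention_is_wider_than_ci95(self, params):
        spec = params.spec("c_outpatient")
        assert make_distribution(spec, "minmax").sd() > make_distribution(spec, "ci95").sd()


class TestParameterSet:
    def test_with_value_widens_bounds(self, params):
        p = params.with_value("c_cuff", 150.0)
        assert p.c_cuff == 150.0
        assert p.spec("c_cuff").high == 150.0
        assert params.c_cuff == 50.0  # original untouched

    def test_unknown_parameter_raises(self, params):
        with pytest.raises(KeyError):
            params.with_value("nope", 1.0)

    def test_dump_frame_has_distribution_families(self, params):
        frame = params.to_frame()
        assert set(["name", "base", "low", "high", "kind", "units",
                    "distribution_family"]) <= set(frame.columns)
        row = frame.set_index("name").loc["c_readm"]
        assert row["distribution_family"] == "gamma"
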