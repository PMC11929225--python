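"""Scenario presets, truth oracles, replication and summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hiersim import (
    BINARY_TRUTH_REFERENCE,
    ScenarioSpec,
    run_replicate,
    run_scenario,
    summarize,
    true_effect,
    truth_reference_diagnostic,
)


class TestPresets:
    def test_scenario_coefficients(self):
        s1 = ScenarioSpec.preset("1")
        assert s1.rho == {"rho1": 0, "rho2": 0.3, "rho3": 0.3, "rho4": 0,
                          "rho5": 0, "rho6": 0}
        s2 = ScenarioSpec.preset("2")
        assert (s2.rho["rho4"], s2.rho["rho5"], s2.rho["rho6"]) == (0.3, 0.3, 0.8)
        assert s2.rho["rho2"] == 0.0
        s3 = ScenarioSpec.preset("3")
        assert s3.rho["rho1"] == 0.0 and s3.rho["rho2"] == 0.3
        s4 = ScenarioSpec.preset("4")
        assert s4.rho["rho1"] == 0.8  # causally related confounders

    def test_adaptation_marginals(self):
        s4a = ScenarioSpec.preset("4a")
        assert s4a.outcome.kind == "bernoulli" and s4a.outcome.p == 0.001
        s4b = ScenarioSpec.preset("4b")
        assert s4b.latent.kind == "bernoulli" and s4b.outcome.kind == "normal"
        s4c = ScenarioSpec.preset("4c")
        assert s4c.latent.p == s4c.outcome.p == 0.10

    def test_z_adjustment_only_when_present(self):
        assert ScenarioSpec.preset("1").with_z
        assert not ScenarioSpec.preset("2").with_z
        assert ScenarioSpec.preset("3").with_z

    def test_applicable_models(self):
        assert ScenarioSpec.preset("2").applicable_models() == (1, 2, 3, 4, 5, 6)
        assert 7 in ScenarioSpec.preset("2", outcome="binary").applicable_models()

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioSpec.preset("5")


class TestTruth:
    def test_continuous_truth_is_the_path_coefficient(self):
        spec = ScenarioSpec.preset("3")
        assert true_effect(spec, 0.3) == 0.3

    def test_binary_null_is_exact(self):
        spec = ScenarioSpec.preset("2", outcome="binary")
        assert true_effect(spec, 0.0) == 0.0

    def test_binary_truth_positive_and_increasing(self):
        spec = ScenarioSpec.preset("2", outcome="binary", base_seed=3)
        t1 = true_effect(spec, 0.1, oracle_n=150_000)
        t3 = true_effect(spec, 0.3, oracle_n=150_000)
        assert 0 < t1 < t3

    def test_reference_diagnostic_reports_not_asserts(self):
        spec = ScenarioSpec.preset("2", outcome="binary", base_seed=3)
        # restrict to the two cheapest grid points via the cache primed above
        table = truth_reference_diagnostic(spec, oracle_n=150_000)
        assert set(table["rho7"]) == set(BINARY_TRUTH_REFERENCE)
        assert "discrepancy" in table.columns


class TestReplication:
    def test_replicate_is_deterministic(self, tiny_spec):
        a = run_replicate(tiny_spec, 0.2, 0, models=(1, 2))
        b = run_replicate(tiny_spec, 0.2, 0, models=(1, 2))
        assert [e.beta_x for e in a] == [e.beta_x for e in b]

    def test_replicates_are_independent_of_execution_order(self, tiny_spec):
        """Seeds are indexed, so any execution order gives identical results."""
        later = run_replicate(tiny_spec, 0.0, 2, models=(1,))[0]
        earlier = run_replicate(tiny_spec, 0.0, 0, models=(1,))[0]
        again_later = run_replicate(tiny_spec, 0.0, 2, models=(1,))[0]
        assert later.beta_x == again_later.beta_x
        assert later.beta_x != earlier.beta_x

    def test_multilevel_estimate_near_truth_without_latent_confounding(self):
        spec = ScenarioSpec.preset("1", n=10_000, C=20, base_seed=5)
        est = run_replicate(spec, 0.2, 0, models=(1,))[0]
        assert 0.15 < est.beta_x < 0.25

    def test_ratio_models_come_back_rescaled(self, tiny_spec):
        ests = {e.model_id: e for e in run_replicate(tiny_spec, 0.2, 1)}
        for mid in (4, 5, 6):
            assert ests[mid].scale_note == "ratio-rescaled"
        assert ests[2].scale_note == "raw"


class TestScenarioRuns:
    def test_zero_replicates_is_empty_not_crash(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, replicates=0)
        result = run_scenario(spec)
        assert result.replicates.empty
        assert result.summary().empty

    def test_summary_shape_and_counts(self, tiny_spec):
        result = run_scenario(tiny_spec, models=(1, 2))
        s = result.summary()
        # 2 grid points x 2 models
        assert len(s) == 4
        assert (s["replicates_used"] + s["excluded"] == 3).all()
        assert (s["sd_bias"] >= 0).all()

    def test_median_estimate_monotone_in_effect_size(self):
        spec = ScenarioSpec.preset(
            "1", n=5_000, C=20, replicates=3, effect_grid=(0.0, 0.2, 0.4),
            base_seed=2,
        )
        s = run_scenario(spec, models=(1,)).summary().sort_values("rho7")
        assert s["median_estimate"].is_monotonic_increasing

    def test_summarize_roundtrip(self, tiny_spec, tmp_path):
        result = run_scenario(tiny_spec, models=(1, 2))
        out = tmp_path / "summary.csv"
        table = summarize([result], out_path=out)
        back = pd.read_csv(out, dtype={"scenario": str})
        pd.testing.assert_frame_equal(
            back, table, check_dtype=False, check_exact=False, atol=1e-12
        )

    def test_summarize_empty_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        table = summarize([], out_path=out)
        assert table.empty
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and "median_bias" in lines[0]

    def test_diagnostic_plot_written(self, tiny_spec, tmp_path):
        result = run_scenario(tiny_spec, models=(1, 2))
        plot = tmp_path / "fit.png"
        summarize([result], plot_path=plot)
        assert plot.stat().st_size > 0
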