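"""Model fits: multilevel, ecological, and ratio rescaling."""

import numpy as np
import pandas as pd
import pytest

from hiersim import (
    ClusterTable,
    Marginal,
    aggregate,
    build_clusters,
    fit_ecological,
    fit_multilevel,
    rescale_ratio_estimate,
    sample_mvn,
)
from hiersim.estimators import ModelEstimate
from hiersim.population_sim import PopulationSample


def _toy_table(X, Y, N, Z=None, outcome_tag="mean"):
    C = len(X)
    data = pd.DataFrame({
        "N_j": N,
        "Z_j": Z if Z is not None else np.zeros(C),
        "L_j": np.zeros(C),
        "X_j": X,
        "Y_j": Y,
    })
    tags = {"N_j": "size", "Z_j": "mean", "L_j": "mean", "X_j": "mean",
            "Y_j": outcome_tag}
    return ClusterTable(data=data, tags=tags)


class TestMultilevel:
    def test_noiseless_recovery(self):
        """Y constructed as exactly 0.4 X is recovered to 1e-6."""
        sample = sample_mvn(np.eye(5), n=2_000, seed=0)
        sample.data["Y"] = 0.4 * sample.data["X"]
        asn = build_clusters(sample.column("N"), C=10, seed=0)
        est = fit_multilevel(sample, asn, "normal", with_z=False)
        assert est.beta_x == pytest.approx(0.4, abs=1e-6)

    def test_aggregation_consistency_oracle(self, small_clustered):
        """With within-cluster variation removed, the multilevel and
        ecological estimators of the exposure effect coincide."""
        sample, assignment, _ = small_clustered
        df = sample.data.copy()
        for col in df.columns:
            df[col] = df.groupby(assignment.labels)[col].transform("mean")
        flat = PopulationSample(
            data=df, marginals=sample.marginals,
            target_corr=sample.target_corr, realized_corr=sample.realized_corr,
        )
        m1 = fit_multilevel(flat, assignment, "normal", with_z=False)
        m2 = fit_ecological(aggregate(flat, assignment), 2, "normal", with_z=False)
        assert m1.beta_x == pytest.approx(m2.beta_x, abs=1e-6)

    def test_binary_fit_is_flagged_marginal(self):
        sample = sample_mvn(np.eye(5), n=5_000, seed=2)
        rng = np.random.default_rng(3)
        sample.data["Y"] = (rng.random(5_000) < 0.1).astype(float)
        sample.marginals["Y"] = Marginal("bernoulli", 0.1)
        asn = build_clusters(sample.column("N"), C=20, seed=2)
        est = fit_multilevel(sample, asn, "poisson", with_z=True)
        assert est.family == "poisson"
        assert est.metadata["random_intercept"] is False
        assert "approximation" in est.metadata

    def test_rejects_unknown_family(self, small_clustered):
        sample, assignment, _ = small_clustered
        with pytest.raises(ValueError):
            fit_multilevel(sample, assignment, "logistic")


class TestEcological:
    def test_exact_linear_relation(self):
        """Y_j identically X_j with constant sizes gives slope 1."""
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        table = _toy_table(x, x, np.full(5, 100))
        est = fit_ecological(table, 2, "normal", with_z=False)
        assert est.beta_x == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_slope(self):
        # Y = 1 + 2X exactly; the constant N_j column is absorbed.
        table = _toy_table([0.0, 1.0, 2.0], [1.0, 3.0, 5.0], [1000] * 3)
        est = fit_ecological(table, 2, "normal", with_z=False)
        assert est.beta_x == pytest.approx(2.0, abs=1e-8)

    @pytest.mark.parametrize("model_id", [2, 3, 4, 5, 6])
    def test_continuous_designs_fit(self, small_clustered, model_id):
        _, _, table = small_clustered
        est = fit_ecological(table, model_id, "normal", with_z=False)
        assert est.converged
        assert est.family == "normal"
        assert np.isfinite(est.beta_x) and est.se > 0

    def test_model7_requires_binary_outcome(self, small_clustered):
        _, _, table = small_clustered
        with pytest.raises(ValueError, match="binary"):
            fit_ecological(table, 7, "normal")

    def test_ratio_models_are_linear_even_for_binary(self, small_clustered):
        _, _, table = small_clustered
        est = fit_ecological(table, 4, "poisson", with_z=False)
        assert est.family == "normal"

    def test_unknown_model_id(self, small_clustered):
        _, _, table = small_clustered
        with pytest.raises(ValueError):
            fit_ecological(table, 8, "normal")


class TestRescale:
    def _estimate(self, model_id=4, beta=50.0):
        return ModelEstimate(model_id=model_id, beta_x=beta, se=5.0,
                             converged=True, family="normal")

    def test_divides_by_cluster_count(self):
        out = rescale_ratio_estimate(self._estimate(), C=100)
        assert out.beta_x == 0.5
        assert out.se == 0.05
        assert out.scale_note == "ratio-rescaled"

    def test_zero_maps_to_zero(self):
        assert rescale_ratio_estimate(self._estimate(beta=0.0), C=7).beta_x == 0.0

    def test_roundtrip(self):
        out = rescale_ratio_estimate(self._estimate(beta=0.123), C=100)
        assert out.beta_x * 100 == pytest.approx(0.123, abs=1e-12)

    def test_custom_divisor(self):
        out = rescale_ratio_estimate(self._estimate(), C=100, divisor=1000.0)
        assert out.beta_x == pytest.approx(0.05)
        assert out.metadata["rescale_divisor"] == 1000.0

    def test_rejects_non_ratio_models(self):
        with pytest.raises(ValueError):
            rescale_ratio_estimate(self._estimate(model_id=2), C=100)

    def test_rejects_double_rescale(self):
        once = rescale_ratio_estimate(self._estimate(), C=100)
        with pytest.raises(ValueError):
            rescale_ratio_estimate(once, C=100)
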