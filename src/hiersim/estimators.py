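"""The seven analysis models: one multilevel, six ecological.

Model 1 is the individual-level analysis: a two-level regression of the
outcome on the exposure and cluster size (plus the observed confounder when
the scenario includes regular confounding).  Continuous outcomes use a
random-intercept linear mixed model.  Binary outcomes use a Poisson log-link
model so estimates are comparable across models; here the point estimate is
obtained from a pooled Poisson fit with cluster-robust variance and the
cluster-size covariate (a random-intercept Poisson contract fulfilled by a
marginal fit; flagged in the estimate metadata).

Models 2-7 are ecological: fitted on the C-row cluster table.

    2: Y_j ~ X_j + N_j             3: Y_j ~ X_j + 1/N_j
    4: Y_j/N_j ~ X_j/N_j           5: Y_j/N_j ~ X_j/N_j + N_j
    6: Y_j/N_j ~ X_j/N_j + 1/N_j   7: poisson Y_j ~ X_j + offset(log N_j)

For continuous outcomes all ecological models are linear.  For binary
outcomes, models 2, 3 and 7 are Poisson (log link) on the aggregated counts
while models 4-6 are linear on the proportions.  Ratio-model estimates
(4-6) are on a different scale and must be divided by the number of clusters
(``rescale_ratio_estimate``) before comparison with the simulated truth.

Ecological variables are used raw (no restandardisation): the variance
shrinkage induced by aggregation is the phenomenon under study.  No
weighting by cluster size is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .aggregation import ClusterTable
from .cluster_builder import ClusterAssignment
from .population_sim import PopulationSample

__all__ = [
    "ModelEstimate",
    "fit_multilevel",
    "fit_ecological",
    "rescale_ratio_estimate",
    "MULTILEVEL_MODEL",
    "ECOLOGICAL_MODELS",
    "RATIO_MODELS",
]

MULTILEVEL_MODEL = 1
ECOLOGICAL_MODELS = (2, 3, 4, 5, 6, 7)
RATIO_MODELS = (4, 5, 6)


@dataclass(frozen=True)
class ModelEstimate:
    """Exposure-effect estimate from one fitted model."""

    model_id: int
    beta_x: float
    se: float
    converged: bool
    family: str  # "normal" | "poisson"
    scale_note: str = "raw"  # "raw" | "ratio-rescaled"
    metadata: dict = field(default_factory=dict)


def _validate_family(outcome_family: str) -> None:
    if outcome_family not in ("normal", "poisson"):
        raise ValueError(f"unknown outcome family {outcome_family!r}")


def _profiled_gls_beta(
    y: np.ndarray,
    exog: np.ndarray,
    labels: np.ndarray,
    sigma2: float,
    tau2: float,
) -> np.ndarray:
    """Random-intercept GLS coefficients at given variance components.

    Uses the exact within/between decomposition: with variance ratio
    lambda = sigma2/tau2 the GLS normal equations are

        (S_w + sum_k c_k xbar_k xbar_k') beta = s_w + sum_k c_k xbar_k ybar_k,
        c_k = n_k lambda / (lambda + n_k),

    where S_w, s_w are within-cluster cross-products.  This is numerically
    stable at the sigma2 -> 0 boundary (cluster-constant data), where the
    estimator degenerates continuously to the unweighted between-cluster
    regression; the direct V^{-1} formulation loses ~2 digits there.
    """
    order = np.argsort(labels, kind="stable")
    y_s, x_s, lab_s = y[order], exog[order], labels[order]
    _, starts, counts = np.unique(lab_s, return_index=True, return_counts=True)
    xbar = np.add.reduceat(x_s, starts, axis=0) / counts[:, None]
    ybar = np.add.reduceat(y_s, starts) / counts
    x_w = x_s - np.repeat(xbar, counts, axis=0)
    y_w = y_s - np.repeat(ybar, counts)
    lam = max(sigma2 / max(tau2, 1e-300), 1e-12)
    c = counts * lam / (lam + counts)
    lhs = x_w.T @ x_w + (xbar * c[:, None]).T @ xbar
    rhs = x_w.T @ y_w + (xbar * c[:, None]).T @ ybar
    return np.linalg.lstsq(lhs, rhs, rcond=None)[0]


def fit_multilevel(
    sample: PopulationSample,
    assignment: ClusterAssignment,
    outcome_family: str = "normal",
    with_z: bool = True,
) -> ModelEstimate:
    """Model 1: individual-level Y on X and cluster size N_j (+ Z).

    ``outcome_family="normal"`` fits a random-intercept linear mixed model
    (REML).  ``"poisson"`` fits the log-link Poisson described in the module
    docstring; the approximation is recorded under
    ``metadata["random_intercept"]``.
    """
    _validate_family(outcome_family)
    y = sample.column("Y")
    n = y.size
    cols = [np.ones(n), sample.column("X"), assignment.sizes_per_individual()]
    names = ["const", "X", "N_j"]
    if with_z:
        cols.append(sample.column("Z"))
        names.append("Z")
    exog = np.column_stack(cols)

    if outcome_family == "normal":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(y, exog, groups=assignment.labels)
            try:
                res = model.fit(method="lbfgs", reml=True)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True)
        # Re-profile the coefficients at the fitted variance components via
        # the stable decomposition (identical away from the singular
        # boundary, exact at it).
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        beta = _profiled_gls_beta(y, exog, np.asarray(assignment.labels),
                                  float(res.scale), tau2)
        return ModelEstimate(
            model_id=MULTILEVEL_MODEL,
            beta_x=float(beta[1]),
            se=float(res.bse[1]),
            converged=bool(res.converged),
            family="normal",
            metadata={"random_intercept": True, "exog_names": names},
        )

    res = sm.GLM(y, exog, family=sm.families.Poisson()).fit(
        cov_type="cluster", cov_kwds={"groups": assignment.labels}
    )
    return ModelEstimate(
        model_id=MULTILEVEL_MODEL,
        beta_x=float(res.params[1]),
        se=float(res.bse[1]),
        converged=bool(res.converged),
        family="poisson",
        metadata={
            "random_intercept": False,
            "approximation": "pooled poisson, cluster-robust variance",
            "exog_names": names,
        },
    )


def _ecological_design(
    table: ClusterTable, model_id: int, outcome_family: str, with_z: bool
):
    """(y, exog, names, offset, family) for the Table-1 ecological designs."""
    nj = table.column("N_j").astype(float)
    xj = table.column("X_j")
    yj = table.column("Y_j")
    zj = table.column("Z_j")
    C = table.C
    offset = None
    family = outcome_family

    if model_id in (2, 3):
        y = yj
        exposure = xj
        extra = nj if model_id == 2 else 1.0 / nj
        extra_name = "N_j" if model_id == 2 else "1/N_j"
    elif model_id in RATIO_MODELS:
        # Ratio models are always linear, for binary outcomes too.
        family = "normal"
        y = yj / nj
        exposure = xj / nj
        if model_id == 4:
            extra, extra_name = None, None
        elif model_id == 5:
            extra, extra_name = nj, "N_j"
        else:
            extra, extra_name = 1.0 / nj, "1/N_j"
    elif model_id == 7:
        if outcome_family != "poisson":
            raise ValueError("model 7 (log-size offset) requires a binary outcome")
        y = yj
        exposure = xj
        extra, extra_name = None, None
        offset = np.log(nj)
    else:
        raise ValueError(f"model_id must be one of {ECOLOGICAL_MODELS}, got {model_id}")

    cols = [np.ones(C), exposure]
    names = ["const", "X_j" if model_id not in RATIO_MODELS else "X_j/N_j"]
    if extra is not None:
        cols.append(extra)
        names.append(extra_name)
    if with_z:
        cols.append(zj)
        names.append("Z_j")
    return y, np.column_stack(cols), names, offset, family


def fit_ecological(
    table: ClusterTable,
    model_id: int,
    outcome_family: str = "normal",
    with_z: bool = True,
) -> ModelEstimate:
    """Models 2-7 on the cluster table; returns the exposure coefficient.

    ``outcome_family`` refers to the individual-level outcome: "normal"
    (Y_j is a mean, all models linear) or "poisson" (Y_j is a count, models
    2, 3, 7 Poisson log-link, models 4-6 linear on proportions).  Zero
    counts are left to the Poisson likelihood; no continuity correction.
    """
    _validate_family(outcome_family)
    y, exog, names, offset, family = _ecological_design(
        table, model_id, outcome_family, with_z
    )
    if family == "poisson":
        res = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset).fit()
        converged = bool(res.converged)
    else:
        res = sm.OLS(y, exog).fit()
        converged = True
    return ModelEstimate(
        model_id=model_id,
        beta_x=float(res.params[1]),
        se=float(res.bse[1]),
        converged=converged,
        family=family,
        metadata={"exog_names": names},
    )


def rescale_ratio_estimate(
    est: ModelEstimate, C: int, divisor: float | None = None
) -> ModelEstimate:
    """Bring a ratio-model (4-6) estimate back to the individual scale.

    The default divisor is the number of clusters C; it is configurable
    because alternatives (e.g. the mean cluster size) are defensible.
    """
    if est.model_id not in RATIO_MODELS:
        raise ValueError("rescaling applies only to the ratio models 4-6")
    if est.scale_note == "ratio-rescaled":
        raise ValueError("estimate is already rescaled")
    d = float(C if divisor is None else divisor)
    return replace(
        est,
        beta_x=est.beta_x / d,
        se=est.se / d,
        scale_note="ratio-rescaled",
        metadata={**est.metadata, "rescale_divisor": d},
    )
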