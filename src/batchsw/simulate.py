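"""Seeded trial simulation and empirical power estimation.

Generates complete batched stepped wedge datasets, fits the analysis
models a trial statistician would use, and estimates rejection rates:

* continuous outcomes follow the linear mixed model with batch-specific
  period effects drawn N(0, 1), correlated cluster(-period) random
  effects and iid residuals; analysis is a REML linear mixed model with
  a random cluster intercept and batch-specific categorical period
  effects;
* binary outcomes are drawn with the conditional linear family method
  for exchangeable within-cluster correlation, with control prevalence
  following a linear trend in within-batch period; analysis is GEE with
  a logit link, exchangeable working correlation and batch-specific
  linear period terms.

Determinism: every replicate's random stream is derived from
``(seed, cell fingerprint, replicate index)`` via ``numpy``'s
``SeedSequence``, so any grid cell or single replicate can be reproduced
in isolation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .covariance import CorrelationModel, ParameterError
from .designs import UNOBSERVED, BatchedDesign, ConfigError
from .gee_power import MarginalSpec, gee_var_combined
from .lmm_power import power_from_variance, var_batched


class FeasibilityError(ValueError):
    """The requested mean/correlation combination admits no binary law."""


@dataclass(frozen=True)
class SimConfig:
    """Settings for one simulation cell.

    ``theta`` is a standardized mean difference for continuous outcomes
    and a risk difference for binary outcomes.  For continuous outcomes
    the batch-period effects are drawn from N(0, period_sd^2) in each
    replicate; for binary outcomes the control-condition prevalence in
    within-batch period t is ``control_base + control_slope * t``.
    """

    design: BatchedDesign
    m: int
    model: CorrelationModel
    outcome: str  # "continuous" | "binary"
    theta: float
    n_sims: int = 1000
    seed: int = 0
    alpha: float = 0.05
    period_sd: float = 1.0
    control_base: float = 0.4
    control_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.outcome not in ("continuous", "binary"):
            raise ConfigError("outcome must be 'continuous' or 'binary'")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if self.m < 1:
            raise ConfigError("cluster-period size m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie strictly in (0, 1)")

    def control_means(self, n_periods: int) -> np.ndarray:
        """Control-condition prevalence trajectory for a binary batch."""
        t = np.arange(1, n_periods + 1)
        return self.control_base + self.control_slope * t


@dataclass(frozen=True)
class FitResult:
    theta_hat: float
    se: float
    p_value: float
    converged: bool


@dataclass(frozen=True)
class SimResult:
    """Empirical rejection rate with its Monte-Carlo uncertainty."""

    rejection_rate: float
    mc_se: float
    n_fitted: int
    n_sims: int
    theoretical_power: float
    unreliable: bool = False


def mc_standard_error(p_hat: float, n: int) -> float:
    """Binomial standard error of an empirical rejection rate."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n))


def _cell_fingerprint(config: SimConfig) -> tuple[int, ...]:
    """Stable integer fingerprint of the simulation cell.

    Includes the calendar layout (hence batch overlaps), so different
    cells of a grid get genuinely independent streams even when their
    schematics coincide.
    """
    parts: list[int] = [0 if config.outcome == "continuous" else 1, config.m]
    for b in config.design.batches:
        parts.extend(
            (
                b.calendar_start,
                b.clusters_per_sequence,
                zlib.crc32(b.schematic.cells.tobytes()),
            )
        )
    for x in (
        config.model.sigma_alpha2,
        config.model.sigma_eps2,
        config.model.cac,
        config.theta,
        config.period_sd,
        config.control_base,
        config.control_slope,
    ):
        parts.append(int(round(x * 1e9)) & 0x7FFFFFFF)
    return tuple(parts)


def replicate_rng(config: SimConfig, replicate: int) -> np.random.Generator:
    """Random generator for one replicate of one simulation cell."""
    entropy = (config.seed, replicate) + _cell_fingerprint(config)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_continuous(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One continuous-outcome dataset in long format.

    Columns: batch, cluster (global id), sequence, period (within
    batch), individual, treatment, outcome.  Unobserved cells of the
    schematic contribute no rows.
    """
    if config.outcome != "continuous":
        raise ConfigError("config.outcome must be 'continuous'")
    frames = []
    cluster_id = 0
    sd_eps = np.sqrt(config.model.sigma_eps2)
    for bi, batch in enumerate(config.design.batches):
        sch = batch.schematic
        n_per, n_seq = sch.n_periods, sch.n_sequences
        n_clusters = n_seq * batch.clusters_per_sequence
        beta = rng.normal(0.0, config.period_sd, size=n_per)
        chol = np.linalg.cholesky(
            config.model.sigma_alpha2 * config.model.r_matrix(n_per)
            + 1e-12 * np.eye(n_per)
        )
        alpha = rng.standard_normal((n_clusters, n_per)) @ chol.T
        eps = rng.standard_normal((n_clusters, n_per, config.m)) * sd_eps

        seq_of_cluster = np.repeat(np.arange(n_seq), batch.clusters_per_sequence)
        x = sch.cells[seq_of_cluster].astype(float)  # (n_clusters, n_per)
        y = (
            beta[None, :, None]
            + config.theta * x[:, :, None]
            + alpha[:, :, None]
            + eps
        )
        obs = sch.cells[seq_of_cluster] != UNOBSERVED
        c_idx, t_idx = np.nonzero(obs)
        n_cells = c_idx.size
        frames.append(
            pd.DataFrame(
                {
                    "batch": bi + 1,
                    "cluster": cluster_id + np.repeat(c_idx, config.m) + 1,
                    "sequence": np.repeat(seq_of_cluster[c_idx], config.m) + 1,
                    "period": np.repeat(t_idx, config.m) + 1,
                    "individual": np.tile(np.arange(1, config.m + 1), n_cells),
                    "treatment": np.repeat(
                        x[c_idx, t_idx].astype(int), config.m
                    ),
                    "outcome": y[c_idx, t_idx].ravel(),
                }
            )
        )
        cluster_id += n_clusters
    return pd.concat(frames, ignore_index=True)


@lru_cache(maxsize=128)
def _clf_coefficients(
    means: tuple[float, ...], rho: float
) -> tuple[tuple[float, ...], ...]:
    """Conditional-linear-family regression coefficients.

    For a binary vector with marginal means ``means`` and exchangeable
    pairwise correlation ``rho``, observation j is drawn with
    conditional success probability

        lambda_j = mu_j + b_j' (y_{1:j-1} - mu_{1:j-1}),
        b_j = Sigma_{1:j-1,1:j-1}^{-1} sigma_{1:j-1, j},

    which reproduces the means and correlations exactly.  Feasibility
    requires every lambda_j to lie in [0, 1] for every binary history;
    the check is sharp (worst-case histories are evaluated term by
    term).  Raises :class:`FeasibilityError` otherwise.
    """
    mu = np.asarray(means, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise FeasibilityError("marginal means must lie strictly in (0, 1)")
    v = mu * (1.0 - mu)
    sd = np.sqrt(v)
    n = mu.size
    sigma = rho * np.outer(sd, sd)
    sigma[np.diag_indices(n)] = v
    coeffs: list[tuple[float, ...]] = [()]
    for j in range(1, n):
        b = np.linalg.solve(sigma[:j, :j], sigma[:j, j])
        lam_min = mu[j] + np.minimum(-b * mu[:j], b * (1.0 - mu[:j])).sum()
        lam_max = mu[j] + np.maximum(-b * mu[:j], b * (1.0 - mu[:j])).sum()
        if lam_min < -1e-12 or lam_max > 1.0 + 1e-12:
            raise FeasibilityError(
                f"conditional probability of observation {j + 1} ranges "
                f"[{lam_min:.4f}, {lam_max:.4f}] over binary histories; "
                f"correlation {rho} is infeasible for these means"
            )
        coeffs.append(tuple(b))
    return tuple(coeffs)


def _draw_clf(
    means: np.ndarray, rho: float, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw exchangeable correlated binary vectors for many clusters."""
    coeffs = _clf_coefficients(tuple(np.round(means, 12)), float(rho))
    n = means.size
    y = np.empty((n_clusters, n))
    u = rng.random((n_clusters, n))
    y[:, 0] = u[:, 0] < means[0]
    for j in range(1, n):
        b = np.asarray(coeffs[j])
        lam = means[j] + (y[:, :j] - means[:j]) @ b
        y[:, j] = u[:, j] < lam
    return y


def simulate_binary_clf(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One binary-outcome dataset via the conditional linear family.

    All observations of a cluster are exchangeable with correlation
    equal to the model's intracluster correlation (requires cac = 1);
    marginal cell means are the control trajectory plus the risk
    difference in intervention cells.
    """
    if config.outcome != "binary":
        raise ConfigError("config.outcome must be 'binary'")
    if config.model.cac != 1.0:
        raise ConfigError(
            "the conditional-linear-family generator supports exchangeable "
            "correlation only (cac = 1)"
        )
    rho = config.model.icc
    frames = []
    cluster_id = 0
    for bi, batch in enumerate(config.design.batches):
        sch = batch.schematic
        mu0 = config.control_means(sch.n_periods)
        for k in range(sch.n_sequences):
            obs = np.flatnonzero(sch.cells[k] != UNOBSERVED)
            x = sch.cells[k, obs].astype(float)
            mu_cells = mu0[obs] + config.theta * x
            if np.any(mu_cells <= 0) or np.any(mu_cells >= 1):
                raise FeasibilityError(
                    f"cell mean outside (0, 1) in batch {bi + 1}, "
                    f"sequence {k + 1}"
                )
            means = np.repeat(mu_cells, config.m)
            y = _draw_clf(means, rho, batch.clusters_per_sequence, rng)
            n_cells = obs.size
            for c in range(batch.clusters_per_sequence):
                frames.append(
                    pd.DataFrame(
                        {
                            "batch": bi + 1,
                            "cluster": cluster_id + c + 1,
                            "sequence": k + 1,
                            "period": np.repeat(obs + 1, config.m),
                            "individual": np.tile(
                                np.arange(1, config.m + 1), n_cells
                            ),
                            "treatment": np.repeat(x.astype(int), config.m),
                            "outcome": y[c],
                        }
                    )
                )
            cluster_id += batch.clusters_per_sequence
    return pd.concat(frames, ignore_index=True)


def fit_lmm(dataset: pd.DataFrame, alpha: float = 0.05) -> FitResult:
    """REML mixed-model fit for a continuous batched stepped wedge.

    The analysis model has batch-specific categorical period effects,
    the treatment indicator, a random cluster intercept and a random
    cluster-period effect.  The fit operates on cluster-period means:
    the cluster-period effect and the averaged residual then pool into a
    single iid cell-level error, which leaves the likelihood for the
    fixed effects (and hence the Wald test of the treatment effect)
    unchanged.  Reports a two-sided Wald z-test of theta = 0.
    """
    cells = (
        dataset.groupby(["batch", "cluster", "period", "treatment"], sort=True)[
            "outcome"
        ]
        .mean()
        .reset_index()
    )
    cells["bp"] = cells["batch"].astype(str) + ":" + cells["period"].astype(str)
    converged = False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "outcome ~ 0 + C(bp) + treatment", cells, groups=cells["cluster"]
        )
        # the default optimizer stalls near the variance boundary when the
        # intracluster correlation is small; fall through a retry ladder
        for method in (None, "lbfgs", "powell"):
            try:
                fit = model.fit(reml=True) if method is None else model.fit(
                    reml=True, method=method
                )
            except Exception:
                continue
            if fit.converged:
                converged = True
                break
    if fit is None:
        return FitResult(np.nan, np.nan, np.nan, False)
    theta_hat = float(fit.params["treatment"])
    se = float(fit.bse["treatment"])
    p = float(fit.pvalues["treatment"])
    if not np.isfinite(p):
        converged = False
    return FitResult(theta_hat, se, p, converged)


def fit_gee(dataset: pd.DataFrame, alpha: float = 0.05) -> FitResult:
    """GEE fit for a binary batched stepped wedge.

    Logit link, exchangeable working correlation, batch-specific
    intercepts and batch-specific linear period terms, and the treatment
    indicator; the test of theta = 0 uses the robust (sandwich)
    variance.  If period does not vary within any batch the slope terms
    are aliased and are dropped with a warning.
    """
    data = dataset.copy()
    periods_per_batch = data.groupby("batch")["period"].nunique()
    if (periods_per_batch > 1).all():
        formula = "outcome ~ 0 + C(batch) + C(batch):period + treatment"
    else:
        warnings.warn(
            "period does not vary within a batch; dropping the period slope",
            stacklevel=2,
        )
        formula = "outcome ~ 0 + C(batch) + treatment"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.gee(
                formula,
                groups="cluster",
                data=data,
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
        except Exception:
            return FitResult(np.nan, np.nan, np.nan, False)
    theta_hat = float(fit.params["treatment"])
    se = float(fit.bse["treatment"])
    p = float(fit.pvalues["treatment"])
    if not np.isfinite(p):
        converged = False
    return FitResult(theta_hat, se, p, converged)


def theoretical_power(config: SimConfig) -> float:
    """Closed-form companion power for a simulation cell.

    Continuous outcomes use the linear-model GLS variance.  Binary
    outcomes use the marginal-model variance with the identity link (the
    generating model is additive on the risk scale), binomial variance
    function, the true exchangeable correlation as working structure,
    and batch-specific linear period effects to mirror the analysis
    model.
    """
    if config.outcome == "continuous":
        res = var_batched(config.design, config.model, config.m)
        return power_from_variance(res.var_combined, config.theta, config.alpha)
    specs = [
        MarginalSpec(
            link="identity",
            variance_function="binomial",
            control_mean_by_period=tuple(
                config.control_means(b.schematic.n_periods)
            ),
            theta=config.theta,
            working=config.model,
            m=config.m,
        )
        for b in config.design.batches
    ]
    res = gee_var_combined(specs, config.design, period_effects="linear")
    return power_from_variance(res.var_combined, config.theta, config.alpha)


def simulate_dataset(config: SimConfig, replicate: int) -> pd.DataFrame:
    """Generate the dataset for one seeded replicate."""
    rng = replicate_rng(config, replicate)
    if config.outcome == "continuous":
        return simulate_continuous(config, rng)
    return simulate_binary_clf(config, rng)


def empirical_power(config: SimConfig) -> SimResult:
    """Estimate the rejection rate of H0: theta = 0 over seeded replicates.

    Replicates that fail to converge are excluded from the rate and
    counted; if more than 10% fail the result is flagged unreliable.
    """
    rejections = 0
    n_fitted = 0
    for rep in range(config.n_sims):
        data = simulate_dataset(config, rep)
        fit = fit_lmm(data, config.alpha) if config.outcome == "continuous" else fit_gee(
            data, config.alpha
        )
        if not fit.converged or not np.isfinite(fit.p_value):
            continue
        n_fitted += 1
        rejections += int(fit.p_value < config.alpha)
    if n_fitted == 0:
        return SimResult(np.nan, np.nan, 0, config.n_sims, theoretical_power(config), True)
    rate = rejections / n_fitted
    return SimResult(
        rejection_rate=rate,
        mc_se=mc_standard_error(rate, n_fitted),
        n_fitted=n_fitted,
        n_sims=config.n_sims,
        theoretical_power=theoretical_power(config),
        unreliable=(config.n_sims - n_fitted) > 0.1 * config.n_sims,
    )
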