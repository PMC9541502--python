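"""Marginal-model (GEE) variance and power for the treatment effect.

For binary or count outcomes analyzed marginally, the mean model is

    g(mu_bkti) = beta_bt + theta * X_bkt,

with link g, batch-specific period effects and a shared link-scale
treatment effect theta.  The model-based GEE variance of theta-hat for
one batch is the Schur complement of the quasi-information matrix

    sum_k D_k' W_k^-1 D_k,      D_k = [d mu / d beta, d mu / d theta],

where W_k = A_k^(1/2) R_k A_k^(1/2) combines the variance function A
with the working correlation R.  Unlike the linear case, the variance
depends on the assumed control-condition mean trajectory, so per-batch
prevalences enter power calculations; batches still combine by summing
precisions when separate period effects are used per batch.

Computation operates at the cluster-period-mean level, which is exact:
averaging m exchangeable individuals inside each cell gives cell-mean
covariance

    cov(Ybar_t, Ybar_s) = v_t (1 + (m - 1) rho) / m            (t = s)
                        = sqrt(v_t v_s) rho r_ts               (t != s)

with v_t the variance function at the cell mean, rho the within-period
intracluster correlation and r_ts its between-period attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .covariance import CorrelationModel, ParameterError
from .designs import UNOBSERVED, BatchedDesign, ConfigError, TreatmentSchematic
from .lmm_power import InestimableDesignError, VarianceResult, combine_batches

_LINKS: dict[str, tuple[Callable, Callable, Callable]] = {
    # link, inverse link, derivative of inverse link wrt linear predictor
    "logit": (
        lambda mu: np.log(mu / (1.0 - mu)),
        lambda eta: 1.0 / (1.0 + np.exp(-eta)),
        lambda eta: np.exp(-eta) / (1.0 + np.exp(-eta)) ** 2,
    ),
    "identity": (lambda mu: mu, lambda eta: eta, lambda eta: np.ones_like(eta)),
    "log": (np.log, np.exp, np.exp),
}

_VARIANCE_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "binomial": lambda mu: mu * (1.0 - mu),
    "poisson": lambda mu: mu,
    "gaussian": lambda mu: np.ones_like(mu),
}


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal mean model and working covariance for one batch.

    Attributes
    ----------
    link
        ``logit``, ``identity`` or ``log``.
    variance_function
        ``binomial`` (mu(1-mu)), ``poisson`` (mu) or ``gaussian``
        (constant; scaled by ``dispersion``).
    control_mean_by_period
        Control-condition means mu0_t, one per within-batch period.
    theta
        Treatment effect on the link scale.
    working
        Correlation model supplying the working intracluster
        correlation (its ``icc``) and between-period attenuation.
    m
        Number of individuals per cluster-period.
    dispersion
        Scale of the gaussian variance function (total variance of one
        observation); ignored for binomial/poisson.
    """

    link: str
    variance_function: str
    control_mean_by_period: tuple[float, ...]
    theta: float
    working: CorrelationModel
    m: int
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.link not in _LINKS:
            raise ParameterError(f"unknown link {self.link!r}")
        if self.variance_function not in _VARIANCE_FUNCTIONS:
            raise ParameterError(
                f"unknown variance function {self.variance_function!r}"
            )
        mu0 = tuple(float(x) for x in self.control_mean_by_period)
        if self.variance_function == "binomial" and not all(0 < x < 1 for x in mu0):
            raise ParameterError("binomial means must lie strictly in (0, 1)")
        if self.variance_function == "poisson" and not all(x > 0 for x in mu0):
            raise ParameterError("poisson means must be strictly positive")
        if self.m < 1:
            raise ParameterError("cluster-period size m must be >= 1")
        object.__setattr__(self, "control_mean_by_period", mu0)

    @property
    def n_periods(self) -> int:
        return len(self.control_mean_by_period)


def logit_effect(p0: float, p1: float) -> float:
    """Treatment effect on the logit scale for prevalences p0 -> p1."""
    for p in (p0, p1):
        if not 0 < p < 1:
            raise ParameterError("prevalences must lie strictly in (0, 1)")
    return float(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)))


def cell_means(spec: MarginalSpec, schematic: TreatmentSchematic) -> np.ndarray:
    """Matrix of marginal means mu_kt implied by the mean model.

    mu_kt = g^-1(g(mu0_t) + theta * X_kt); unobserved cells are NaN.
    Control cells reproduce mu0_t exactly.
    """
    if spec.n_periods != schematic.n_periods:
        raise ConfigError(
            f"spec has {spec.n_periods} periods but schematic has "
            f"{schematic.n_periods}"
        )
    link, inv, _ = _LINKS[spec.link]
    mu0 = np.asarray(spec.control_mean_by_period, dtype=float)
    eta = link(mu0)[None, :] + spec.theta * schematic.cells.astype(float)
    mu = np.where(schematic.cells == UNOBSERVED, np.nan, inv(eta))
    # control cells carry the stated means exactly (no round trip error)
    control = schematic.cells == 0
    mu[control] = np.broadcast_to(mu0, mu.shape)[control]
    _check_domain(spec, mu)
    return mu


def _check_domain(spec: MarginalSpec, mu: np.ndarray) -> None:
    vals = mu[np.isfinite(mu)]
    if spec.variance_function == "binomial" and (
        np.any(vals <= 0) or np.any(vals >= 1)
    ):
        raise ParameterError("implied binomial means leave (0, 1)")
    if spec.variance_function == "poisson" and np.any(vals <= 0):
        raise ParameterError("implied poisson means are not positive")


def _cell_mean_working_cov(spec: MarginalSpec, mu_row: np.ndarray) -> np.ndarray:
    """Working covariance of one cluster's cell means (observed cells)."""
    v = _VARIANCE_FUNCTIONS[spec.variance_function](mu_row)
    if spec.variance_function == "gaussian":
        v = v * spec.dispersion
    rho = spec.working.icc
    n = mu_row.size
    r = spec.working.r_matrix(n)  # indices are consecutive observed periods
    sd = np.sqrt(v)
    w = np.outer(sd, sd) * rho * r
    w[np.diag_indices(n)] = v * (1.0 + (spec.m - 1) * rho) / spec.m
    return w


PERIOD_EFFECT_CHOICES = ("categorical", "linear", "none")


def gee_var_batch(
    spec: MarginalSpec,
    schematic: TreatmentSchematic,
    clusters_per_sequence: int = 1,
    period_effects: str = "categorical",
) -> float:
    """Model-based GEE variance of theta-hat for one batch.

    ``period_effects`` selects the nuisance parameterization of time in
    the mean model: ``categorical`` fits one coefficient per
    within-batch period (the recommended, assumption-lean default),
    ``linear`` fits an intercept plus a linear term in period, and
    ``none`` fits a single intercept (appropriate only when the control
    mean is genuinely constant over time; it yields markedly higher
    power because no information is spent on secular trends).
    """
    if clusters_per_sequence < 1:
        raise ParameterError("clusters_per_sequence must be a positive integer")
    if period_effects not in PERIOD_EFFECT_CHOICES:
        raise ParameterError(
            f"period_effects must be one of {PERIOD_EFFECT_CHOICES}"
        )
    problems = schematic.violations()
    if problems:
        raise InestimableDesignError("; ".join(problems))
    link, _, dinv = _LINKS[spec.link]
    mu = cell_means(spec, schematic)
    mu0 = np.asarray(spec.control_mean_by_period, dtype=float)
    n_per = schematic.n_periods
    n_beta = {"categorical": n_per, "linear": 2, "none": 1}[period_effects]

    i_bb = np.zeros((n_beta, n_beta))
    i_bt = np.zeros(n_beta)
    i_tt = 0.0
    for k in range(schematic.n_sequences):
        obs = schematic.cells[k] != UNOBSERVED
        if not obs.any():
            continue
        x = schematic.cells[k, obs].astype(float)
        eta = link(mu0[obs]) + spec.theta * x
        deriv = dinv(eta)  # d mu / d eta at each observed cell
        w = _cell_mean_working_cov(spec, mu[k, obs])
        # note r_ts in the working covariance uses positions among the
        # observed cells; exact for exchangeable-type structures, and for
        # discrete decay when observed periods are contiguous
        w_inv = np.linalg.inv(w)
        d_theta = deriv * x
        if period_effects == "categorical":
            d_beta = np.zeros((int(obs.sum()), n_beta))
            d_beta[np.arange(obs.sum()), np.flatnonzero(obs)] = deriv
        elif period_effects == "linear":
            periods = np.flatnonzero(obs) + 1.0
            d_beta = np.column_stack([deriv, deriv * periods])
        else:
            d_beta = deriv[:, None]
        i_bb += d_beta.T @ w_inv @ d_beta
        i_bt += d_beta.T @ w_inv @ d_theta
        i_tt += float(d_theta @ w_inv @ d_theta)

    used = np.diag(i_bb) > 0
    info = i_tt - float(
        i_bt[used] @ np.linalg.solve(i_bb[np.ix_(used, used)], i_bt[used])
    )
    if info <= 1e-12 * max(i_tt, 1.0):
        raise InestimableDesignError(
            "treatment effect information is singular given the period effects"
        )
    return 1.0 / info / clusters_per_sequence


def gee_var_combined(
    specs: Sequence[MarginalSpec],
    design: BatchedDesign,
    period_effects: str = "categorical",
) -> VarianceResult:
    """Combine per-batch GEE variances by summing precisions.

    Requires one spec per batch sharing the same link-scale theta; the
    control-mean trajectories may differ by batch, which (unlike the
    linear model) changes each batch's variance.
    """
    if len(specs) != design.n_batches:
        raise ConfigError(
            f"{len(specs)} specs for {design.n_batches} batches"
        )
    thetas = {float(s.theta) for s in specs}
    if len(thetas) > 1:
        raise ConfigError("all batches must share the same treatment effect theta")
    per_batch = [
        gee_var_batch(
            spec, batch.schematic, batch.clusters_per_sequence, period_effects
        )
        for spec, batch in zip(specs, design.batches)
    ]
    result = combine_batches(per_batch)
    return VarianceResult(
        var_combined=result.var_combined,
        var_per_batch=result.var_per_batch,
        method="gee",
        var0=result.var0,
    )
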