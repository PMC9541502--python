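"""Within-cluster correlation structures and covariance matrices.

Outcomes from the same cluster are correlated through random
cluster-period effects alpha_{bkt} with var(alpha_{bkt}) = sigma_alpha^2
and cov(alpha_{bkt}, alpha_{bks}) = r_ts * sigma_alpha^2.  Three standard
choices of r_ts are supported:

* ``hussey_hughes``       r_ts = 1 (a single random cluster intercept),
* ``nested_exchangeable`` r_ts = r for t != s,
* ``discrete_decay``      r_ts = r ** |t - s|.

The intracluster correlation rho is the correlation between two
individuals in the same cluster and period; the cluster autocorrelation
r attenuates it across periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRUCTURES = ("hussey_hughes", "nested_exchangeable", "discrete_decay")


class ParameterError(ValueError):
    """A correlation or variance parameter is out of its valid range."""


class NumericError(RuntimeError):
    """A computed covariance matrix is numerically unusable."""


@dataclass(frozen=True)
class CorrelationModel:
    """Variance components defining the within-cluster covariance.

    Attributes
    ----------
    structure
        One of ``hussey_hughes``, ``nested_exchangeable``,
        ``discrete_decay``.
    sigma_alpha2
        Variance of the cluster(-period) random effect.
    sigma_eps2
        Individual-level residual variance.
    cac
        Cluster autocorrelation r in (0, 1]; 1 for Hussey-Hughes.
    """

    structure: str
    sigma_alpha2: float
    sigma_eps2: float
    cac: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ParameterError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if self.sigma_alpha2 < 0 or self.sigma_eps2 <= 0:
            raise ParameterError("variance components must be positive (sigma_alpha2 >= 0)")
        if not 0 < self.cac <= 1:
            raise ParameterError("cac must lie in (0, 1]")

    @property
    def total_var(self) -> float:
        return self.sigma_alpha2 + self.sigma_eps2

    @property
    def icc(self) -> float:
        """Within-period intracluster correlation rho."""
        return self.sigma_alpha2 / self.total_var

    def r_ts(self, t: int, s: int) -> float:
        """Between-period attenuation of the cluster-effect covariance."""
        if t == s:
            return 1.0
        if self.structure == "hussey_hughes":
            return 1.0
        if self.structure == "nested_exchangeable":
            return self.cac
        return self.cac ** abs(t - s)

    def r_matrix(self, n_periods: int) -> np.ndarray:
        """The T x T matrix of r_ts values."""
        t = np.arange(n_periods)
        lag = np.abs(t[:, None] - t[None, :])
        if self.structure == "hussey_hughes":
            return np.ones((n_periods, n_periods))
        if self.structure == "nested_exchangeable":
            return np.where(lag == 0, 1.0, self.cac)
        return self.cac ** lag


def from_icc_cac(
    structure: str,
    icc: float,
    cac: float = 1.0,
    total_var: float = 1.0,
) -> CorrelationModel:
    """Build a correlation model by splitting a total variance.

    sigma_alpha^2 = rho * sigma^2 and sigma_eps^2 = (1 - rho) * sigma^2,
    so that rho is the within-period intracluster correlation.  For the
    Hussey-Hughes structure ``cac`` is forced to 1.
    """
    if not 0 <= icc < 1:
        raise ParameterError("icc must lie in [0, 1)")
    if not 0 < cac <= 1:
        raise ParameterError("cac must lie in (0, 1]")
    if total_var <= 0:
        raise ParameterError("total_var must be positive")
    if structure == "hussey_hughes":
        cac = 1.0
    return CorrelationModel(
        structure=structure,
        sigma_alpha2=icc * total_var,
        sigma_eps2=(1.0 - icc) * total_var,
        cac=cac,
    )


def binary_as_linear(
    p: float,
    icc: float,
    structure: str = "hussey_hughes",
    cac: float = 1.0,
) -> CorrelationModel:
    """Variance components for treating a binary outcome as linear.

    The residual variance is fixed at the Bernoulli variance,
    sigma_eps^2 = p(1 - p), and the cluster-effect variance is
    back-solved from the intracluster correlation:
    sigma_alpha^2 = icc * sigma_eps^2 / (1 - icc).
    """
    if not 0 < p < 1:
        raise ParameterError("prevalence p must lie strictly in (0, 1)")
    if not 0 <= icc < 1:
        raise ParameterError("icc must lie in [0, 1)")
    sigma_eps2 = p * (1.0 - p)
    sigma_alpha2 = icc * sigma_eps2 / (1.0 - icc)
    if structure == "hussey_hughes":
        cac = 1.0
    return CorrelationModel(
        structure=structure,
        sigma_alpha2=sigma_alpha2,
        sigma_eps2=sigma_eps2,
        cac=cac,
    )


def cluster_period_cov(
    n_periods: int, m: int, model: CorrelationModel
) -> np.ndarray:
    """Covariance matrix V of one cluster's cluster-period means.

    V[t, s] = sigma_alpha^2 * r_ts + 1{t = s} * sigma_eps^2 / m, the
    covariance of the T period means of a cluster observing m
    individuals per period.
    """
    if m < 1:
        raise ParameterError("cluster-period size m must be >= 1")
    v = model.sigma_alpha2 * model.r_matrix(n_periods)
    v = v + np.eye(n_periods) * (model.sigma_eps2 / m)
    eigmin = float(np.linalg.eigvalsh(v)[0])
    if eigmin <= 0:
        raise NumericError(
            f"cluster-period covariance not positive definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    return v


def individual_cov(n_periods: int, m: int, model: CorrelationModel) -> np.ndarray:
    """Covariance of all T*m individual outcomes of one cluster.

    Ordered period-major: rows/columns (t-1)*m + i for individual i of
    period t.  Averaging within periods reproduces
    :func:`cluster_period_cov` exactly; used as the brute-force building
    block of the full GLS oracle.
    """
    if m < 1:
        raise ParameterError("cluster-period size m must be >= 1")
    r = model.r_matrix(n_periods)
    sigma = model.sigma_alpha2 * np.kron(r, np.ones((m, m)))
    sigma[np.diag_indices_from(sigma)] += model.sigma_eps2
    return sigma
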