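"""Variance and power of the treatment effect under linear mixed models.

The outcome model for individual i of cluster k in period t of batch b is

    Y_bkti = beta_bt + theta * X_bkt + alpha_bkt + eps_bkti,

with batch-specific fixed period effects beta_bt, shared treatment
effect theta, correlated cluster-period random effects alpha and iid
residuals.  Collapsing to cluster-period means, the generalized least
squares variance of theta-hat in one batch with one cluster per sequence
is

    var0 = [ sum_k X_k' V^-1 X_k
             - (1/K) (sum_k X_k)' V^-1 (sum_k X_k) ]^-1,

where V is the covariance of a cluster's period means and X_k the
treatment-indicator vector of sequence k.  With C clusters per sequence
the variance is var0 / C, and independent batches combine by summing
precisions: var = (sum_b 1 / var_b)^-1.  Because the period effects are
batch-specific, none of this depends on how batches align in calendar
time — the design's power is robust to delays between batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .covariance import CorrelationModel, ParameterError, cluster_period_cov, individual_cov
from .designs import UNOBSERVED, BatchedDesign, TreatmentSchematic

_SINGULAR_TOL = 1e-10


class InestimableDesignError(ValueError):
    """The design carries no information about the treatment effect."""


@dataclass(frozen=True)
class VarianceResult:
    """Per-batch and combined variance of the treatment-effect estimator."""

    var_combined: float
    var_per_batch: tuple[float, ...]
    method: str
    var0: float | None = None  # common per-component variance, identical batches only

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.var_per_batch) or self.var_combined <= 0:
            raise ParameterError("variances must be strictly positive")


def _information_components(
    cells: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Accumulate the GLS information blocks over sequences.

    Returns (I_bb, I_bt, I_tt) for the period-effect block, the
    period-by-treatment block and the treatment scalar, with unobserved
    cells dropped (their rows/columns of V are deleted per sequence).
    """
    n_seq, n_per = cells.shape
    i_bb = np.zeros((n_per, n_per))
    i_bt = np.zeros(n_per)
    i_tt = 0.0
    for k in range(n_seq):
        obs = cells[k] != UNOBSERVED
        if not obs.any():
            continue
        w = np.linalg.inv(v[np.ix_(obs, obs)])
        x = cells[k, obs].astype(float)
        i_bb[np.ix_(obs, obs)] += w
        i_bt[obs] += w @ x
        i_tt += float(x @ w @ x)
    return i_bb, i_bt, i_tt


def var_single_batch(
    schematic: TreatmentSchematic,
    v: np.ndarray,
    clusters_per_sequence: int = 1,
) -> float:
    """GLS variance of theta-hat for one stepped wedge component.

    Profiles out the within-batch period effects via the Schur
    complement of the information matrix; equivalent to the full
    individual-level GLS fit with batch-specific period fixed effects.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (schematic.n_periods, schematic.n_periods):
        raise ParameterError(
            f"V must be {schematic.n_periods} x {schematic.n_periods}, got {v.shape}"
        )
    if clusters_per_sequence < 1:
        raise ParameterError("clusters_per_sequence must be a positive integer")
    problems = schematic.violations()
    if problems:
        raise InestimableDesignError("; ".join(problems))

    i_bb, i_bt, i_tt = _information_components(schematic.cells, v)
    used = np.diag(i_bb) > 0  # periods observed in at least one sequence
    info = i_tt - float(
        i_bt[used] @ np.linalg.solve(i_bb[np.ix_(used, used)], i_bt[used])
    )
    if info <= _SINGULAR_TOL * max(i_tt, 1.0):
        raise InestimableDesignError(
            "treatment indicator is confounded with the period effects"
        )
    return 1.0 / info / clusters_per_sequence


def combine_batches(var_per_batch: Sequence[float]) -> VarianceResult:
    """Combine per-batch variances by summing precisions.

    var(theta-hat) = (sum_b 1 / var_b)^-1; for B identical batches with
    common variance var0 this is var0 / B.
    """
    variances = [float(v) for v in var_per_batch]
    if len(variances) == 0:
        raise ParameterError("at least one per-batch variance is required")
    if any(v <= 0 for v in variances):
        raise ParameterError("per-batch variances must be strictly positive")
    combined = 1.0 / sum(1.0 / v for v in variances)
    var0 = variances[0] if len(set(variances)) == 1 else None
    return VarianceResult(
        var_combined=combined,
        var_per_batch=tuple(variances),
        method="reduced_eq3",
        var0=var0,
    )


def var_batched(
    design: BatchedDesign, model: CorrelationModel, m: int
) -> VarianceResult:
    """Variance of theta-hat for a batched design.

    Computes each batch's GLS variance from its own schematic and
    combines by precision.  The result is independent of the batches'
    calendar offsets/overlaps by construction: only the schematics and
    cluster counts enter.
    """
    per_batch = []
    for batch in design.batches:
        v = cluster_period_cov(batch.schematic.n_periods, m, model)
        per_batch.append(
            var_single_batch(batch.schematic, v, batch.clusters_per_sequence)
        )
    return combine_batches(per_batch)


def gls_oracle(
    design: BatchedDesign,
    model: CorrelationModel,
    m: int,
    include_batch_period_interaction: bool = True,
) -> float:
    """Brute-force individual-level GLS variance of theta-hat.

    Materializes the full design matrix (batch-specific period indicator
    columns when the interaction flag is set, otherwise shared
    calendar-period indicators) and the block-diagonal covariance over
    clusters, and returns the theta entry of (W' Sigma^-1 W)^-1.  Test
    scale only: O(total observations ** 3).
    """
    x_rows: list[np.ndarray] = []  # per-cluster design blocks
    sigmas: list[np.ndarray] = []

    if include_batch_period_interaction:
        n_period_cols = sum(b.schematic.n_periods for b in design.batches)
        col_offset = {}
        off = 0
        for bi, b in enumerate(design.batches):
            col_offset[bi] = off
            off += b.schematic.n_periods
    else:
        n_period_cols = design.total_calendar_periods

    for bi, batch in enumerate(design.batches):
        sch = batch.schematic
        full_sigma = individual_cov(sch.n_periods, m, model)
        for k in range(sch.n_sequences):
            obs_periods = np.flatnonzero(sch.cells[k] != UNOBSERVED)
            if obs_periods.size == 0:
                continue
            rows = np.concatenate(
                [np.arange(t * m, (t + 1) * m) for t in obs_periods]
            )
            sigma_k = full_sigma[np.ix_(rows, rows)]
            block = np.zeros((rows.size, n_period_cols + 1))
            for j, t in enumerate(obs_periods):
                if include_batch_period_interaction:
                    col = col_offset[bi] + t
                else:
                    col = batch.calendar_start - 1 + t
                block[j * m : (j + 1) * m, col] = 1.0
                block[j * m : (j + 1) * m, -1] = float(sch.cells[k, t])
            for _ in range(batch.clusters_per_sequence):
                x_rows.append(block)
                sigmas.append(sigma_k)

    info = np.zeros((n_period_cols + 1, n_period_cols + 1))
    for block, sigma_k in zip(x_rows, sigmas):
        info += block.T @ np.linalg.solve(sigma_k, block)

    # drop all-zero period columns (calendar periods no batch observes)
    keep = np.diag(info) > 0
    if not keep[-1]:
        raise InestimableDesignError("no observed treatment contrast")
    info = info[np.ix_(keep, keep)]
    eigvals = np.linalg.eigvalsh(info)
    if eigvals[0] <= _SINGULAR_TOL * eigvals[-1]:
        aliased = _aliased_columns(info)
        raise InestimableDesignError(
            f"design matrix is rank deficient (aliased columns: {aliased})"
        )
    cov = np.linalg.inv(info)
    return float(cov[-1, -1])


def _aliased_columns(info: np.ndarray) -> list[int]:
    """Indices of columns in the null space of the information matrix."""
    _, s, vt = np.linalg.svd(info)
    null = vt[s <= _SINGULAR_TOL * s[0]]
    if null.size == 0:
        return []
    return sorted(int(i) for i in np.flatnonzero(np.abs(null).max(axis=0) > 1e-6))


def clusters_for_power(
    schematic: TreatmentSchematic,
    model: CorrelationModel,
    m: int,
    theta: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
    max_clusters: int = 10_000,
) -> int:
    """Smallest clusters-per-sequence reaching the target power.

    Convenience search for a single-component design; power is monotone
    in the cluster count, so a bisection over C suffices.
    """
    if not 0 < target_power < 1:
        raise ParameterError("target_power must lie strictly in (0, 1)")
    v = cluster_period_cov(schematic.n_periods, m, model)
    var1 = var_single_batch(schematic, v, 1)

    def power_at(c: int) -> float:
        return power_from_variance(var1 / c, theta, alpha)

    lo, hi = 1, max_clusters
    if power_at(hi) < target_power:
        raise ParameterError(
            f"target power {target_power} unreachable within {max_clusters} "
            "clusters per sequence"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def power_from_variance(var: float, theta: float, alpha: float = 0.05) -> float:
    """Power of the two-sided Wald z-test of H0: theta = 0.

    Normal approximation with known variance:
    power = Phi(|theta| / sqrt(var) - z_{1 - alpha/2}).
    """
    if var <= 0:
        raise ParameterError("variance must be strictly positive")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie strictly in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(theta) / np.sqrt(var) - z_crit))
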