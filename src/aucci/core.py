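"""Rank-based estimation of the area under the ROC curve (AUC).

For a diagnostic marker measured in ``n1`` cases and ``n0`` controls, the AUC
equals ``P(X1 > X0) + 0.5 * P(X1 = X0)`` for a random case/control pair: the
probability that a randomly chosen diseased individual scores higher than a
randomly chosen non-diseased one, ties counted half.  The estimator used
throughout this package is the (normalized) Mann-Whitney statistic, computed
from mid-ranks of the pooled sample::

    auc_hat = (rbar1 - rbar0) / n + 0.5

where ``rbar_i`` is the mean pooled mid-rank of group ``i`` and
``n = n0 + n1``.  This module provides the estimator, the placement-value
("structural component") standard error, Bamber's distribution-free variance,
the asymptotic maximum variance behind the modified Wald interval, and the
parametric binormal AUC fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MarkerSample",
    "RankSummary",
    "SummaryAUC",
    "VarianceEstimates",
    "BinormalFit",
    "compute_midranks",
    "estimate_auc",
    "placement_values",
    "se_empirical",
    "var_bamber",
    "var_max",
    "variance_estimates",
    "fit_binormal",
]


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty: each status group needs at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values; missing data is not allowed")
    return arr


@dataclass(frozen=True)
class MarkerSample:
    """Individual-level marker data for a two-group (case-control) study.

    ``values0`` are the control measurements, ``values1`` the case
    measurements.  Higher marker values are assumed to indicate disease
    (monotonic posterior); ties are allowed, missing values are not.
    """

    values0: np.ndarray
    values1: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values0", _as_group(self.values0, "values0 (controls)"))
        object.__setattr__(self, "values1", _as_group(self.values1, "values1 (cases)"))

    @property
    def n0(self) -> int:
        return self.values0.size

    @property
    def n1(self) -> int:
        return self.values1.size

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    def swapped(self) -> "MarkerSample":
        """Return the sample with case and control labels exchanged."""
        return MarkerSample(values0=self.values1, values1=self.values0)


@dataclass(frozen=True)
class RankSummary:
    """Pooled mid-ranks of a :class:`MarkerSample`, split by group."""

    midranks0: np.ndarray
    midranks1: np.ndarray

    @property
    def rbar0(self) -> float:
        return float(self.midranks0.mean())

    @property
    def rbar1(self) -> float:
        return float(self.midranks1.mean())


@dataclass(frozen=True)
class SummaryAUC:
    """The published summary several intervals can be built from.

    Only the estimated AUC and the two group sizes are stored; this is the
    information typically available from a published report when individual
    patient data are not.
    """

    auc_hat: float
    n0: int
    n1: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_hat <= 1.0:
            raise ValueError(f"auc_hat must lie in [0, 1], got {self.auc_hat}")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("each group needs at least one observation")

    @property
    def n(self) -> int:
        return self.n0 + self.n1


@dataclass(frozen=True)
class VarianceEstimates:
    """The three nonparametric variance quantities used by the intervals."""

    se_empirical: float
    se_bamber: float
    var_max: float


@dataclass(frozen=True)
class BinormalFit:
    """Sample moments and binormal AUC for normally distributed groups."""

    mean0: float
    mean1: float
    sd0: float
    sd1: float
    auc_star: float
    se_star: float


def compute_midranks(sample: MarkerSample) -> RankSummary:
    """Pooled mid-ranks of all ``n`` observations, split back into groups.

    Tied observations share the mean of the rank positions they occupy,
    consistent with the normalized distribution function
    ``F(x) = P(X < x) + 0.5 * P(X = x)``.
    """
    pooled = np.concatenate((sample.values0, sample.values1))
    ranks = stats.rankdata(pooled, method="average")
    return RankSummary(midranks0=ranks[: sample.n0], midranks1=ranks[sample.n0:])


def estimate_auc(sample: MarkerSample) -> SummaryAUC:
    """Mann-Whitney estimate of the AUC from pooled mid-ranks.

    Equals the pairwise count ``(#{X1 > X0} + 0.5 * #{X1 = X0}) / (n0 * n1)``;
    the rank form is O(n log n).
    """
    ranks = compute_midranks(sample)
    auc = (ranks.rbar1 - ranks.rbar0) / sample.n + 0.5
    # guard against floating noise at the boundaries
    auc = min(1.0, max(0.0, auc))
    return SummaryAUC(auc_hat=auc, n0=sample.n0, n1=sample.n1)


def placement_values(sample: MarkerSample) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation placement values ``(cases, controls)``.

    The placement of a case is the fraction of controls it exceeds (ties
    half-weighted); the placement of a control is the fraction of cases
    exceeding it.  Both vectors average to the estimated AUC.
    """
    s0 = np.sort(sample.values0)
    s1 = np.sort(sample.values1)
    lo = np.searchsorted(s0, sample.values1, side="left")
    hi = np.searchsorted(s0, sample.values1, side="right")
    cases = (lo + 0.5 * (hi - lo)) / sample.n0
    lo0 = np.searchsorted(s1, sample.values0, side="left")
    hi0 = np.searchsorted(s1, sample.values0, side="right")
    controls = ((sample.n1 - hi0) + 0.5 * (hi0 - lo0)) / sample.n1
    return cases, controls


def _require_variance_sizes(sample: MarkerSample) -> None:
    if sample.n0 < 2 or sample.n1 < 2:
        raise ValueError(
            "variance estimation needs at least 2 observations per group "
            f"(got n0={sample.n0}, n1={sample.n1})"
        )


def se_empirical(sample: MarkerSample) -> float:
    """Placement-based standard error of the estimated AUC.

    ``SE^2 = S1^2/n1 + S0^2/n0`` with ``S_i^2`` the (n_i - 1)-denominator
    sample variances of the case and control placement vectors.  This is the
    standard structural-component estimator, asymptotically equivalent to the
    rank-based variance of Brunner & Munzel.
    """
    _require_variance_sizes(sample)
    cases, controls = placement_values(sample)
    return float(np.sqrt(cases.var(ddof=1) / sample.n1 + controls.var(ddof=1) / sample.n0))


def var_bamber(sample: MarkerSample) -> float:
    """Bamber's distribution-free, unbiased variance estimate of the AUC.

    The exact variance of the Mann-Whitney estimate is
    ``[Var(w) + (n1-1)(Q1 - A^2) + (n0-1)(Q2 - A^2)] / (n0 n1)`` where
    ``w`` is the 0/0.5/1 comparison kernel, ``Q1`` the probability that two
    independent cases both exceed one control and ``Q2`` that one case
    exceeds two independent controls.  Plugging the U-statistic estimates
    ``mean(w^2) - auc_hat^2``, ``Q1_hat - auc_hat^2``, ``Q2_hat - auc_hat^2``
    into the bracket and dividing by ``(n0 - 1)(n1 - 1)`` instead of
    ``n0 n1`` makes the estimator unbiased — the squared-estimate bias of
    each term cancels exactly against the smaller denominator, which is how
    Bamber's estimator is constructed.  (The naive ``/(n0 n1)`` plug-in
    underestimates the variance by the factor ``(n0-1)(n1-1)/(n0 n1)``,
    about 10% at n = 40.)  ``Q1_hat``/``Q2_hat`` are computed in
    O(n log n) from sorted counts and match exhaustive enumeration over all
    case-case-control and case-control-control triples.
    """
    _require_variance_sizes(sample)
    n0, n1 = sample.n0, sample.n1
    s0 = np.sort(sample.values0)
    s1 = np.sort(sample.values1)

    # per case: counts of controls strictly below / tied
    lo = np.searchsorted(s0, sample.values1, side="left")
    hi = np.searchsorted(s0, sample.values1, side="right")
    g_case = lo.astype(float)
    e_case = (hi - lo).astype(float)
    w_case = g_case + 0.5 * e_case          # sum over controls of beat-weights
    sq_case = g_case + 0.25 * e_case        # sum of squared beat-weights

    # per control: counts of cases strictly above / tied
    lo0 = np.searchsorted(s1, sample.values0, side="left")
    hi0 = np.searchsorted(s1, sample.values0, side="right")
    g_ctrl = (n1 - hi0).astype(float)
    e_ctrl = (hi0 - lo0).astype(float)
    w_ctrl = g_ctrl + 0.5 * e_ctrl
    sq_ctrl = g_ctrl + 0.25 * e_ctrl

    auc = float(w_case.sum()) / (n0 * n1)
    mean_w2 = float(sq_case.sum()) / (n0 * n1)  # = auc for tie-free data
    q1 = float(np.sum(w_ctrl**2 - sq_ctrl)) / (n0 * n1 * (n1 - 1))
    q2 = float(np.sum(w_case**2 - sq_case)) / (n1 * n0 * (n0 - 1))
    v = (
        (mean_w2 - auc**2) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / ((n0 - 1) * (n1 - 1))
    return max(v, 0.0)


def var_max(summary: SummaryAUC) -> float:
    """Estimated asymptotic maximum variance of the AUC estimate.

    ``auc_hat * (1 - auc_hat) / (0.75 * n - 1)`` — Bamber's bound for
    continuous markers with monotonic posterior and balanced groups.  This is
    the variance the modified Wald intervals plug in; it needs only the point
    estimate and the total sample size.
    """
    n = summary.n
    if 0.75 * n - 1 <= 0:
        raise ValueError(f"maximum variance requires n >= 2, got n={n}")
    return summary.auc_hat * (1.0 - summary.auc_hat) / (0.75 * n - 1.0)


def variance_estimates(sample: MarkerSample) -> VarianceEstimates:
    """Convenience bundle of all three variance quantities for a sample."""
    summary = estimate_auc(sample)
    return VarianceEstimates(
        se_empirical=se_empirical(sample),
        se_bamber=float(np.sqrt(var_bamber(sample))),
        var_max=var_max(summary),
    )


def fit_binormal(sample: MarkerSample) -> BinormalFit:
    """Binormal AUC ``Phi((xbar1 - xbar0) / sqrt(s0^2 + s1^2))`` with a
    delta-method standard error.

    Assumes ``X0 ~ N(mu0, sigma0^2)`` and ``X1 ~ N(mu1, sigma1^2)``.  Writing
    ``delta = (xbar1 - xbar0)/tau`` with ``tau^2 = s0^2 + s1^2``, first-order
    propagation of the sampling variances of the group means and variances
    (under normality, ``Var(s_i^2) = 2 sigma_i^4/(n_i - 1)``) gives

    ``Var(delta) ~= (s0^2/n0 + s1^2/n1)/tau^2
                    + delta^2/(2 tau^4) * (s0^4/(n0-1) + s1^4/(n1-1))``

    and ``se_star = phi(delta) * sqrt(Var(delta))``.
    """
    _require_variance_sizes(sample)
    n0, n1 = sample.n0, sample.n1
    m0 = float(sample.values0.mean())
    m1 = float(sample.values1.mean())
    s0 = float(sample.values0.std(ddof=1))
    s1 = float(sample.values1.std(ddof=1))
    tau2 = s0**2 + s1**2
    if tau2 <= 0:
        raise ValueError("binormal fit is degenerate: both groups have zero variance")
    delta = (m1 - m0) / np.sqrt(tau2)
    var_delta = (s0**2 / n0 + s1**2 / n1) / tau2 + (
        delta**2 / (2.0 * tau2**2)
    ) * (s0**4 / (n0 - 1) + s1**4 / (n1 - 1))
    return BinormalFit(
        mean0=m0,
        mean1=m1,
        sd0=s0,
        sd1=s1,
        auc_star=float(stats.norm.cdf(delta)),
        se_star=float(stats.norm.pdf(delta) * np.sqrt(var_delta)),
    )
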