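"""Ten two-sided confidence intervals for the AUC.

Four intervals need individual patient data (LT, M-W, Bamber, binormal);
the six others (Wilson with/without continuity correction, Agresti-Coull,
Clopper-Pearson, and the modified Wald with/without continuity correction)
treat the AUC as a single proportion with "sample size" ``n = n0 + n1`` and
can be built from published summary information alone.

The modified Wald interval is ``auc_hat +/- z * sqrt(var_max)`` with
``var_max = auc_hat(1 - auc_hat)/(0.75 n - 1)``, Bamber's asymptotic maximum
variance for continuous markers; the continuity-corrected version widens each
side by ``1/(2n)``.

Every constructor returns a :class:`ConfidenceInterval` carrying
computability and range-preservation metadata mirroring the methods'
analytic properties (e.g. LT, M-W, binormal, Agresti-Coull, Clopper-Pearson
and the uncorrected Wald interval break down at ``auc_hat = 1``).  Raw
limits may leave ``[0, 1]`` for the non-range-preserving methods;
:func:`report_interval` applies the reporting rule that truncates the upper
limit to 1.

The private ``*_limits`` kernels are vectorized over numpy arrays and are
shared with the Monte-Carlo engine in :mod:`aucci.sim`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .core import BinormalFit, SummaryAUC

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "DATA_ONLY_METHODS",
    "SUMMARY_METHODS",
    "RANGE_PRESERVING",
    "COMPUTABLE_AT_AUC_ONE",
    "DISPLAY_NAMES",
    "ConfidenceInterval",
    "ci_lt",
    "ci_mw",
    "ci_bamber",
    "ci_binormal",
    "ci_proportion",
    "ci_modified_wald",
    "report_interval",
    "intervals_from_sample",
    "intervals_from_summary",
]

METHODS: tuple[str, ...] = (
    "lt",
    "mw",
    "bamber",
    "binormal",
    "wilson",
    "wilson_cc",
    "agresti_coull",
    "clopper_pearson",
    "wald",
    "wald_cc",
)

#: methods that require individual patient data
DATA_ONLY_METHODS = frozenset({"lt", "mw", "bamber", "binormal"})
#: methods computable from (auc_hat, n) alone
SUMMARY_METHODS = frozenset(METHODS) - DATA_ONLY_METHODS
#: both limits always inside [0, 1]
RANGE_PRESERVING = frozenset({"lt", "wilson", "wilson_cc", "clopper_pearson"})
#: methods that still yield a usable interval when auc_hat = 1
COMPUTABLE_AT_AUC_ONE = frozenset({"bamber", "wilson", "wilson_cc", "wald_cc"})

DISPLAY_NAMES = {
    "lt": "LT",
    "mw": "M-W",
    "bamber": "Bamber",
    "binormal": "Binormal",
    "wilson": "Wilson",
    "wilson_cc": "Wilson-cc",
    "agresti_coull": "A-C",
    "clopper_pearson": "C-P",
    "wald": "Wald",
    "wald_cc": "Wald-cc",
}


@dataclass(frozen=True)
class ConfidenceInterval:
    method: str
    lower: float
    upper: float
    alpha: float
    computable: bool = True
    clipped: bool = False

    @property
    def range_preserving(self) -> bool:
        return self.method in RANGE_PRESERVING

    @property
    def length(self) -> float:
        if not self.computable:
            return float("nan")
        return self.upper - self.lower

    def to_record(self) -> dict:
        """Flat record for serialization (CSV / JSON rows)."""
        return {
            "method": self.method,
            "lower": self.lower,
            "upper": self.upper,
            "length": self.length,
            "alpha": self.alpha,
            "computable": self.computable,
            "clipped": self.clipped,
        }


def _zq(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


# ---------------------------------------------------------------------------
# vectorized limit kernels (shared with aucci.sim)
# ---------------------------------------------------------------------------

def lt_limits(auc, se, z):
    """Logit-transformed Mann-Whitney limits; valid only for 0 < auc < 1."""
    auc = np.asarray(auc, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        half = z * se / (auc * (1.0 - auc))
        center = logit(auc)
        return expit(center - half), expit(center + half)


def mw_limits(auc, se, z):
    auc = np.asarray(auc, dtype=float)
    half = z * np.asarray(se, dtype=float)
    return auc - half, auc + half


def bamber_limits(auc, var_b, z):
    auc = np.asarray(auc, dtype=float)
    half = z * np.sqrt(np.asarray(var_b, dtype=float))
    return auc - half, auc + half


def wald_limits(auc, n, z, continuity=False):
    """Modified Wald limits using the maximum variance auc(1-auc)/(0.75n-1)."""
    auc = np.asarray(auc, dtype=float)
    half = z * np.sqrt(auc * (1.0 - auc) / (0.75 * n - 1.0))
    if continuity:
        half = half + 1.0 / (2.0 * n)
    return auc - half, auc + half


def wilson_limits(auc, n, z):
    auc = np.asarray(auc, dtype=float)
    t = z * z / n
    root = np.sqrt(auc * (1.0 - auc) * t + t * t / 4.0)
    return (auc + t / 2.0 - root) / (1.0 + t), (auc + t / 2.0 + root) / (1.0 + t)


def wilson_cc_limits(auc, n, z):
    """Continuity-corrected Wilson score limits, truncated into [0, 1]."""
    auc = np.asarray(auc, dtype=float)
    z2 = z * z
    denom = 2.0 * (n + z2)
    with np.errstate(invalid="ignore"):
        lo = (
            2.0 * n * auc + z2 - 1.0
            - z * np.sqrt(z2 - 2.0 - 1.0 / n + 4.0 * auc * (n * (1.0 - auc) + 1.0))
        ) / denom
        up = (
            2.0 * n * auc + z2 + 1.0
            + z * np.sqrt(z2 + 2.0 - 1.0 / n + 4.0 * auc * (n * (1.0 - auc) - 1.0))
        ) / denom
    # the corrected radicand can go (slightly) negative at the boundaries;
    # the score interval is degenerate there and the limits clamp to [0, 1]
    lo = np.nan_to_num(lo, nan=0.0)
    up = np.nan_to_num(up, nan=1.0)
    return np.clip(lo, 0.0, 1.0), np.clip(up, 0.0, 1.0)


def agresti_coull_limits(auc, n, z):
    auc = np.asarray(auc, dtype=float)
    shifted = (auc * n + 2.0) / (n + 4.0)
    half = z * np.sqrt(shifted * (1.0 - shifted) / (n + 4.0))
    return shifted - half, shifted + half


def success_count(auc, n):
    """``k = round(auc_hat * n)``, rounding halves away from zero."""
    auc = np.asarray(auc, dtype=float)
    return np.floor(auc * n + 0.5).astype(int)


def clopper_pearson_limits(k, n, alpha):
    """Exact (F-quantile form) limits for k successes out of n.

    Lower limit is 0 at k = 0; at k = n the interval is undefined (NaN) —
    callers flag those runs as non-computable.
    """
    k = np.asarray(k, dtype=int)
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    lo = np.zeros(k.shape)
    up = np.full(k.shape, np.nan)
    pos = k > 0
    if np.any(pos):
        kk = k[pos].astype(float)
        f_lo = stats.f.ppf(alpha / 2.0, 2.0 * kk, 2.0 * (n - kk + 1.0))
        lo[pos] = kk * f_lo / (n - kk + 1.0 + kk * f_lo)
    ok = k < n
    if np.any(ok):
        kk = k[ok].astype(float)
        f_up = stats.f.ppf(1.0 - alpha / 2.0, 2.0 * (kk + 1.0), 2.0 * (n - kk))
        up[ok] = (kk + 1.0) * f_up / (n - kk + (kk + 1.0) * f_up)
    if scalar:
        return float(lo[0]), float(up[0])
    return lo, up


def binormal_limits(auc_star, se_star, z):
    auc_star = np.asarray(auc_star, dtype=float)
    half = z * np.asarray(se_star, dtype=float)
    return auc_star - half, auc_star + half


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def _not_computable(method: str, alpha: float, lower=float("nan"), upper=float("nan")):
    return ConfidenceInterval(
        method=method, lower=lower, upper=upper, alpha=alpha, computable=False
    )


def ci_lt(summary: SummaryAUC, se: float, alpha: float = 0.05) -> ConfidenceInterval:
    """Mann-Whitney interval with logit transformation (LT).

    ``expit(logit(auc_hat) +/- z * se / (auc_hat (1 - auc_hat)))`` — always
    range-preserving, but undefined when ``auc_hat`` is 0 or 1.
    """
    z = _zq(alpha)
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if summary.auc_hat in (0.0, 1.0):
        return _not_computable("lt", alpha)
    lo, up = lt_limits(summary.auc_hat, se, z)
    return ConfidenceInterval("lt", float(lo), float(up), alpha)


def ci_mw(summary: SummaryAUC, se: float, alpha: float = 0.05) -> ConfidenceInterval:
    """Untransformed Mann-Whitney (normal-approximation) interval."""
    z = _zq(alpha)
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if summary.auc_hat == 1.0:
        return _not_computable("mw", alpha, lower=1.0, upper=1.0)
    lo, up = mw_limits(summary.auc_hat, se, z)
    return ConfidenceInterval("mw", float(lo), float(up), alpha)


def ci_bamber(summary: SummaryAUC, var_b: float, alpha: float = 0.05) -> ConfidenceInterval:
    """Bamber's interval ``auc_hat +/- z * sqrt(var_b)``; defined at auc_hat = 1."""
    z = _zq(alpha)
    if var_b < 0:
        raise ValueError("variance must be nonnegative")
    lo, up = bamber_limits(summary.auc_hat, var_b, z)
    return ConfidenceInterval("bamber", float(lo), float(up), alpha)


def ci_binormal(fit: BinormalFit, alpha: float = 0.05) -> ConfidenceInterval:
    """Wald interval around the binormal AUC with its delta-method SE."""
    z = _zq(alpha)
    if not np.isfinite(fit.auc_star) or not np.isfinite(fit.se_star):
        return _not_computable("binormal", alpha)
    lo, up = binormal_limits(fit.auc_star, fit.se_star, z)
    return ConfidenceInterval("binormal", float(lo), float(up), alpha)


def ci_proportion(
    summary: SummaryAUC, method: str, alpha: float = 0.05
) -> ConfidenceInterval:
    """Single-proportion interval for the AUC with ``n = n0 + n1`` "trials".

    ``method`` is one of ``wilson``, ``wilson_cc``, ``agresti_coull``,
    ``clopper_pearson``.  Clopper-Pearson uses the estimated success count
    ``k = round(auc_hat * n)`` and is undefined at ``k = n``; Agresti-Coull is
    treated as unavailable at ``auc_hat = 1``.
    """
    z = _zq(alpha)
    auc, n = summary.auc_hat, summary.n
    if method == "wilson":
        lo, up = wilson_limits(auc, n, z)
    elif method == "wilson_cc":
        lo, up = wilson_cc_limits(auc, n, z)
    elif method == "agresti_coull":
        if auc == 1.0:
            return _not_computable("agresti_coull", alpha)
        lo, up = agresti_coull_limits(auc, n, z)
    elif method == "clopper_pearson":
        k = int(success_count(auc, n))
        if k == n:
            return _not_computable("clopper_pearson", alpha)
        lo, up = clopper_pearson_limits(k, n, alpha)
    else:
        raise ValueError(f"unknown proportion method {method!r}")
    return ConfidenceInterval(method, float(lo), float(up), alpha)


def ci_modified_wald(
    summary: SummaryAUC, continuity: bool = False, alpha: float = 0.05
) -> ConfidenceInterval:
    """The modified Wald interval ``auc_hat +/- z * sqrt(var_max) [+ 1/(2n)]``.

    Without the continuity correction the interval degenerates to ``[1, 1]``
    at ``auc_hat = 1`` and is flagged non-computable there; with the
    correction it stays usable for every estimate.
    """
    z = _zq(alpha)
    n = summary.n
    if 0.75 * n - 1 <= 0:
        raise ValueError(f"modified Wald interval requires n >= 2, got n={n}")
    method = "wald_cc" if continuity else "wald"
    if summary.auc_hat == 1.0 and not continuity:
        return _not_computable("wald", alpha, lower=1.0, upper=1.0)
    lo, up = wald_limits(summary.auc_hat, n, z, continuity=continuity)
    return ConfidenceInterval(method, float(lo), float(up), alpha)


def report_interval(ci: ConfidenceInterval) -> ConfidenceInterval:
    """Apply the reporting rule: truncate the upper limit to 1.

    Only the upper limit is clipped (the scenarios of interest have AUC well
    above 0.5, so lower limits below 0 do not arise; if one ever does it is
    logged and left untouched).
    """
    if not ci.computable:
        raise ValueError(f"cannot report a non-computable {ci.method} interval")
    if ci.lower < 0.0:
        logger.warning(
            "%s interval lower limit %.4f is below 0 and was not truncated",
            ci.method,
            ci.lower,
        )
    if ci.upper > 1.0:
        return replace(ci, upper=1.0, clipped=True)
    return ci


# ---------------------------------------------------------------------------
# batch construction helpers
# ---------------------------------------------------------------------------

def intervals_from_sample(sample, methods=None, alpha: float = 0.05):
    """All (or selected) intervals from individual-level data.

    Returns a list of reported (upper-clipped) :class:`ConfidenceInterval`,
    in canonical method order.  Non-computable results are passed through
    unclipped.
    """
    from . import core  # local import to avoid cycles at module load

    methods = list(METHODS) if methods is None else list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    summary = core.estimate_auc(sample)
    out = []
    for method in METHODS:
        if method not in methods:
            continue
        if method == "lt":
            ci = ci_lt(summary, core.se_empirical(sample), alpha)
        elif method == "mw":
            ci = ci_mw(summary, core.se_empirical(sample), alpha)
        elif method == "bamber":
            ci = ci_bamber(summary, core.var_bamber(sample), alpha)
        elif method == "binormal":
            ci = ci_binormal(core.fit_binormal(sample), alpha)
        elif method in ("wald", "wald_cc"):
            ci = ci_modified_wald(summary, continuity=(method == "wald_cc"), alpha=alpha)
        else:
            ci = ci_proportion(summary, method, alpha)
        out.append(report_interval(ci) if ci.computable else ci)
    return out


def intervals_from_summary(summary: SummaryAUC, methods=None, alpha: float = 0.05):
    """Summary-mode intervals from ``(auc_hat, n0, n1)`` alone.

    Refuses the data-only methods (LT, M-W, binormal need individual values;
    Bamber's variance estimator does too, despite only ``auc_hat`` appearing
    in its interval formula).
    """
    methods = sorted(SUMMARY_METHODS, key=METHODS.index) if methods is None else list(methods)
    refused = set(methods) & DATA_ONLY_METHODS
    if refused:
        raise ValueError(
            f"method(s) {sorted(refused)} need individual patient data and cannot be "
            "computed from summary information (estimated AUC and group sizes) alone"
        )
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    out = []
    for method in METHODS:
        if method not in methods:
            continue
        if method in ("wald", "wald_cc"):
            ci = ci_modified_wald(summary, continuity=(method == "wald_cc"), alpha=alpha)
        else:
            ci = ci_proportion(summary, method, alpha)
        out.append(report_interval(ci) if ci.computable else ci)
    return out
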