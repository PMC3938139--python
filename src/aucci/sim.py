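"""Monte-Carlo evaluation of the AUC confidence intervals.

The framework reproduces a standard diagnostic case-control design: controls
are drawn ``N(0, sigma0^2)`` and cases ``N(delta, sigma1^2)`` with the shift

    delta = Phi^{-1}(AUC0) * shift_sd,   shift_sd = sqrt(sigma0^2 + sigma1^2)

so the population AUC, ``Phi(delta / sqrt(sigma0^2 + sigma1^2))``, equals the
nominal truth.  (``shift_sd`` can be pinned — e.g. to the homoscedastic
``sqrt(2)`` — for the variance-heterogeneity robustness study, where the
realized AUC then deliberately drifts from the nominal one.)

Coverage is evaluated with *spike averaging*: each nominal ``AUC0`` is run at
``AUC0 - 0.01``, ``AUC0`` and ``AUC0 + 0.01`` and the three coverage /
length estimates are averaged, smoothing the sawtooth behaviour that
discrete statistics produce.  Runs whose interval cannot be computed (e.g.
``auc_hat = 1`` for LT/M-W, ``k = n`` for Clopper-Pearson) are counted in
``n_failed`` and excluded from both coverage and length denominators.

Statistical power of an interval is the fraction of runs, simulated under an
alternative ``AUC1``, whose reported (upper-clipped) interval excludes the
null value ``AUC0``; at ``AUC1 = AUC0`` this estimates the type-I error.

Everything is vectorized across repetitions; a scalar per-sample path
(:func:`simulate_sample` plus :mod:`aucci.intervals`) exists for unit-level
work and serves as the reference the batch path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .core import MarkerSample

__all__ = [
    "ScenarioConfig",
    "PowerConfig",
    "SimulationResult",
    "group_sizes",
    "parse_ratio",
    "simulate_sample",
    "categorize_ordinal",
    "midranks_2d",
    "run_coverage",
    "run_power",
    "power_grid",
    "paper_grid",
    "run_grid",
    "summarize_scenarios",
]

SCALES = ("continuous", "ordinal5")


def parse_ratio(ratio) -> tuple[int, int]:
    """Normalize a case:control ratio given as tuple or ``"1:2"`` string."""
    if isinstance(ratio, str):
        parts = ratio.split(":")
        if len(parts) != 2:
            raise ValueError(f"ratio must look like '1:2', got {ratio!r}")
        ratio = (int(parts[0]), int(parts[1]))
    r1, r0 = int(ratio[0]), int(ratio[1])
    if r1 < 1 or r0 < 1:
        raise ValueError(f"ratio parts must be positive, got {r1}:{r0}")
    return r1, r0


def group_sizes(n: int, ratio) -> tuple[int, int]:
    """Split total ``n`` into ``(n1 cases, n0 controls)`` for a case:control ratio.

    The case count is rounded to the nearest integer (1:2 at n=40 gives
    13 cases / 27 controls); both groups must end up with at least 2.
    """
    r1, r0 = parse_ratio(ratio)
    n1 = int(np.floor(n * r1 / (r1 + r0) + 0.5))
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(f"allocation {r1}:{r0} of n={n} leaves a group below 2 "
                         f"(n1={n1}, n0={n0})")
    return n1, n0


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell.

    ``shift_sd`` pins the scale used in the case shift; ``None`` (default)
    means ``sqrt(sigma0^2 + sigma1^2)``, i.e. the realized AUC equals the
    nominal truth.  ``binormal_reps`` optionally restricts the binormal
    interval to the first k repetitions (mirroring studies that evaluate an
    expensive method on a subset).
    """

    auc0: float
    n: int
    ratio: tuple[int, int] = (1, 1)
    sigma0: float = 1.0
    sigma1: float = 1.0
    scale: str = "continuous"
    reps: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    perturb: bool = True
    shift_sd: float | None = None
    binormal_reps: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", parse_ratio(self.ratio))
        if not 0.0 < self.auc0 < 1.0:
            raise ValueError(f"auc0 must lie in (0, 1), got {self.auc0}")
        if self.perturb and not 0.0 < self.auc0 - 0.01 < 1.0:
            raise ValueError("perturbed truth auc0 - 0.01 leaves (0, 1)")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("group standard deviations must be positive")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        group_sizes(self.n, self.ratio)  # validates n vs ratio

    @property
    def n1(self) -> int:
        return group_sizes(self.n, self.ratio)[0]

    @property
    def n0(self) -> int:
        return group_sizes(self.n, self.ratio)[1]

    @property
    def truths(self) -> tuple[float, ...]:
        if self.perturb:
            return (self.auc0 - 0.01, self.auc0, self.auc0 + 0.01)
        return (self.auc0,)

    def shift(self, truth: float) -> float:
        sd = self.shift_sd
        if sd is None:
            sd = float(np.hypot(self.sigma0, self.sigma1))
        return float(stats.norm.ppf(truth) * sd)


@dataclass(frozen=True)
class PowerConfig:
    """Null value and alternative grid for a power study."""

    auc0: float
    auc1_grid: tuple[float, ...]
    methods: tuple[str, ...] = ("lt", "wald", "wald_cc")

    def __post_init__(self) -> None:
        grid = tuple(float(a) for a in self.auc1_grid)
        if len(grid) == 0:
            raise ValueError("auc1_grid is empty")
        if abs(grid[0] - self.auc0) > 1e-12:
            raise ValueError("auc1_grid must start at auc0 (power at delta 0 "
                             "estimates the type-I error)")
        object.__setattr__(self, "auc1_grid", grid)
        object.__setattr__(self, "methods", tuple(self.methods))


def power_grid(auc0: float, stop: float, step: float = 0.001) -> tuple[float, ...]:
    """Equally spaced alternative grid ``auc0, auc0+step, ..., stop``."""
    count = int(round((stop - auc0) / step)) + 1
    return tuple(np.round(np.linspace(auc0, stop, count), 6))


@dataclass(frozen=True)
class SimulationResult:
    """Per-method coverage summary of one scenario cell."""

    method: str
    coverage: float
    mean_length: float
    n_failed: int
    mc_se: float
    reps: int
    per_truth_coverage: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def simulate_sample(config: ScenarioConfig, truth: float, rng: np.random.Generator) -> MarkerSample:
    """Draw one case-control sample under the scenario at the given truth."""
    if not 0.0 < truth < 1.0:
        raise ValueError(f"truth must lie in (0, 1), got {truth}")
    n1, n0 = group_sizes(config.n, config.ratio)
    x0 = rng.normal(0.0, config.sigma0, size=n0)
    x1 = rng.normal(config.shift(truth), config.sigma1, size=n1)
    sample = MarkerSample(values0=x0, values1=x1)
    if config.scale == "ordinal5":
        sample = categorize_ordinal(sample)
    return sample


def categorize_ordinal(sample: MarkerSample) -> MarkerSample:
    """Bin a continuous sample into five ordered categories.

    Cut points are the 20/40/60/80th empirical percentiles of the pooled
    sample of that run; values above k cut points land in category k+1.
    """
    pooled = np.concatenate((sample.values0, sample.values1))
    cuts = np.quantile(pooled, (0.2, 0.4, 0.6, 0.8))

    def _cat(values: np.ndarray) -> np.ndarray:
        return 1.0 + (values[:, None] > cuts[None, :]).sum(axis=1)

    return MarkerSample(values0=_cat(sample.values0), values1=_cat(sample.values1))


def _simulate_batch(config: ScenarioConfig, truth: float, reps: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n1, n0 = group_sizes(config.n, config.ratio)
    x0 = rng.normal(0.0, config.sigma0, size=(reps, n0))
    x1 = rng.normal(config.shift(truth), config.sigma1, size=(reps, n1))
    if config.scale == "ordinal5":
        x0, x1 = _categorize_batch(x0, x1)
    return x0, x1


def _categorize_batch(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate((x0, x1), axis=1)
    cuts = np.quantile(pooled, (0.2, 0.4, 0.6, 0.8), axis=1)  # (4, reps)

    def _cat(values: np.ndarray) -> np.ndarray:
        out = np.ones_like(values)
        for row in cuts:
            out += values > row[:, None]
        return out

    return _cat(x0), _cat(x1)


# ---------------------------------------------------------------------------
# vectorized rank statistics
# ---------------------------------------------------------------------------

def midranks_2d(a: np.ndarray) -> np.ndarray:
    """Row-wise mid-ranks (ties share the mean of their rank positions).

    Equivalent to ``scipy.stats.rankdata(a, method="average", axis=1)`` but
    implemented with whole-array accumulations, which is what makes the
    10 000-repetition grids affordable.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError("midranks_2d expects a 2-D array")
    m, n = a.shape
    order = np.argsort(a, axis=1, kind="stable")
    s = np.take_along_axis(a, order, axis=1)
    pos = np.arange(1, n + 1, dtype=float)[None, :]
    starts = np.empty((m, n), dtype=bool)
    starts[:, 0] = True
    np.not_equal(s[:, 1:], s[:, :-1], out=starts[:, 1:])
    first = np.where(starts, pos, 0.0)
    np.maximum.accumulate(first, axis=1, out=first)
    ends = np.empty((m, n), dtype=bool)
    ends[:, -1] = True
    ends[:, :-1] = starts[:, 1:]
    last = np.where(ends, pos, np.inf)[:, ::-1]
    last = np.minimum.accumulate(last, axis=1)[:, ::-1]
    mid_sorted = 0.5 * (first + last)
    out = np.empty((m, n), dtype=float)
    np.put_along_axis(out, order, mid_sorted, axis=1)
    return out


def _batch_rank_stats(x0: np.ndarray, x1: np.ndarray, want_se: bool):
    """Per-repetition AUC estimate and (optionally) the placement SE."""
    n0, n1 = x0.shape[1], x1.shape[1]
    n = n0 + n1
    pooled_ranks = midranks_2d(np.concatenate((x0, x1), axis=1))
    r0 = pooled_ranks[:, :n0]
    r1 = pooled_ranks[:, n0:]
    auc = (r1.mean(axis=1) - r0.mean(axis=1)) / n + 0.5
    np.clip(auc, 0.0, 1.0, out=auc)
    if not want_se:
        return auc, None
    # placement values via the rank identity: pooled midrank minus
    # within-group midrank counts the opposite group (ties half-weighted)
    v1 = (r1 - midranks_2d(x1)) / n0          # case placements, mean = auc
    v0 = (r0 - midranks_2d(x0)) / n1          # fraction of cases below each control
    se = np.sqrt(v1.var(axis=1, ddof=1) / n1 + v0.var(axis=1, ddof=1) / n0)
    return auc, se


def _batch_bamber(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-repetition (auc, Bamber variance), chunked to bound memory."""
    reps, n0 = x0.shape
    n1 = x1.shape[1]
    auc = np.empty(reps)
    var = np.empty(reps)
    chunk = max(1, int(2e7 // (n0 * n1)))
    for start in range(0, reps, chunk):
        sl = slice(start, min(start + chunk, reps))
        gt = x1[sl][:, :, None] > x0[sl][:, None, :]      # (c, n1, n0)
        eq = x1[sl][:, :, None] == x0[sl][:, None, :]
        w = gt + 0.5 * eq
        sq = gt + 0.25 * eq
        w_case = w.sum(axis=2)                            # (c, n1)
        w_ctrl = w.sum(axis=1)                            # (c, n0)
        a = w_case.sum(axis=1) / (n0 * n1)
        sq_case = sq.sum(axis=2)
        mean_w2 = sq_case.sum(axis=1) / (n0 * n1)
        q1 = (w_ctrl**2 - sq.sum(axis=1)).sum(axis=1) / (n0 * n1 * (n1 - 1))
        q2 = (w_case**2 - sq_case).sum(axis=1) / (n1 * n0 * (n0 - 1))
        v = (
            (mean_w2 - a**2) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)
        ) / ((n0 - 1) * (n1 - 1))
        auc[sl] = a
        var[sl] = np.maximum(v, 0.0)
    return auc, var


def _batch_binormal(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-repetition binormal AUC and delta-method SE (see core.fit_binormal)."""
    n0, n1 = x0.shape[1], x1.shape[1]
    m0 = x0.mean(axis=1)
    m1 = x1.mean(axis=1)
    v0 = x0.var(axis=1, ddof=1)
    v1 = x1.var(axis=1, ddof=1)
    tau2 = v0 + v1
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (m1 - m0) / np.sqrt(tau2)
        var_delta = (v0 / n0 + v1 / n1) / tau2 + (delta**2 / (2.0 * tau2**2)) * (
            v0**2 / (n0 - 1) + v1**2 / (n1 - 1)
        )
        auc_star = stats.norm.cdf(delta)
        se_star = stats.norm.pdf(delta) * np.sqrt(var_delta)
    return auc_star, se_star


_NEEDS_SE = frozenset({"lt", "mw"})


def _method_limits(method: str, *, z: float, alpha: float, n: int,
                   auc=None, se=None, var_b=None, binorm=None):
    """Vectorized (lower, upper, computable) for one method."""
    if method == "lt":
        lo, up = iv.lt_limits(auc, se, z)
        comp = (auc > 0.0) & (auc < 1.0)
    elif method == "mw":
        lo, up = iv.mw_limits(auc, se, z)
        comp = auc < 1.0
    elif method == "bamber":
        lo, up = iv.bamber_limits(auc, var_b, z)
        comp = np.ones(auc.shape, dtype=bool)
    elif method == "binormal":
        auc_star, se_star = binorm
        lo, up = iv.binormal_limits(auc_star, se_star, z)
        comp = np.isfinite(auc_star) & np.isfinite(se_star)
    elif method == "wilson":
        lo, up = iv.wilson_limits(auc, n, z)
        comp = np.ones(auc.shape, dtype=bool)
    elif method == "wilson_cc":
        lo, up = iv.wilson_cc_limits(auc, n, z)
        comp = np.ones(auc.shape, dtype=bool)
    elif method == "agresti_coull":
        lo, up = iv.agresti_coull_limits(auc, n, z)
        comp = auc < 1.0
    elif method == "clopper_pearson":
        k = iv.success_count(auc, n)
        lo, up = iv.clopper_pearson_limits(k, n, alpha)
        comp = k < n
    elif method == "wald":
        lo, up = iv.wald_limits(auc, n, z)
        comp = auc < 1.0
    elif method == "wald_cc":
        lo, up = iv.wald_limits(auc, n, z, continuity=True)
        comp = np.ones(auc.shape, dtype=bool)
    else:
        raise ValueError(f"unknown method {method!r}")
    return lo, up, comp


def _validate_methods(methods) -> list[str]:
    methods = list(methods)
    unknown = set(methods) - set(iv.METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    return methods


def _batch_stats(x0, x1, methods):
    """Compute only the statistics the requested methods need."""
    want_se = any(m in _NEEDS_SE for m in methods)
    want_bamber = "bamber" in methods
    want_binorm = "binormal" in methods
    if want_bamber and not want_se:
        auc, var_b = _batch_bamber(x0, x1)
        se = None
    else:
        auc, se = _batch_rank_stats(x0, x1, want_se)
        var_b = _batch_bamber(x0, x1)[1] if want_bamber else None
    binorm = _batch_binormal(x0, x1) if want_binorm else None
    return auc, se, var_b, binorm


# ---------------------------------------------------------------------------
# coverage / power drivers
# ---------------------------------------------------------------------------

def run_coverage(config: ScenarioConfig, methods=iv.METHODS) -> dict[str, SimulationResult]:
    """Spike-averaged coverage and mean reported length for one scenario.

    Returns ``{method: SimulationResult}``.  Coverage per truth is the
    fraction of *computable* runs whose reported interval contains that
    truth; the scenario value is the unweighted mean over the (up to three)
    truths.  Identical ``(config, methods)`` always reproduce the same
    result: each truth draws from an independent child stream of
    ``config.seed``.
    """
    methods = _validate_methods(methods)
    z = float(stats.norm.ppf(1.0 - config.alpha / 2.0))
    n = config.n
    truths = config.truths
    streams = np.random.SeedSequence(config.seed).spawn(len(truths))

    cov = {m: [] for m in methods}
    length_sum = {m: 0.0 for m in methods}
    length_n = {m: 0 for m in methods}
    failed = {m: 0 for m in methods}
    chunk_rows = max(256, int(4e6 // max(n, 1)))

    for truth, ss in zip(truths, streams):
        rng = np.random.default_rng(ss)
        covered = {m: 0 for m in methods}
        usable = {m: 0 for m in methods}
        done = 0
        while done < config.reps:
            reps = min(chunk_rows, config.reps - done)
            x0, x1 = _simulate_batch(config, truth, reps, rng)
            auc, se, var_b, binorm = _batch_stats(x0, x1, methods)
            for m in methods:
                lo, up, comp = _method_limits(
                    m, z=z, alpha=config.alpha, n=n,
                    auc=auc, se=se, var_b=var_b, binorm=binorm,
                )
                failed[m] += int(reps - comp.sum())
                use = comp
                if m == "binormal" and config.binormal_reps is not None:
                    # evaluate the binormal interval on the first k reps only;
                    # withheld reps are neither failures nor denominators
                    idx = done + np.arange(reps)
                    use = comp & (idx < config.binormal_reps)
                with np.errstate(invalid="ignore"):
                    hit = use & (lo <= truth) & (truth <= up)
                covered[m] += int(hit.sum())
                usable[m] += int(use.sum())
                rep_up = np.minimum(up, 1.0)
                length_sum[m] += float((rep_up[use] - lo[use]).sum())
                length_n[m] += int(use.sum())
            done += reps
        for m in methods:
            cov[m].append(covered[m] / usable[m] if usable[m] else float("nan"))

    out = {}
    for m in methods:
        per_truth = tuple(cov[m])
        coverage = float(np.mean(per_truth))
        total_usable = length_n[m]
        mc_se = float(np.sqrt(coverage * (1.0 - coverage) / total_usable)) if total_usable else float("nan")
        out[m] = SimulationResult(
            method=m,
            coverage=coverage,
            mean_length=length_sum[m] / total_usable if total_usable else float("nan"),
            n_failed=failed[m],
            mc_se=mc_se,
            reps=config.reps * len(truths),
            per_truth_coverage=per_truth,
        )
    return out


def run_power(config: ScenarioConfig, power: PowerConfig) -> pd.DataFrame:
    """Power curves: P(reported interval excludes ``auc0``) along the grid.

    All methods are evaluated on the same simulated samples (common random
    numbers), so power *differences* between methods carry much less
    Monte-Carlo noise than the individual curves.  Returns a tidy frame with
    columns ``auc1, method, power, n_used, n_failed``.
    """
    methods = _validate_methods(power.methods)
    z = float(stats.norm.ppf(1.0 - config.alpha / 2.0))
    n = config.n
    streams = np.random.SeedSequence(config.seed).spawn(len(power.auc1_grid))
    rows = []
    for auc1, ss in zip(power.auc1_grid, streams):
        rng = np.random.default_rng(ss)
        x0, x1 = _simulate_batch(config, auc1, config.reps, rng)
        auc, se, var_b, binorm = _batch_stats(x0, x1, methods)
        for m in methods:
            lo, up, comp = _method_limits(
                m, z=z, alpha=config.alpha, n=n,
                auc=auc, se=se, var_b=var_b, binorm=binorm,
            )
            rep_up = np.minimum(up, 1.0)
            with np.errstate(invalid="ignore"):
                reject = comp & ((power.auc0 < lo) | (rep_up < power.auc0))
            n_used = int(comp.sum())
            rows.append({
                "auc1": float(auc1),
                "method": m,
                "power": reject.sum() / n_used if n_used else float("nan"),
                "n_used": n_used,
                "n_failed": config.reps - n_used,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario grids and summaries
# ---------------------------------------------------------------------------

def paper_grid(
    *,
    ratio=(1, 1),
    sigma0: float = 1.0,
    sigma1: float = 1.0,
    scale: str = "continuous",
    n_values=(40, 100, 200),
    auc0_values=(0.7, 0.8, 0.9),
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    perturb: bool = True,
    shift_sd: float | None = None,
    binormal_reps: int | None = None,
) -> list[ScenarioConfig]:
    """The standard 9-cell grid: n in {40, 100, 200} x AUC0 in {0.7, 0.8, 0.9}.

    Each cell receives an independent integer seed derived from ``seed``, so
    cells can be run in any order (or subset) with identical results.
    """
    cells = [(n, a) for n in n_values for a in auc0_values]
    seeds = np.random.SeedSequence(seed).generate_state(len(cells)) & 0x7FFFFFFF
    return [
        ScenarioConfig(
            auc0=a, n=n, ratio=ratio, sigma0=sigma0, sigma1=sigma1, scale=scale,
            reps=reps, seed=int(s), alpha=alpha, perturb=perturb,
            shift_sd=shift_sd, binormal_reps=binormal_reps,
        )
        for (n, a), s in zip(cells, seeds)
    ]


def run_grid(configs, methods=iv.METHODS, progress=None) -> pd.DataFrame:
    """Run ``run_coverage`` over scenario cells; tidy one-row-per-cell-method frame."""
    methods = _validate_methods(methods)
    rows = []
    for i, config in enumerate(configs):
        results = run_coverage(config, methods)
        if progress is not None:
            progress(i, config, results)
        for m, res in results.items():
            rows.append({
                "auc0": config.auc0,
                "n": config.n,
                "n1": config.n1,
                "n0": config.n0,
                "ratio": f"{config.ratio[0]}:{config.ratio[1]}",
                "sigma0": config.sigma0,
                "sigma1": config.sigma1,
                "scale": config.scale,
                "reps": config.reps,
                "method": m,
                "coverage": res.coverage,
                "mean_length": res.mean_length,
                "n_failed": res.n_failed,
                "mc_se": res.mc_se,
            })
    return pd.DataFrame(rows)


def summarize_scenarios(results: pd.DataFrame, value: str = "coverage") -> pd.DataFrame:
    """Five-number summary (median, quartiles, min, max) per method.

    Mirrors how grid results are usually displayed as box plots: the median
    and range of a metric across the scenario cells, one row per method.
    """
    grouped = results.groupby("method")[value]
    out = grouped.agg(
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
        min="min",
        max="max",
        n_cells="count",
    )
    return out.reset_index()
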