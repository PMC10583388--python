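"""Statistical layer: dose/intensity fits, group tests, detection
threshold, and the Q°–TNF power-model regression.

Standard procedures are delegated to scipy (OLS/Pearson via linregress,
Student t tests, one-way ANOVA, Tukey HSD, nonlinear least squares);
the procedures specific to this analysis — the saline-referenced detection
threshold, the power-law biomarker fit with original-scale R², and exact
small-sample Spearman p-values — are implemented here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import AnalysisError, ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class PowerFitResult:
    """TNF = a·Q°^b (or the fixed-exponent variant), with original-scale R²."""

    a: float
    b: float
    r_squared: float
    spearman_rho: float
    spearman_p: float
    n: int
    model: str = "power"


@dataclass
class GroupTestResult:
    test: str                      # paired_t | unpaired_t | anova_tukey
    statistic: float
    p_value: float
    group_means: list[float] = field(default_factory=list)
    group_sems: list[float] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)  # pairwise adjusted p's


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise AnalysisError("non-finite values in input")


def linear_fit(x, y) -> LinearFitResult:
    """Ordinary least squares with Pearson r and its two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AnalysisError(f"need matched x/y with n >= 3, got n = {x.size}")
    _check_finite(x, y)
    if np.ptp(x) == 0:
        raise AnalysisError("zero variance in x: no regression possible")
    res = stats.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def _sem(a: np.ndarray) -> float:
    return float(np.std(a, ddof=1) / np.sqrt(a.size))


def two_group_test(a, b, paired: bool = False) -> GroupTestResult:
    """Two-tailed Student t test (paired on differences; unpaired pooled)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, b)
    if paired:
        if a.size != b.size:
            raise AnalysisError("paired test requires equal-length matched vectors")
        if a.size < 2:
            raise AnalysisError("need n >= 2 pairs")
        t, p = stats.ttest_rel(a, b)
        name = "paired_t"
    else:
        if min(a.size, b.size) < 2:
            raise AnalysisError("need n >= 2 per group")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        name = "unpaired_t"
    return GroupTestResult(
        test=name,
        statistic=float(t),
        p_value=float(p),
        group_means=[float(np.mean(a)), float(np.mean(b))],
        group_sems=[_sem(a), _sem(b)],
    )


def anova_multcomp(groups: list, labels: list[str] | None = None,
                   method: str = "tukey") -> GroupTestResult:
    """One-way ANOVA with all-pairs multiple comparisons.

    ``method`` is ``"tukey"`` (Tukey HSD, default) or ``"holm"``
    (Holm-adjusted pairwise unpaired t tests).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise AnalysisError("need at least 3 groups for ANOVA with comparisons")
    if any(g.size < 2 for g in arrays):
        raise AnalysisError("every group needs n >= 2")
    for g in arrays:
        _check_finite(g)
    labels = labels or [f"g{i + 1}" for i in range(len(arrays))]
    f, p = stats.f_oneway(*arrays)

    comparisons: list[dict] = []
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    if method == "tukey":
        res = stats.tukey_hsd(*arrays)
        for i, j in pairs:
            comparisons.append(
                {
                    "pair": (labels[i], labels[j]),
                    "p_adjusted": float(res.pvalue[i, j]),
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                }
            )
    elif method == "holm":
        raw = [
            float(stats.ttest_ind(arrays[i], arrays[j], equal_var=True).pvalue)
            for i, j in pairs
        ]
        adj = holm_adjust(raw)
        for (i, j), pa in zip(pairs, adj):
            comparisons.append(
                {
                    "pair": (labels[i], labels[j]),
                    "p_adjusted": float(pa),
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                }
            )
    else:
        raise ConfigurationError(f"unknown multiple-comparison method '{method}'")
    return GroupTestResult(
        test="anova_" + method,
        statistic=float(f),
        p_value=float(p),
        group_means=[float(np.mean(g)) for g in arrays],
        group_sems=[_sem(g) for g in arrays],
        comparisons=comparisons,
    )


def holm_adjust(pvalues: list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def detection_threshold(
    dose_qo: dict[float, list[float]],
    saline_qo: list[float],
    k: float = 3.0,
    zero_variance_floor: float = 0.05,
) -> float | None:
    """Smallest dose whose Q° clears the saline criterion in a majority of
    replicates.

    The criterion is mean(saline Q°) + k·SD(saline Q°); with zero saline
    variance (e.g. a noiseless bank where nothing is detected in saline)
    the criterion falls back to the configured absolute floor (µC).
    Returns ``None`` when no dose qualifies.
    """
    sal = np.asarray(saline_qo, dtype=float)
    if sal.size < 3:
        raise AnalysisError(f"need >= 3 saline replicates, got {sal.size}")
    sd = float(np.std(sal, ddof=1))
    if sd == 0.0 and k > 0:
        logger.info(
            "saline Q° has zero variance; using absolute floor %.3g µC",
            zero_variance_floor,
        )
        criterion = float(np.mean(sal)) + zero_variance_floor
    else:
        criterion = float(np.mean(sal)) + k * sd
    for dose in sorted(dose_qo):
        reps = np.asarray(dose_qo[dose], dtype=float)
        if reps.size == 0:
            continue
        if np.sum(reps > criterion) > reps.size / 2:
            return float(dose)
    return None


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with mid-ranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 10 and the
    usual t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise AnalysisError("need matched x/y with n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise AnalysisError("constant input: Spearman rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 10:
        # Exact two-sided p over all n! rank permutations of y, in chunks.
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        scale = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
        obs = abs(rho)
        count = 0
        total = 0
        perm_iter = itertools.permutations(ry_c)
        while True:
            chunk = np.array(list(itertools.islice(perm_iter, 200_000)))
            if chunk.size == 0:
                break
            r = chunk @ rx_c / scale
            count += int(np.sum(np.abs(r) >= obs - 1e-12))
            total += r.size
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0))


def power_fit(qo, tnf, model: str = "power") -> PowerFitResult:
    """Nonlinear least squares of TNF = a·Q°^b on the original TNF scale.

    ``model`` selects the exponent handling: ``"power"`` fits (a, b) freely,
    ``"power2"`` fixes b = 2 (the two published readings of a "second-order
    power" curve).  Initialization is the log–log OLS line; R² is computed
    on the original TNF scale.  Spearman rho/p accompany the fit because
    the relation is monotone but non-linear.
    """
    x = np.asarray(qo, dtype=float)
    y = np.asarray(tnf, dtype=float)
    if x.size != y.size or x.size < 4:
        raise AnalysisError("need matched Q°/TNF with n >= 4")
    _check_finite(x, y)
    if np.any(x <= 0):
        raise AnalysisError("power model requires Q° > 0 for every fitted row")

    loglog = stats.linregress(np.log(x), np.log(y))
    a0, b0 = float(np.exp(loglog.intercept)), float(loglog.slope)

    if model == "power":
        def f(xv, a, b):
            return a * xv**b
        p0 = (a0, np.clip(b0, -10.0, 10.0))
        bounds = ([0.0, -10.0], [np.inf, 10.0])
    elif model == "power2":
        def f(xv, a):
            return a * xv**2
        p0 = (float(np.mean(y / x**2)),)
        bounds = ([0.0], [np.inf])
    else:
        raise ConfigurationError(f"unknown power-model variant '{model}'")

    try:
        popt, _ = optimize.curve_fit(
            f, x, y, p0=p0, bounds=bounds, method="trf", maxfev=50_000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise AnalysisError(
            f"power fit failed to converge (log-log initializer a={a0:.4g}, "
            f"b={b0:.4g}): {exc}"
        ) from exc
    if model == "power":
        a, b = float(popt[0]), float(popt[1])
    else:
        a, b = float(popt[0]), 2.0
    resid = y - f(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rho, sp = spearman(x, y)
    return PowerFitResult(
        a=a, b=b, r_squared=float(r2), spearman_rho=rho, spearman_p=sp,
        n=int(x.size), model=model,
    )


def variance_explained(fit: PowerFitResult) -> float | None:
    """Percentage of TNF variance explained by the fitted curve
    (100·(1 − SS_res/SS_tot) on the TNF scale); None when SS_tot = 0."""
    if not np.isfinite(fit.r_squared):
        return None
    return 100.0 * fit.r_squared
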