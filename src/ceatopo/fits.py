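"""Linear and sigmoid encoding-model fits with bootstrap comparison.

Stimulus-period activity (dF/F over t = 0-60 s from first hot-plate
contact) is fit per neuron with an ordinary least-squares line and with
a four-parameter logistic ``y(x) = c / (1 + exp(-k*(x - x0))) + y0``.
Model preference is summarized by the change in residual standard
error, ``delta_se = se_lin - se_sig`` (positive favors the sigmoid),
with ``se = sqrt(SSE / (n - p))`` so the sigmoid pays for its two extra
parameters.  Population statistics (slope, R^2, sigmoid k, delta_se)
are bootstrapped by resampling neurons 10000 times.

The sigmoid optimizer is multi-start: a data-driven primary start plus
a small grid over k and x0; an optional linear-limit start (tiny k
with c scaled to the OLS slope) makes the logistic family effectively
nest the line, guaranteeing r2_sig >= r2_lin up to optimizer tolerance
when enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import sigmoid


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float
    se: float  # residual standard error, sqrt(SSE / (n - 2))
    n: int


@dataclass(frozen=True)
class SigmoidFit:
    c: float
    k: float
    x0: float
    y0: float
    r2: float
    se: float  # residual standard error, sqrt(SSE / (n - 4))
    converged: bool
    n: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return sigmoid(t, self.c, self.k, self.x0, self.y0)


@dataclass(frozen=True)
class ModelComparison:
    delta_r2: float  # r2_sig - r2_lin
    delta_se: float  # se_lin - se_sig; positive favors the sigmoid


def fit_linear(t: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS line with two-sided p for a non-zero slope.

    Degenerate constant input yields slope 0 with r2 defined as 0.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(t) == 0:
        raise ValueError("singular design: constant time axis")
    if np.ptp(y) == 0:
        return LinearFit(0.0, float(y[0]), 0.0, 1.0, 0.0, t.size)
    fit = stats.linregress(t, y)
    resid = y - (fit.slope * t + fit.intercept)
    se = float(np.sqrt((resid**2).sum() / (t.size - 2)))
    return LinearFit(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue), se, t.size
    )


def _sigmoid_jac(x: np.ndarray, c: float, k: float, x0: float, y0: float) -> np.ndarray:
    z = np.clip(-k * (x - x0), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    sp = s * (1.0 - s)
    return np.column_stack((s, c * sp * (x - x0), -c * k * sp, np.ones_like(x)))


def _sigmoid_starts(
    t: np.ndarray, y: np.ndarray, include_linear_limit: bool
) -> list[tuple[float, float, float, float]]:
    span = float(np.ptp(t))
    rng_y = float(np.ptp(y))
    y0 = float(np.min(y))
    mid = float(t.min() + span / 2.0)
    starts = []
    if include_linear_limit:
        # k -> 0 with c*k/4 matching the OLS slope makes the logistic
        # reproduce the best-fit line, so the families strictly nest
        lin = stats.linregress(t, y) if np.ptp(y) > 0 else None
        if lin is not None and lin.slope != 0:
            k0 = 1e-5
            c0 = 4.0 * lin.slope / k0
            y_mid = lin.slope * mid + lin.intercept
            starts.append((c0, k0, mid, y_mid - c0 / 2.0))
    starts.append((rng_y if rng_y > 0 else 1.0, 4.0 / span, mid, y0))
    quartiles = np.quantile(t, [0.25, 0.5, 0.75])
    for k in (0.02, 0.1, 0.5):
        for x0 in quartiles:
            starts.append((rng_y if rng_y > 0 else 1.0, k, float(x0), y0))
    return starts


def fit_sigmoid(
    t: np.ndarray, y: np.ndarray, include_linear_limit: bool = False
) -> SigmoidFit:
    """Least-squares four-parameter logistic with multi-start fallback.

    Starts: a data-driven primary (c = range(y), y0 = min(y), x0 at the
    window midpoint, k = 4/window) plus a grid over k in {0.02, 0.1,
    0.5} 1/s and x0 at the time quartiles.  With
    ``include_linear_limit=True`` an extra tiny-k start scaled to the
    OLS slope is prepended, which makes the logistic family effectively
    nest the straight line (guaranteeing r2_sig >= r2_lin up to
    optimizer tolerance) at the cost of letting the sigmoid chase noise
    on truly linear data.

    Bounds: c and y0 free-signed, k > 0, x0 within the time window
    padded by 30 s (prevents the mirror-symmetric duplicate optimum at
    c < 0, k < 0).  The best converged start by SSE wins; if no start
    converges the fit is flagged and should be excluded from population
    summaries.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need >= 5 points")
    if np.ptp(y) == 0:
        # constant data: exactly reproduced by c=0, y0=mean
        return SigmoidFit(0.0, 1.0, float(t.mean()), float(y[0]), 0.0, 0.0, True, t.size)
    lb = [-np.inf, 1e-6, t.min() - 30.0, -np.inf]
    ub = [np.inf, np.inf, t.max() + 30.0, np.inf]
    sst = float(((y - y.mean()) ** 2).sum())
    best: tuple[float, np.ndarray] | None = None
    for p0 in _sigmoid_starts(t, y, include_linear_limit):
        p0 = np.clip(p0, lb, ub)
        # the start itself is a candidate: on ridge-degenerate data the
        # optimizer can wander to non-finite parameters
        sse0 = float(((y - sigmoid(t, *p0)) ** 2).sum())
        if np.isfinite(sse0) and (best is None or sse0 < best[0]):
            best = (sse0, np.asarray(p0, dtype=float))
        if best is not None and best[0] <= 1e-9 * sst:
            break  # essentially perfect; optimizing further cannot help
        try:
            popt, _ = optimize.curve_fit(
                sigmoid,
                t,
                y,
                p0=p0,
                bounds=(lb, ub),
                jac=_sigmoid_jac,
                x_scale="jac",
                maxfev=5000,
                method="trf",
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(((y - sigmoid(t, *popt)) ** 2).sum())
        if np.isfinite(sse) and np.isfinite(popt).all() and (best is None or sse < best[0]):
            best = (sse, popt)
        if best is not None and best[0] <= 1e-9 * sst:
            break
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, t.size)
    sse, popt = best
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    se = float(np.sqrt(sse / max(t.size - 4, 1)))
    return SigmoidFit(*(float(v) for v in popt), r2=r2, se=se, converged=True, n=t.size)


def compare_models(lin: LinearFit, sig: SigmoidFit) -> ModelComparison:
    """Goodness-of-fit change when switching from the line to the sigmoid."""
    if lin.n != sig.n:
        raise ValueError("fits were computed on different data lengths")
    return ModelComparison(delta_r2=sig.r2 - lin.r2, delta_se=lin.se - sig.se)


@dataclass(frozen=True)
class BootstrapDistribution:
    """Neuron-resampling bootstrap of a population-mean statistic."""

    statistic: str  # "slope" | "r2" | "k" | "delta_se"
    samples: np.ndarray
    mean: float
    sd: float
    n_boot: int
    seed: int


def bootstrap_population_stat(
    per_neuron_values: np.ndarray,
    statistic: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapDistribution:
    """Bootstrap the population mean of a per-neuron fit statistic.

    The resampling unit is the neuron; each of ``n_boot`` resamples
    records the mean over a with-replacement draw of the neurons.
    Non-finite values (e.g. from non-converged fits) are excluded.
    """
    vals = np.asarray(per_neuron_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >= 2 finite per-neuron values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    samples = vals[idx].mean(axis=1)
    return BootstrapDistribution(
        statistic=statistic,
        samples=samples,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=0)),
        n_boot=n_boot,
        seed=seed,
    )


def compare_population_fits(
    a: BootstrapDistribution, b: BootstrapDistribution
) -> tuple[float, float]:
    """Two-sided unpaired t-test on two bootstrap sample sets.

    Reproduces the bootstrapped-distribution comparison used for
    population goodness-of-fit contrasts.  Note the calibration caveat:
    n_boot inflates the degrees of freedom, so this test is
    anticonservative by construction; see
    :func:`bootstrap_difference_ci` for a percentile-CI alternative.
    """
    if a.statistic != b.statistic:
        raise ValueError(f"mismatched statistics: {a.statistic!r} vs {b.statistic!r}")
    if a.n_boot != b.n_boot:
        raise ValueError("bootstrap distributions have different n_boot")
    if np.array_equal(a.samples, b.samples):
        return 0.0, 1.0
    res = stats.ttest_ind(a.samples, b.samples)
    return float(res.statistic), float(res.pvalue)


def bootstrap_difference_ci(
    a: BootstrapDistribution, b: BootstrapDistribution, level: float = 0.95
) -> tuple[float, float]:
    """Percentile CI for the difference of two bootstrap distributions.

    An extension beyond the t-test route: the (1-level)/2 and
    1-(1-level)/2 percentiles of pairwise differences of the two sample
    sets.  Better calibrated than a t-test across bootstrap replicates.
    """
    if a.statistic != b.statistic:
        raise ValueError("mismatched statistics")
    diff = a.samples - b.samples if a.samples.size == b.samples.size else None
    if diff is None:
        raise ValueError("bootstrap distributions have different sizes")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(diff, [tail, 1.0 - tail])
    return float(lo), float(hi)
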