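"""Growth-rate inference from plate-reader OD600 time series.

The primary fit is a logistic curve in log2-OD space,

    y(t) = baseline + amplitude / (1 + exp(-k (t - t_m))),   y = log2(OD - blank),

whose maximum slope gamma = amplitude*k/4 is the growth rate in doublings/hour
and whose lag is the intercept of the max-slope tangent with the baseline,
lag = t_m - 2/k. Uncertainty is a Laplace approximation around the weighted
least-squares optimum (flat priors): parameter draws come from a multivariate
normal with the fit covariance, and gamma is recomputed per draw. Rate ratios
between strains and their CIs are computed over paired posterior draws.

Alternative estimators provided: windowed log-linear regression ("effective"
rate), pooled early-exponential regression with per-well intercepts, and a
GCV smoothing-spline fit (max derivative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline

_SAT_LEVEL = 0.95  # fraction of amplitude defining time-to-saturation


class GrowthFitError(RuntimeError):
    """Raised when the growth model cannot be fit; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class GrowthCurve:
    """One well's OD600 time series. Times in hours, strictly increasing."""

    well_id: str
    times: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def log2_od(self) -> np.ndarray:
        """log2(od - blank), flooring non-positive values to half the smallest positive."""
        v = self.od - self.blank
        pos = v[v > 0]
        if len(pos) == 0:
            raise GrowthFitError("no OD readings above blank", {"well": self.well_id})
        floor = 0.5 * pos.min()
        return np.log2(np.maximum(v, floor))


@dataclass
class GrowthFit:
    """Fitted growth parameters plus (optionally) posterior draws."""

    gamma: float
    lag: float
    amplitude: float
    baseline: float
    covariance: np.ndarray | None = None
    params: np.ndarray | None = None  # (baseline, amplitude, k, t_m)
    posterior_samples: np.ndarray | None = None  # n x 4 parameter draws
    gamma_samples: np.ndarray | None = None
    fit_method: str = "model"
    no_growth: bool = False
    residual_sd: float = float("nan")
    n_points: int = 0
    flags: list[str] = field(default_factory=list)

    def gamma_ci(self, level: float = 0.95) -> tuple[float, float]:
        if self.gamma_samples is None:
            raise ValueError("sample the posterior first (sample_posterior)")
        lo, hi = np.percentile(self.gamma_samples, [50 * (1 - level), 50 * (1 + level)])
        return float(lo), float(hi)


@dataclass
class RateRatio:
    """Ratio of two strains' growth rates with a paired-draw CI."""

    gamma_ratio: float
    ci_low: float
    ci_high: float
    n_samples: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.gamma_ratio <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _logistic(t, baseline, amplitude, k, tm):
    return baseline + amplitude / (1.0 + np.exp(-np.clip(k * (t - tm), -500, 500)))


def _gamma_of(amplitude, k):
    return amplitude * k / 4.0


def _logistic_od(t, baseline, amplitude, k, tm):
    return 2.0 ** _logistic(t, baseline, amplitude, k, tm)


def fit_growth_model(curve: GrowthCurve) -> GrowthFit:
    """Least-squares logistic growth fit.

    The growth model is logistic in log2-OD space, but the residuals are
    minimized on the OD scale (od - blank vs 2**y(t)): plate-reader noise is
    approximately constant in OD units, so an unweighted OD-space fit is the
    correctly weighted estimator and avoids the bias a log transform induces
    in near-baseline readings. Returns a ``no_growth`` fit (gamma = 0) for
    flat or monotonically decreasing curves.
    """
    v = curve.od - curve.blank
    usable = int(np.sum(v > 0))
    if usable < 10:
        raise GrowthFitError(
            "need >= 10 usable time points above blank", {"usable": usable, "well": curve.well_id}
        )
    y = curve.log2_od()
    t = curve.times
    span = float(y.max() - y.min())
    trend = np.polyfit(t, y, 1)[0]
    if span < 0.5 or trend < 0:
        return GrowthFit(
            gamma=0.0,
            lag=float("nan"),
            amplitude=0.0,
            baseline=float(np.median(y)),
            fit_method="model",
            no_growth=True,
            n_points=len(t),
        )

    b0 = float(np.percentile(y, 5))
    a0 = span
    dy = np.gradient(_moving_mean(y, 5), t)
    tm0 = float(t[np.argmax(dy)])
    k0 = max(4.0 * float(dy.max()) / a0, 1e-3)
    # bounds keep the sigmoid anchored to the observed data range: a baseline
    # far below the data or an inflection outside the window is a degenerate
    # stretched-exponential solution whose nominal max slope is meaningless
    lower = [y.min() - 2.0, 1e-6, 1e-6, t.min()]
    upper = [y.max(), 1.5 * span + 2.0, 1e3, t.max()]
    p0 = [
        float(np.clip(b0, lower[0], upper[0])),
        float(np.clip(a0, lower[1], upper[1])),
        k0,
        float(np.clip(tm0, lower[3], upper[3])),
    ]
    try:
        popt, pcov = optimize.curve_fit(
            _logistic_od,
            t,
            v,
            p0=p0,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise GrowthFitError(
            "logistic fit did not converge", {"well": curve.well_id, "p0": p0}
        ) from exc
    baseline, amplitude, k, tm = popt
    resid = v - _logistic_od(t, *popt)
    return GrowthFit(
        gamma=float(_gamma_of(amplitude, k)),
        lag=float(tm - 2.0 / k),
        amplitude=float(amplitude),
        baseline=float(baseline),
        covariance=pcov,
        params=np.asarray(popt),
        fit_method="model",
        residual_sd=float(np.std(resid, ddof=4)) if len(t) > 4 else float("nan"),
        n_points=len(t),
    )


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    if len(x) < w:
        return x
    c = np.convolve(x, np.ones(w) / w, mode="same")
    return c


def sample_posterior(fit: GrowthFit, n: int = 10_000, seed: int = 0) -> GrowthFit:
    """Draw n parameter vectors from the Laplace approximation; recompute gamma per draw.

    A non-positive-definite covariance is jittered (flagged) before sampling.
    Degenerate (near-zero) covariance collapses all draws onto the point
    estimate, which is the correct noiseless limit.
    """
    if fit.no_growth:
        fit.posterior_samples = np.tile(
            [fit.baseline, fit.amplitude, 0.0, 0.0], (n, 1)
        )
        fit.gamma_samples = np.zeros(n)
        return fit
    if fit.covariance is None or fit.params is None:
        raise ValueError("fit carries no covariance; refit with fit_growth_model")
    cov = np.asarray(fit.covariance, dtype=float)
    rng = np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(cov + 0.0)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(np.trace(cov) / 4.0, 1e-12)
        chol = np.linalg.cholesky(cov + jitter * np.eye(4))
        fit.flags.append("covariance_jittered")
    draws = fit.params + rng.standard_normal((n, 4)) @ chol.T
    fit.posterior_samples = draws
    fit.gamma_samples = np.maximum(_gamma_of(draws[:, 1], draws[:, 2]), 0.0)
    return fit


def effective_growth_rate(
    curve: GrowthCurve, window: tuple[float, float], n_samples: int = 10_000, seed: int = 0
) -> GrowthFit:
    """Windowed log-linear regression rate (for curves without a clean logistic shape).

    gamma is the OLS slope of log2(od - blank) on time inside the window, in
    doublings/hour; posterior draws are normal around the slope with the
    regression standard error.
    """
    t0, t1 = window
    mask = (curve.times >= t0) & (curve.times <= t1)
    if mask.sum() < 4:
        raise ValueError(f"window [{t0}, {t1}] contains {int(mask.sum())} < 4 points")
    t = curve.times[mask]
    y = curve.log2_od()[mask]
    res = stats.linregress(t, y)
    rng = np.random.default_rng(seed)
    gamma_draws = res.slope + res.stderr * rng.standard_normal(n_samples)
    fit = GrowthFit(
        gamma=float(res.slope),
        lag=float("nan"),
        amplitude=float("nan"),
        baseline=float(res.intercept),
        fit_method="effective",
        n_points=int(mask.sum()),
    )
    fit.gamma_samples = np.maximum(gamma_draws, 0.0)
    return fit


def exp_window_rate(
    curves: list[GrowthCurve], doubling_cutoff: float = 3.0
) -> GrowthFit:
    """Pooled early-exponential rate: shared slope, one intercept per well.

    Uses only points before each well's OD exceeds 2**doubling_cutoff times its
    initial above-blank OD, then fits log2 OD ~ time with per-well intercepts
    (least-squares dummy variables; on balanced designs the pooled slope equals
    the mean of per-well slopes).
    """
    ts, ys, wells = [], [], []
    for c in curves:
        v = c.od - c.blank
        pos = v[v > 0]
        if len(pos) == 0:
            continue
        init = pos[: max(1, min(3, len(pos)))].mean()
        mask = (v > 0) & (v <= init * 2.0**doubling_cutoff)
        if mask.sum() >= 2:
            ts.append(c.times[mask])
            ys.append(c.log2_od()[mask])
            wells.append(np.full(mask.sum(), c.well_id))
    if not ts:
        raise ValueError("no points below the doubling cutoff in any curve")
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    well = np.concatenate(wells)
    uniq = np.unique(well)
    X = np.zeros((len(t), 1 + len(uniq)))
    X[:, 0] = t
    for j, w in enumerate(uniq):
        X[well == w, 1 + j] = 1.0
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(t) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    slope_se = float(np.sqrt(s2 * xtx_inv[0, 0]))
    fit = GrowthFit(
        gamma=float(beta[0]),
        lag=float("nan"),
        amplitude=float("nan"),
        baseline=float(np.mean(beta[1:])),
        fit_method="exp_window",
        n_points=len(t),
        residual_sd=float(np.sqrt(s2)),
    )
    fit.covariance = np.array([[slope_se**2]])
    return fit


def fit_growth_spline(curve: GrowthCurve, n_grid: int = 400) -> GrowthFit:
    """Spline-guided rate: GCV smoothing spline on log2 OD, gamma = max derivative."""
    t = curve.times
    y = curve.log2_od()
    spl = make_smoothing_spline(t, y)
    grid = np.linspace(t.min(), t.max(), n_grid)
    deriv = spl.derivative()(grid)
    i = int(np.argmax(deriv))
    gamma = float(deriv[i])
    baseline = float(spl(grid).min())
    # tangent at the max-slope point down to the baseline level
    lag = float(grid[i] - (spl(grid[i]) - baseline) / gamma) if gamma > 0 else float("nan")
    return GrowthFit(
        gamma=max(gamma, 0.0),
        lag=lag,
        amplitude=float(spl(grid).max() - baseline),
        baseline=baseline,
        fit_method="spline",
        n_points=len(t),
    )


def lag_and_saturation(curve: GrowthCurve, fit: GrowthFit | None = None) -> tuple[float, float]:
    """Lag time and time-to-saturation (first time y reaches 95% of amplitude).

    Returns (nan, nan) for no-growth / zero-amplitude fits.
    """
    if fit is None:
        fit = fit_growth_model(curve)
    if fit.no_growth or fit.amplitude <= 0 or fit.params is None:
        return float("nan"), float("nan")
    _, _, k, tm = fit.params
    t_sat = tm + np.log(_SAT_LEVEL / (1 - _SAT_LEVEL)) / k
    return float(fit.lag), float(t_sat)


def growth_rate_ratio(samples_a: np.ndarray, samples_b: np.ndarray) -> RateRatio:
    """Gamma ratio a/b over paired posterior draws with a 95% percentile CI."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample set")
    m = min(len(a), len(b))
    a, b = a[:m], b[:m]
    flags = []
    mask = b > 0
    if not mask.all():
        flags.append("nonpositive_denominator_draws_dropped")
    ratio = a[mask] / b[mask]
    if len(ratio) == 0:
        raise ValueError("no positive denominator draws")
    lo, med, hi = np.percentile(ratio, [2.5, 50, 97.5])
    return RateRatio(
        gamma_ratio=float(med), ci_low=float(lo), ci_high=float(hi), n_samples=int(len(ratio)), flags=flags
    )


def significantly_different(r1: RateRatio, r2: RateRatio) -> bool:
    """Two conditions differ when their ratio CIs do not overlap."""
    return r1.ci_high < r2.ci_low or r2.ci_high < r1.ci_low


def prune_outlier_wells(fits: list[GrowthFit], factor: float = 3.0) -> list[bool]:
    """Flag wells whose fit residual SD exceeds `factor` x the median across wells.

    Automatic analog of discarding wells with optical artifacts; returns a
    keep-mask aligned with the input list.
    """
    sds = np.array([f.residual_sd for f in fits], dtype=float)
    med = np.nanmedian(sds)
    if not np.isfinite(med) or med == 0:
        return [True] * len(fits)
    return [not (np.isfinite(s) and s > factor * med) for s in sds]


def fit_condition_table(
    curves_by_group: dict[tuple[str, str], list[GrowthCurve]],
    n_posterior: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every (strain, condition) group and tabulate rates with 95% CIs.

    Replicate wells are fitted independently, outlier wells pruned, posterior
    draws pooled across the kept replicates (equal draws per well).
    """
    rows = []
    groups = sorted(curves_by_group)
    for gi, key in enumerate(groups):
        strain, condition = key
        curves = curves_by_group[key]
        fits = [fit_growth_model(c) for c in curves]
        keep = prune_outlier_wells(fits)
        kept = [f for f, k in zip(fits, keep) if k] or fits
        per = max(n_posterior // len(kept), 100)
        pooled = []
        for fi, f in enumerate(kept):
            sample_posterior(f, n=per, seed=seed * 100_003 + gi * 131 + fi)
            pooled.append(f.gamma_samples)
        draws = np.concatenate(pooled)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "strain": strain,
                "condition": condition,
                "rate": float(np.median([f.gamma for f in kept])),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "method": "model",
                "n_replicates": len(kept),
                "n_pruned": len(fits) - len(kept),
            }
        )
    return pd.DataFrame(rows)


def read_growth_long(path, plate_map: pd.DataFrame | None = None) -> dict[tuple[str, str], list[GrowthCurve]]:
    """Read long-format (well, time_min, od) growth data, grouped by strain/condition.

    If strain/condition columns are absent, a plate-map table (well -> strain,
    condition) supplies them.
    """
    df = pd.read_csv(path, sep="\t")
    if plate_map is not None:
        df = df.merge(plate_map, on="well", how="left", suffixes=("", "_map"))
    out: dict[tuple[str, str], list[GrowthCurve]] = {}
    for (strain, condition, well), sub in df.groupby(["strain", "condition", "well"]):
        sub = sub.sort_values("time_min")
        curve = GrowthCurve(
            well_id=str(well), times=sub["time_min"].to_numpy() / 60.0, od=sub["od"].to_numpy(), blank=0.04
        )
        out.setdefault((str(strain), str(condition)), []).append(curve)
    return out
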