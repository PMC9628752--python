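"""Growth-rate estimation and the logistic light-response model.

Biomass-specific growth rates mu (h^-1) within one sequencing-batch-reactor
(SBR) reaction phase follow from the exponential-growth integral,

    mu = ln(X1/X0) / (T1 - T0),

either between the phase endpoints or as the slope of ln X against time.
Across light conditions, mu responds to the photon supply x (incident
irradiance in W m^-2, or the specific supply rate r_EX in
umol photons s^-1 gVSS^-1) through a generic logistic,

    mu(x) = a / (1 + exp(-b (x - c))),

whose asymptote a is read as the maximum growth rate mu_max and whose
midpoint c as a half-saturation constant for light K_L. The model object
follows the statsmodels convention: construct from data, call ``fit()``,
inspect the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CycleSeries",
    "GrowthRateEstimate",
    "LightResponseModel",
    "LightResponseResults",
    "RegimeCall",
    "estimate_growth_rate",
    "logistic",
    "washout_rate",
    "classify_regime",
]

# Default acetate detection limit (mmol/L) for "below detection limit" calls
DETECTION_LIMIT_MMOL = 0.02
# Specific light supply rate separating light- from acetate-limited operation
REX_THRESHOLD = 10.0


@dataclass
class CycleSeries:
    """Time series of biomass and acetate within one SBR reaction phase.

    Parameters
    ----------
    condition_irradiance : float
        Incident irradiance of the condition, W m^-2.
    cycle_id : str
        Identifier of the cycle within the condition.
    time : array-like
        Sampling times in hours, strictly increasing.
    biomass : array-like
        Biomass concentrations in g VSS L^-1 (NaN where not measured).
    acetate : array-like
        Acetate concentrations in mmol L^-1 (NaN where not measured).
    """

    condition_irradiance: float
    cycle_id: str
    time: np.ndarray
    biomass: np.ndarray
    acetate: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.acetate = np.asarray(self.acetate, dtype=float)
        if not (len(self.time) == len(self.biomass) == len(self.acetate)):
            raise ValueError("time, biomass and acetate must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.biomass < 0) or np.any(self.acetate < 0):
                raise ValueError("biomass and acetate must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_W_m2": self.condition_irradiance,
                "cycle_id": self.cycle_id,
                "time_h": self.time,
                "biomass_gVSS_L": self.biomass,
                "acetate_mmol_L": self.acetate,
            }
        )


@dataclass(frozen=True)
class GrowthRateEstimate:
    """A biomass-specific growth rate over a time window."""

    mu: float  # h^-1; may be <= 0 for decaying biomass
    window: tuple[float, float]  # (T0, T1) in h
    n_points: int
    method: str  # "endpoint" | "log-linear-regression"

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window must satisfy T1 > T0")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


def estimate_growth_rate(
    series: CycleSeries,
    window: tuple[float, float] | None = None,
    method: str = "endpoint",
) -> GrowthRateEstimate:
    """Estimate mu (h^-1) from a cycle's biomass observations.

    ``endpoint`` applies mu = ln(X1/X0)/(T1-T0) to the first and last
    observations inside the window; ``log-linear-regression`` fits the slope
    of ln X against time over all in-window points. The two agree exactly on
    perfectly exponential data.
    """
    mask = np.isfinite(series.biomass)
    t = series.time[mask]
    x = series.biomass[mask]
    if window is not None:
        t0, t1 = window
        inwin = (t >= t0) & (t <= t1)
        t, x = t[inwin], x[inwin]
    if len(t) < 2:
        raise ValueError("at least 2 biomass observations required in window")
    if np.any(x <= 0):
        raise ValueError("biomass must be > 0 within the estimation window")

    if method == "endpoint":
        mu = float(np.log(x[-1] / x[0]) / (t[-1] - t[0]))
    elif method == "log-linear-regression":
        slope, _ = np.polyfit(t, np.log(x), 1)
        mu = float(slope)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return GrowthRateEstimate(
        mu=mu, window=(float(t[0]), float(t[-1])), n_points=len(t), method=method
    )


def select_exponential_window(
    series: CycleSeries, min_points: int = 3, r2_floor: float = 0.98
) -> tuple[float, float]:
    """Pick the longest early window over which ln(biomass) is linear.

    Scans windows anchored at the first observation and returns the longest
    one whose log-linear fit achieves R^2 >= ``r2_floor``. Intended for
    cycles where substrate depletion flattens growth partway through the
    phase. When no anchored window reaches the floor (flat or noisy series
    carrying no depletion signature) the whole phase is returned, so the
    estimate degrades gracefully to the full-phase regression.
    """
    mask = np.isfinite(series.biomass)
    t = series.time[mask]
    x = series.biomass[mask]
    if len(t) < min_points:
        raise ValueError("too few biomass observations for window selection")
    if np.any(x <= 0):
        raise ValueError("biomass must be > 0 for log-linear window selection")
    logx = np.log(x)
    chosen_end = None
    for end in range(min_points, len(t) + 1):
        slope, icpt = np.polyfit(t[:end], logx[:end], 1)
        resid = logx[:end] - (slope * t[:end] + icpt)
        sst = np.sum((logx[:end] - logx[:end].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        if r2 >= r2_floor:
            chosen_end = end  # keep extending while linearity holds
    end = chosen_end if chosen_end is not None else len(t)
    return float(t[0]), float(t[end - 1])


def select_substrate_window(
    series: CycleSeries, min_points: int = 3, depletion_fraction: float = 0.05
) -> tuple[float, float]:
    """Window from phase start to the moment the substrate is depleted.

    Growth is substrate-unlimited (and hence exponential at the light-set
    rate) while acetate remains; the window ends at the first observation
    where acetate falls below ``depletion_fraction`` of its initial value
    (extended if needed to keep ``min_points`` observations). Cycles that
    never deplete return the whole phase. Falls back to the whole phase when
    no acetate data are present.
    """
    mask = np.isfinite(series.biomass)
    t = series.time[mask]
    ace = series.acetate[mask]
    if len(t) < min_points:
        raise ValueError("too few biomass observations for window selection")
    finite_ace = np.isfinite(ace)
    if not finite_ace.any() or ace[finite_ace][0] <= 0:
        return float(t[0]), float(t[-1])
    threshold = depletion_fraction * float(ace[finite_ace][0])
    depleted = np.where(finite_ace & (ace < threshold))[0]
    end = int(depleted[0]) + 1 if len(depleted) else len(t)
    end = max(end, min_points)
    return float(t[0]), float(t[end - 1])


def logistic(x, a, b, c):
    """Generic logistic response a / (1 + exp(-b (x - c)))."""
    return a / (1.0 + np.exp(-b * (np.asarray(x, dtype=float) - c)))


@dataclass
class LightResponseResults:
    """Fit results for the logistic light-response model.

    Attributes
    ----------
    params : ndarray
        Fitted (a, b, c).
    bse : ndarray
        Asymptotic standard errors of the parameters (NaN when the
        covariance is not estimable, e.g. degenerate data).
    rss : float
        Residual sum of squares.
    converged : bool
        Whether the optimiser converged to a non-degenerate optimum.
    degenerate : bool
        True when the data carry no information on the steepness b
        (e.g. flat response); a then approaches the common level.
    """

    model: "LightResponseModel"
    params: np.ndarray
    bse: np.ndarray
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def b(self) -> float:
        return float(self.params[1])

    @property
    def c(self) -> float:
        return float(self.params[2])

    # interpretation aliases
    @property
    def mu_max(self) -> float:
        """Asymptotic maximum growth rate, h^-1."""
        return self.a

    @property
    def K_L(self) -> float:
        """Half-saturation constant for light, in the model's x units."""
        return self.c

    def predict(self, x) -> np.ndarray:
        """Predicted growth rate at light level(s) x."""
        return logistic(x, *self.params)

    def summary(self) -> str:
        rows = [
            ("a (mu_max, h^-1)", self.a, self.bse[0]),
            (f"b (per {self.model.x_kind})", self.b, self.bse[1]),
            (f"c (K_L, {self.model.x_kind})", self.c, self.bse[2]),
        ]
        lines = [
            "Logistic light-response fit: mu(x) = a / (1 + exp(-b (x - c)))",
            f"x kind: {self.model.x_kind}   n obs: {len(self.model.x)}",
            f"converged: {self.converged}   degenerate: {self.degenerate}",
            f"residual sum of squares: {self.rss:.6g}",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>14}{'std err':>14}",
            "-" * 58,
        ]
        for name, est, se in rows:
            se_s = f"{se:14.4g}" if np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<22}{est:14.5g}{se_s}")
        lines.append("-" * 58)
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


class LightResponseModel:
    """Logistic model of specific growth rate against light supply.

    Parameters
    ----------
    x : array-like
        Light levels: incident irradiance (W m^-2) or specific light supply
        rate r_EX (umol photons s^-1 gVSS^-1), all >= 0.
    y : array-like
        Specific growth rates, h^-1.
    x_kind : str
        ``"incident_W_m2"`` or ``"rEX_umol_s_gVSS"`` — which light axis the
        model is expressed on.

    Examples
    --------
    >>> from ppblight.datasets import load_condition_means
    >>> tbl = load_condition_means()
    >>> res = LightResponseModel(tbl["irradiance_W_m2"], tbl["mu_h"]).fit()
    >>> round(res.mu_max, 2)
    0.24
    """

    X_KINDS = ("incident_W_m2", "rEX_umol_s_gVSS")

    def __init__(self, x, y, x_kind: str = "incident_W_m2") -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 4:
            raise ValueError("at least 4 (x, y) pairs are required")
        if np.any(x < 0):
            raise ValueError("light levels must be >= 0")
        if len(np.unique(x)) < 2:
            raise ValueError("at least two distinct light levels required")
        if x_kind not in self.X_KINDS:
            raise ValueError(f"x_kind must be one of {self.X_KINDS}")
        order = np.argsort(x, kind="stable")
        self.x = x[order]
        self.y = y[order]
        self.x_kind = x_kind

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_col: str = "irradiance_W_m2",
        y_col: str = "mu_h",
        x_kind: str = "incident_W_m2",
    ) -> "LightResponseModel":
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy(), x_kind=x_kind)

    def _start_values(self) -> tuple[float, float, float]:
        a0 = float(np.max(self.y))
        if a0 <= 0:
            a0 = 1e-6
        half = a0 / 2.0
        c0 = float(self.x[np.argmin(np.abs(self.y - half))])
        span = float(self.x.max() - self.x.min())
        b0 = 1.0 / (span / 4.0)
        return a0, b0, c0

    def fit(self, n_starts: int = 5, maxfev: int = 20000) -> LightResponseResults:
        """Unweighted nonlinear least squares with a multi-start on c.

        Initialisation: a0 = max(y); c0 = x where y is closest to max(y)/2;
        b0 = 4 / x-range. Bounds: a in (0, 2 max(y)], b > 0,
        c in [min(x), max(x)]. ``n_starts`` equispaced c starting points
        guard against the midpoint landing in a flat region.
        """
        a0, b0, _ = self._start_values()
        lower = [1e-12, 1e-12, float(self.x.min())]
        upper = [2.0 * max(np.max(self.y), 1e-12), np.inf, float(self.x.max())]
        c_starts = np.linspace(self.x.min(), self.x.max(), n_starts)

        best = None
        errors = []
        for c0 in c_starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        logistic,
                        self.x,
                        self.y,
                        p0=[a0, b0, c0],
                        bounds=(lower, upper),
                        maxfev=maxfev,
                    )
            except (RuntimeError, ValueError) as exc:  # non-convergence of one start
                errors.append(str(exc))
                continue
            rss = float(np.sum((logistic(self.x, *popt) - self.y) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)

        if best is None:
            nan3 = np.full(3, np.nan)
            return LightResponseResults(
                model=self,
                params=nan3,
                bse=nan3.copy(),
                rss=np.nan,
                converged=False,
                message="all starts failed: " + "; ".join(errors[:2]),
            )

        popt, pcov, rss = best
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        # Flat data leave the steepness unidentified: the optimum collapses
        # onto the b -> 0 ridge where the prediction is the constant a/2 (any
        # a with a/2 = level fits equally well). Detect via an exploding or
        # inestimable steepness error, or a prediction with no dynamic range.
        pred = logistic(self.x, *popt)
        degenerate = bool(
            not np.all(np.isfinite(bse))
            or (np.isfinite(bse[1]) and bse[1] > 1e3 * max(abs(popt[1]), 1e-12))
            or np.ptp(pred) < 1e-3 * max(abs(popt[0]), 1e-12)
        )
        return LightResponseResults(
            model=self,
            params=np.asarray(popt, dtype=float),
            bse=np.asarray(bse, dtype=float),
            rss=rss,
            converged=True,
            degenerate=degenerate,
            message="steepness b is not identified by the data" if degenerate else "",
        )


def predict_mu(results_or_params, x):
    """Growth rate predicted by a fitted model or an (a, b, c) triple."""
    if isinstance(results_or_params, LightResponseResults):
        return results_or_params.predict(x)
    a, b, c = results_or_params
    return logistic(x, a, b, c)


def washout_rate(srt: float) -> float:
    """Minimum growth rate retained at solids retention time ``srt`` (h).

    Biomass growing slower than 1/SRT is purged faster than it divides and
    washes out of the reactor.
    """
    if srt <= 0:
        raise ValueError("SRT must be > 0")
    return 1.0 / srt


@dataclass(frozen=True)
class RegimeCall:
    """Limitation-regime classification of one light condition."""

    condition_irradiance: float
    regime: str  # "acetate_limited" | "light_limited" | "dark"
    residual_acetate: float
    rEX: float | None = None

    def __post_init__(self) -> None:
        if (self.condition_irradiance == 0) != (self.regime == "dark"):
            raise ValueError("dark regime iff irradiance == 0")


def classify_regime(
    residual_acetate: float,
    rEX: float | None,
    irradiance: float,
    detection_limit: float = DETECTION_LIMIT_MMOL,
    rex_threshold: float = REX_THRESHOLD,
) -> RegimeCall:
    """Classify a condition as dark, acetate-limited or light-limited.

    A culture that exhausts its acetate by the end of the reaction phase
    (residual at or below the detection limit), or that receives photons
    above the r_EX threshold, is acetate-limited; otherwise, residual
    acetate with scarce photons marks light limitation.
    """
    if residual_acetate < 0:
        raise ValueError("residual_acetate must be >= 0")
    if irradiance == 0:
        regime = "dark"
    elif residual_acetate <= detection_limit or (
        rEX is not None and rEX >= rex_threshold
    ):
        regime = "acetate_limited"
    else:
        regime = "light_limited"
    return RegimeCall(
        condition_irradiance=irradiance,
        regime=regime,
        residual_acetate=residual_acetate,
        rEX=rEX,
    )
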