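"""Four-parameter log-logistic dose-response model and censoring-aware IC50.

The model is the standard LL.4 curve

    f(x) = c + (d - c) / (1 + (x / e)^b)

with slope ``b``, lower limit ``c``, upper limit ``d`` and inflection
concentration ``e`` (µM).  For an inhibition curve expressed as residual
signal, ``d`` is the uninhibited plateau near 100% and ``c`` the fully
quenched plateau near 0%; the reported IC50 is the fitted inflection ``e``
(relative IC50).

Fitting is nonlinear least squares on log10 concentration with a small
deterministic multi-start over the slope.  Fit quality is gated on the
coefficient of determination (R^2 < 0.80 is deemed unsuitable) and on
whether both plateaus were actually observed within the tested range;
IC50 values that cannot be pinned inside the range are censored as
``>cmax`` / ``<cmin`` bounds or as a bracketing interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidParams, InvalidRange

# quality labels
OK = "OK"
UNSUITABLE = "UNSUITABLE"
NO_FIT = "NO_FIT"
EXTEND_RANGE = "EXTEND_RANGE"

# censoring kinds
POINT = "point"
GREATER_THAN = "greater_than"
LESS_THAN = "less_than"
INTERVAL = "interval"
NONE = "none"


@dataclass
class LL4Params:
    """LL.4 parameters: slope b, lower limit c, upper limit d, inflection e (µM)."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not (self.e > 0):
            raise InvalidParams(f"inflection e must be > 0, got {self.e}")


def ll4(x, params: LL4Params):
    """Evaluate the LL.4 curve at concentration(s) x > 0 (µM)."""
    x = np.asarray(x, dtype=float)
    return params.c + (params.d - params.c) / (1.0 + (x / params.e) ** params.b)


@dataclass
class DoseResponseData:
    """Replicated observations for one compound in one assay."""

    compound_id: str
    concentration_um: np.ndarray
    response: np.ndarray  # normalized %, residual-signal or inhibition scale
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration_um = np.asarray(self.concentration_um, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration_um.shape != self.response.shape:
            raise InvalidRange("concentration and response lengths differ")
        if np.any(self.concentration_um <= 0):
            raise InvalidRange("concentrations must be > 0 (controls are excluded)")
        if len(np.unique(self.concentration_um)) < 2:
            raise InvalidRange("need >= 2 distinct concentrations to fit")

    @property
    def cmin(self) -> float:
        return float(self.concentration_um.min())

    @property
    def cmax(self) -> float:
        return float(self.concentration_um.max())

    def concentration_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique concentrations (ascending) and the mean response at each."""
        concs = np.unique(self.concentration_um)
        means = np.array(
            [self.response[self.concentration_um == c].mean() for c in concs]
        )
        return concs, means


@dataclass
class CensoredIC50:
    """IC50 that may be a point, a one-sided bound, an interval, or absent."""

    kind: str
    value_um: float | None = None  # point estimate
    lo_um: float | None = None  # interval lower / bound value
    hi_um: float | None = None

    @classmethod
    def point(cls, value: float) -> "CensoredIC50":
        return cls(POINT, value_um=float(value))

    @classmethod
    def greater_than(cls, bound: float) -> "CensoredIC50":
        return cls(GREATER_THAN, lo_um=float(bound))

    @classmethod
    def less_than(cls, bound: float) -> "CensoredIC50":
        return cls(LESS_THAN, hi_um=float(bound))

    @classmethod
    def interval(cls, lo: float, hi: float) -> "CensoredIC50":
        return cls(INTERVAL, lo_um=float(lo), hi_um=float(hi))

    @classmethod
    def none(cls) -> "CensoredIC50":
        return cls(NONE)


@dataclass
class FitResult:
    """Fitted LL.4 curve with quality gates and censored IC50."""

    compound_id: str
    params: LL4Params | None
    ic50: CensoredIC50
    r_squared: float
    rse: float
    n: int
    k: int = 4
    quality: str = NO_FIT
    converged: bool = False
    sum_sq_res: float = field(default=np.nan, repr=False)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot (1 for a perfect fit of
    constant data, by convention)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    ssres = float(np.sum((y - yhat) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return 1.0 if ssres <= 1e-12 else 0.0
    return 1.0 - ssres / sstot


def residual_standard_error(observed, predicted, k: int = 4) -> float:
    """RSE = sqrt(SSres / (n - k)) with k fitted parameters."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    n = len(y)
    if n <= k:
        return float("nan")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / (n - k)))


def _model(log10x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    b, c, d, log10e = theta
    return c + (d - c) / (1.0 + 10.0 ** (b * (log10x - log10e)))


def fit_ll4(
    data: DoseResponseData,
    plateau_margin: float = 10.0,
    min_r_squared: float = 0.80,
    midpoint: float = 50.0,
    scale: str = "residual",
) -> FitResult:
    """Fit the LL.4 model and derive quality class and censored IC50.

    Initialization: d from the median response at the two lowest
    concentrations, c from the two highest, e at the geometric mean of the
    tested range, slope multi-started at 0.5 / 1 / 2 (best objective wins,
    ties broken by the smallest fitted slope).  Bounds: b in [0.1, 20], e in
    [cmin/100, cmax*100], c and d within the observed response range +/- 50.

    ``scale`` declares what the responses measure — "residual" (% signal
    remaining, falls with dose) or "inhibition" (% inhibition, rises with
    dose) — and orients the censoring rules.
    """
    x = data.concentration_um
    y = data.response
    logx = np.log10(x)
    n = len(y)

    sstot = float(np.sum((y - y.mean()) ** 2))
    flat = sstot <= 1e-12 * max(1.0, float(np.mean(y)) ** 2) * n

    order = np.argsort(x)
    concs, _ = data.concentration_means()
    low_mask = np.isin(x, concs[:2])
    high_mask = np.isin(x, concs[-2:])
    d0 = float(np.median(y[low_mask]))
    c0 = float(np.median(y[high_mask]))
    log_e0 = float((np.log10(data.cmin) + np.log10(data.cmax)) / 2.0)

    ymin, ymax = float(y.min()), float(y.max())
    lower = np.array([0.1, ymin - 50.0, ymin - 50.0, np.log10(data.cmin / 100.0)])
    upper = np.array([20.0, ymax + 50.0, ymax + 50.0, np.log10(data.cmax * 100.0)])

    best = None  # (ssres, theta)
    for b0 in (0.5, 1.0, 2.0):
        theta0 = np.clip(
            np.array([b0, c0, d0, log_e0]), lower + 1e-12, upper - 1e-12
        )
        try:
            sol = least_squares(
                lambda th: _model(logx, th) - y,
                theta0,
                bounds=(lower, upper),
                method="trf",
                ftol=1e-8,
                xtol=1e-10,
                gtol=1e-8,
                max_nfev=200,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        # a solution that merely hit the evaluation cap is still the
        # optimizer's best point; the R^2 gate decides whether it is usable
        ssres = float(np.sum(sol.fun**2))
        if (
            best is None
            or ssres < best[0] * (1 - 1e-9)
            or (abs(ssres - best[0]) <= 1e-9 * max(best[0], 1e-300) and sol.x[0] < best[1][0])
        ):
            best = (ssres, sol.x)

    if best is None:
        fit = FitResult(
            compound_id=data.compound_id,
            params=None,
            ic50=CensoredIC50.none(),
            r_squared=np.nan,
            rse=np.nan,
            n=n,
            quality=NO_FIT,
            converged=False,
        )
        fit.ic50 = ic50(fit, data.cmin, data.cmax, data=data, midpoint=midpoint,
                        scale=scale)
        return fit

    ssres, theta = best
    params = LL4Params(b=float(theta[0]), c=float(theta[1]), d=float(theta[2]),
                       e=float(10.0 ** theta[3]))
    predicted = _model(logx, theta)
    r2 = r_squared(y, predicted)
    rse = residual_standard_error(y, predicted, k=4)

    fit = FitResult(
        compound_id=data.compound_id,
        params=params,
        ic50=CensoredIC50.none(),
        r_squared=float(r2),
        rse=rse,
        n=n,
        converged=True,
        sum_sq_res=ssres,
    )
    if flat:
        fit.quality = NO_FIT  # no signal variation: nothing to fit
    else:
        fit.quality = classify_fit(
            fit, data, plateau_margin=plateau_margin, min_r_squared=min_r_squared
        )
    fit.ic50 = ic50(fit, data.cmin, data.cmax, data=data, midpoint=midpoint,
                    scale=scale)
    return fit


def classify_fit(
    fit: FitResult,
    data: DoseResponseData,
    plateau_margin: float = 10.0,
    min_r_squared: float = 0.80,
) -> str:
    """Quality class for a converged fit.

    ``UNSUITABLE`` when R^2 < 0.80; ``EXTEND_RANGE`` when the fitted
    inflection lies outside the tested range or one of the plateaus was not
    observed within ``plateau_margin`` response units; ``OK`` otherwise.
    """
    if not fit.converged or fit.params is None:
        return NO_FIT
    if fit.r_squared < min_r_squared:
        return UNSUITABLE
    p = fit.params
    if not (data.cmin <= p.e <= data.cmax):
        return EXTEND_RANGE
    _, means = data.concentration_means()
    hi, lo = max(p.c, p.d), min(p.c, p.d)
    top_seen = means.max() >= hi - plateau_margin
    bottom_seen = means.min() <= lo + plateau_margin
    if not (top_seen and bottom_seen):
        return EXTEND_RANGE
    return OK


def ic50(
    fit: FitResult,
    cmin: float,
    cmax: float,
    data: DoseResponseData | None = None,
    midpoint: float = 50.0,
    scale: str = "residual",
) -> CensoredIC50:
    """Censoring-aware IC50 from a fit and the tested extremes.

    The half-effect crossing is judged on the per-concentration mean
    responses (robust to a poor fit): if the means never reach the inhibited
    side of ``midpoint`` the IC50 is right-censored at ``cmax``; if even the
    lowest tested concentration is fully on the inhibited side it is
    left-censored at ``cmin``.  When the crossing is bracketed in-range, an
    ``OK`` fit with in-range inflection gives a point estimate; an unstable
    fit (low R^2 or out-of-range inflection) gives the bracketing interval;
    a failed fit gives no value.

    ``scale`` fixes which side of ``midpoint`` counts as inhibited:
    "residual" (inhibited below) or "inhibition" (inhibited above).
    """
    if scale not in ("residual", "inhibition"):
        raise ValueError(f"unknown response scale {scale!r}")
    if data is not None:
        concs, means = data.concentration_means()
    elif fit.params is not None:
        concs = np.geomspace(cmin, cmax, 25)
        means = ll4(concs, fit.params)
    else:
        return CensoredIC50.none()

    inhibited = means < midpoint if scale == "residual" else means > midpoint

    if not inhibited.any():
        return CensoredIC50.greater_than(cmax)
    if inhibited.all():
        return CensoredIC50.less_than(cmin)

    if fit.quality == OK and fit.params is not None and cmin <= fit.params.e <= cmax:
        return CensoredIC50.point(fit.params.e)

    if not fit.converged:
        # no usable curve: report nothing rather than an unfounded bracket
        return CensoredIC50.none()

    # bracket the first crossing between adjacent tested concentrations
    for j in range(len(concs) - 1):
        if inhibited[j] != inhibited[j + 1]:
            return CensoredIC50.interval(float(concs[j]), float(concs[j + 1]))
    return CensoredIC50.none()
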