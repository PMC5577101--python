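"""Four-parameter logistic dose-response fitting and cross-experiment summaries.

The model is the standard Hill equation

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill)

fitted by trust-region least squares with multi-start initialisation over a
log-spaced EC50 grid (EC50 is fitted on the log scale). Orientation is
normalised after fitting so that ``top >= bottom`` always; declining curves
carry a negative Hill slope. Per-experiment EC50/IC50 values are summarised
across independent experiments as geometric mean with min, max and n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ParameterError


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the 4PL curve at concentrations x (> 0)."""
    x = np.asarray(x, np.float64)
    # extreme slopes during optimisation overflow harmlessly to the asymptotes
    with np.errstate(over="ignore", divide="ignore"):
        return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass(frozen=True)
class Fit4PL:
    """Fitted 4PL parameters with diagnostics; ``unit`` is carried, not converted."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    n_points: int
    unit: str | None = None

    @property
    def ic50(self) -> float:
        """Alias used when the fitted response is percent inhibition."""
        return self.ec50

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class SummaryStat:
    """Geometric mean / min / max / n across independent experiments."""

    geometric_mean: float
    min: float
    max: float
    n: int


def _normalise_orientation(bottom: float, top: float, hill: float) -> tuple[float, float, float]:
    # (b, t, h) and (t, b, -h) describe the same curve; report top >= bottom
    if top < bottom:
        return top, bottom, -hill
    return bottom, top, hill


def fit_4pl(
    concentrations,
    responses,
    weights_inverse_y2: bool = False,
    unit: str | None = None,
) -> Fit4PL:
    """Least-squares 4PL fit with multi-start initialisation.

    Zero/vehicle concentrations are excluded from the fit (they have no
    defined position on a log-concentration axis and serve as the
    unstimulated anchor only). At least four distinct positive
    concentrations are required. Flat responses produce a degenerate
    ``bottom == top`` fit flagged ``converged=False`` rather than raising.
    """
    x = np.asarray(concentrations, np.float64)
    y = np.asarray(responses, np.float64)
    if x.shape != y.shape:
        raise ParameterError(f"concentrations and responses differ in length: {x.shape} vs {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ParameterError("responses must be finite")
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 4:
        raise ParameterError(f"need >= 4 distinct positive concentrations, got {len(np.unique(x))}")

    y_span = float(y.max() - y.min())
    if y_span == 0.0:
        return Fit4PL(bottom=float(y[0]), top=float(y[0]), ec50=float(np.exp(np.mean(np.log(x)))),
                      hill=0.0, rss=0.0, converged=False, n_points=len(x), unit=unit)

    w = 1.0 / np.maximum(np.abs(y), 1e-12) if weights_inverse_y2 else np.ones_like(y)

    def residuals(theta):
        b, t, log_e, h = theta
        return (four_pl(x, b, t, math.exp(log_e), h) - y) * w

    lo, hi = float(y.min()), float(y.max())
    log_grid = np.linspace(math.log(x.min()) - math.log(3), math.log(x.max()) + math.log(3), 7)
    best = None
    for log_e0 in log_grid:
        for h0 in (1.0, -1.0, 2.5, -2.5):
            try:
                res = least_squares(residuals, x0=[lo, hi, log_e0, h0], method="trf", max_nfev=400)
            except Exception:  # pragma: no cover - optimiser pathologies
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:  # pragma: no cover
        raise ParameterError("4PL optimisation failed from every start")
    b, t, log_e, h = best.x
    b, t, h = _normalise_orientation(float(b), float(t), float(h))
    rss = float(2 * best.cost)
    converged = bool(best.success) and abs(t - b) > 1e-9 * max(1.0, abs(t))
    return Fit4PL(bottom=b, top=t, ec50=float(math.exp(log_e)), hill=h,
                  rss=rss, converged=converged, n_points=len(x), unit=unit)


def ic50_from_inhibition(concentrations, percent_inhibition, unit: str | None = None) -> Fit4PL:
    """Fit the 4PL to percent-inhibition data; ``.ic50`` is the midpoint.

    Percent inhibition rises with inhibitor concentration, so the fit is an
    ascending 4PL whose EC50 field is reported as the IC50 of the underlying
    response decline.
    """
    return fit_4pl(concentrations, percent_inhibition, unit=unit)


def summarize_experiments(values) -> SummaryStat:
    """Geometric mean, min, max and n of per-experiment EC50/IC50 values."""
    v = np.asarray(list(values), np.float64)
    if len(v) == 0:
        raise ParameterError("no values to summarise")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ParameterError("summary values must be positive and finite")
    return SummaryStat(
        geometric_mean=float(np.exp(np.mean(np.log(v)))),
        min=float(v.min()),
        max=float(v.max()),
        n=int(len(v)),
    )


def fit_experiments(tidy: pd.DataFrame, response_col: str = "response") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit each experiment in a tidy table and build the summary table.

    ``tidy`` needs columns experiment_id, concentration, unit, and the
    response column. Returns (per-experiment fits, one-row summary with
    geometric_mean / min / max / n of the EC50s).
    """
    fits = []
    for exp_id, sub in tidy.groupby("experiment_id", sort=True):
        unit = sub["unit"].iloc[0] if "unit" in sub else None
        fit = fit_4pl(sub["concentration"], sub[response_col], unit=unit)
        fits.append(
            {
                "experiment_id": exp_id,
                "bottom": fit.bottom,
                "top": fit.top,
                "ec50": fit.ec50,
                "hill": fit.hill,
                "rss": fit.rss,
                "converged": fit.converged,
                "n_points": fit.n_points,
                "unit": unit,
            }
        )
    fits_df = pd.DataFrame(fits)
    ok = fits_df.loc[fits_df["converged"], "ec50"]
    if len(ok):
        s = summarize_experiments(ok)
        summary = pd.DataFrame(
            [{"geometric_mean": s.geometric_mean, "min": s.min, "max": s.max, "n": s.n}]
        )
    else:
        summary = pd.DataFrame(columns=["geometric_mean", "min", "max", "n"])
    return fits_df, summary
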