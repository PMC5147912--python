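"""Serial dilutions, four-parameter logistic fits, EC50/IC50 estimation.

The response model is the four-parameter logistic (4PL)

    r(c) = bottom + (top - bottom) / (1 + (midpoint / c)^hill)

fitted by least squares on log10 concentration with multi-start
initialization. ``hill > 0`` gives an increasing curve (activation, EC50);
``hill < 0`` a decreasing one (viability inhibition, IC50). The reported
midpoint is the *relative* EC50 (the curve's inflection between its own
asymptotes); where the asymptotes bracket the 50-response level the
absolute-50 crossing is reported alongside.

A fit is flagged ``converged`` only when the optimizer succeeded, the fitted
dynamic range is resolvable above the residual noise, and the midpoint lies
within (an extended) tested concentration range; flat or noise-only series
come back ``converged=False`` with an undefined midpoint instead of a
spurious potency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import conc_to_uM

__all__ = [
    "DilutionSeries",
    "DoseResponseFit",
    "make_dilution_series",
    "fit_4pl",
    "viability_from_absorbance",
    "fit_ic50",
    "ec50_from_plate",
]


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric (serial) dilution series, highest concentration first."""

    top_conc: float
    fold: float
    n_points: int
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.top_conc <= 0:
            raise ValueError("top_conc must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")

    @property
    def concentrations(self) -> np.ndarray:
        return self.top_conc / self.fold ** np.arange(self.n_points)


def make_dilution_series(
    top_conc: float, fold: float = 2.0, n_points: int = 8, unit: str = "uM"
) -> DilutionSeries:
    """Exact geometric series ``top/fold^i`` for i = 0..n_points-1."""
    return DilutionSeries(top_conc=float(top_conc), fold=float(fold), n_points=int(n_points), unit=unit)


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit result; ``midpoint`` is the relative EC50/IC50."""

    bottom: float
    top: float
    midpoint: float  # concentration units of the input; NaN when not converged
    hill: float
    rss: float
    converged: bool
    n_points: int
    residual_sd: float
    midpoint_abs: float | None = None  # absolute-50 crossing, if bracketed
    unit: str = "uM"

    @property
    def span(self) -> float:
        return self.top - self.bottom


def _4pl(logc: np.ndarray, bottom: float, top: float, logm: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logm - logc)))


def _absolute_crossing(bottom, top, midpoint, hill, level=50.0):
    if not (min(bottom, top) < level < max(bottom, top)):
        return None
    f = (level - bottom) / (top - bottom)  # in (0, 1)
    return float(midpoint * (f / (1.0 - f)) ** (1.0 / hill))


def fit_4pl(
    conc,
    response,
    weights=None,
    direction: str = "auto",
    min_span: float = 10.0,
    unit: str = "uM",
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    Multi-start: midpoint guesses at the 25/50/75th percentiles of the
    tested log-concentrations crossed with two Hill-slope magnitudes.
    ``direction`` constrains the Hill-slope sign ("increasing",
    "decreasing", or "auto" to infer it from the data trend). ``min_span``
    is the smallest fitted dynamic range (response units) accepted as a real
    dose effect; below it the fit reports ``converged=False``.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape or conc.ndim != 1:
        raise ValueError("conc and response must be 1-D arrays of equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 (log-scale fit)")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(conc).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if direction not in ("auto", "increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    logc = np.log10(conc)
    n = y.size
    failed = DoseResponseFit(
        bottom=float(np.min(y)),
        top=float(np.max(y)),
        midpoint=float("nan"),
        hill=float("nan"),
        rss=float("inf"),
        converged=False,
        n_points=n,
        residual_sd=float("nan"),
        unit=unit,
    )
    if np.ptp(y) == 0:  # perfectly flat: nothing to fit
        return failed

    if direction == "auto":
        slope = np.polyfit(logc, y, 1)[0]
        direction = "increasing" if slope >= 0 else "decreasing"
    hill_bounds = (0.05, 8.0) if direction == "increasing" else (-8.0, -0.05)

    lo_y, hi_y = float(np.min(y)), float(np.max(y))
    pad = 0.5 * (hi_y - lo_y) + 1e-9
    bounds = (
        [lo_y - 10 * pad, lo_y - 10 * pad, logc.min() - 3.0, hill_bounds[0]],
        [hi_y + 10 * pad, hi_y + 10 * pad, logc.max() + 3.0, hill_bounds[1]],
    )

    def residuals(p):
        return w * (_4pl(logc, *p) - y)

    best = None
    logm_starts = np.quantile(logc, [0.25, 0.5, 0.75])
    hill_starts = [0.8, 1.5] if direction == "increasing" else [-0.8, -1.5]
    b0, t0 = (lo_y, hi_y)
    for logm0 in logm_starts:
        for h0 in hill_starts:
            p0 = np.clip(
                [b0, t0, logm0, h0],
                np.asarray(bounds[0]) + 1e-12,
                np.asarray(bounds[1]) - 1e-12,
            )
            try:
                sol = least_squares(
                    residuals, p0, bounds=bounds, method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - trf is robust on bounded 4PL
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return failed

    rss, sol = best
    bottom, top, logm, hill = (float(v) for v in sol.x)
    if top < bottom:  # same curve re-parameterized; normalize to top >= bottom
        bottom, top, hill = top, bottom, -hill
    midpoint = 10.0**logm
    residual_sd = math.sqrt(rss / max(n - 4, 1))
    span = top - bottom
    in_range = (conc.min() / 10.0) <= midpoint <= (conc.max() * 10.0)
    converged = bool(
        span >= max(min_span, 3.0 * residual_sd) and in_range and np.isfinite(rss)
    )
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        midpoint=midpoint if converged else float("nan"),
        hill=hill,
        rss=rss,
        converged=converged,
        n_points=n,
        residual_sd=residual_sd,
        midpoint_abs=_absolute_crossing(bottom, top, midpoint, hill) if converged else None,
        unit=unit,
    )


def plot_dose_response(
    conc,
    response,
    fit: DoseResponseFit | None,
    path,
    xlabel: str = "concentration (uM)",
    ylabel: str = "response",
) -> None:
    """Write a log-dose response plot (points + fitted 4PL curve) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conc = np.asarray(conc, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.semilogx(conc, response, "o", color="tab:blue", ms=5)
    if fit is not None and fit.converged:
        grid = np.geomspace(conc.min(), conc.max(), 200)
        ax.semilogx(grid, _4pl(np.log10(grid), fit.bottom, fit.top, np.log10(fit.midpoint), fit.hill),
                    "-", color="tab:red")
        ax.axvline(fit.midpoint, ls=":", color="gray", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def viability_from_absorbance(table: pd.DataFrame) -> pd.DataFrame:
    """MTT absorbance table -> per-concentration viability (%).

    Expects columns ``role`` (treated/vehicle/blank), ``conc`` and
    ``absorbance``. Viability is
    ``100 * (A_treated - mean A_blank) / (mean A_vehicle - mean A_blank)``;
    replicate treated wells are averaged per concentration with an sd.
    Vehicle wells average 100% by construction.
    """
    for col in ("role", "absorbance"):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    blank = table.loc[table["role"] == "blank", "absorbance"]
    vehicle = table.loc[table["role"] == "vehicle", "absorbance"]
    if blank.empty or vehicle.empty:
        raise ValueError("need at least one vehicle and one blank well")
    a_blank = float(blank.mean())
    a_vehicle = float(vehicle.mean())
    window = a_vehicle - a_blank
    if window == 0:
        raise ValueError("vehicle and blank absorbances are equal; cannot normalize")
    treated = table[table["role"] == "treated"].copy()
    treated["viability"] = 100.0 * (treated["absorbance"] - a_blank) / window
    out = (
        treated.groupby("conc", sort=False)["viability"]
        .agg(viability_mean="mean", viability_sd="std", n="count")
        .reset_index()
    )
    return out


def fit_ic50(viability: pd.DataFrame, min_span: float = 10.0, unit: str = "uM") -> DoseResponseFit:
    """Fit the decreasing 4PL to per-concentration viability percentages."""
    return fit_4pl(
        viability["conc"].to_numpy(),
        viability["viability_mean"].to_numpy(),
        direction="decreasing",
        min_span=min_span,
        unit=unit,
    )


def ec50_from_plate(
    summaries,
    layout,
    controls,
    direction: str = "increasing",
    min_span: float = 10.0,
) -> dict[str, DoseResponseFit]:
    """Per-compound EC50 from well summaries on a dose plate.

    ``summaries`` maps well id -> WellSummary (or anything with
    ``pct_translocated``); activities are normalized against the plate
    controls, concentrations converted to uM, and one 4PL fitted per
    compound. Midpoints are reported in uM.
    """
    from .screening import normalize_activity  # local import avoids a cycle

    by_compound: dict[str, tuple[list[float], list[float]]] = {}
    for entry in layout.entries(roles=["compound"]):
        if entry.well not in summaries:
            continue
        pct = summaries[entry.well].pct_translocated
        if not np.isfinite(pct):
            continue
        concs, acts = by_compound.setdefault(entry.compound, ([], []))
        concs.append(conc_to_uM(entry.conc, entry.conc_unit))
        acts.append(normalize_activity(pct, controls))
    fits: dict[str, DoseResponseFit] = {}
    for compound, (concs, acts) in by_compound.items():
        fits[compound] = fit_4pl(
            np.asarray(concs), np.asarray(acts), direction=direction,
            min_span=min_span, unit="uM",
        )
    return fits
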