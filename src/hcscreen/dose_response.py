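"""Serial-dilution series, four-parameter logistic fitting, and validation calls.

The concentration-response model used throughout is the four-parameter
logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x) ** hill)

so that y -> bottom as x -> 0 and y -> top as x -> inf (for hill > 0).
Decreasing responses are represented by bottom > top rather than a negative
Hill exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError

__all__ = [
    "DilutionSeries",
    "DoseResponseFit",
    "ValidationCall",
    "four_param_logistic",
    "serial_dilution",
    "round_to_sig_figs",
    "fit_sigmoid",
    "classify_validated",
    "activity_vs_cellnumber",
]


def four_param_logistic(
    x: np.ndarray | float, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray | float:
    """Evaluate the 4PL model at concentration(s) ``x`` (must be > 0)."""
    x = np.asarray(x, dtype=float)
    out = bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DilutionSeries:
    """A strictly decreasing serial-dilution concentration ladder (mg/mL)."""

    concentrations: tuple[float, ...]
    dilution_factor: float
    start: float

    def __post_init__(self):
        conc = self.concentrations
        if len(conc) < 1 or any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive and non-empty")
        if any(b >= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.concentrations)

    def __iter__(self):
        return iter(self.concentrations)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)


def serial_dilution(start: float, factor: float, n_points: int) -> DilutionSeries:
    """Build an ``n_points``-long series: start, start/factor, start/factor^2, ...

    Raises ``ValueError`` for ``start <= 0``, ``factor <= 1`` or ``n_points < 1``.
    """
    if start <= 0:
        raise ValueError(f"start must be > 0, got {start}")
    if factor <= 1:
        raise ValueError(f"factor must be > 1, got {factor}")
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    conc = tuple(start / factor**i for i in range(n_points))
    return DilutionSeries(concentrations=conc, dilution_factor=float(factor), start=float(start))


def round_to_sig_figs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures (used to match printed tables)."""
    if x == 0:
        return 0.0
    if n < 1:
        raise ValueError("n must be >= 1")
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n - 1 - exponent)


@dataclass(frozen=True)
class DoseResponseFit:
    """Least-squares 4PL parameters for one dilution series."""

    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    rss: float
    degenerate: bool = False
    n_points: int = 0
    message: str = ""

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return four_param_logistic(x, self.bottom, self.top, self.ec50, self.hill)


def fit_sigmoid(
    series: DilutionSeries | Sequence[float],
    responses: Sequence[float],
) -> DoseResponseFit:
    """Fit the 4PL to (concentration, response) pairs by least squares.

    Missing responses (NaN) are dropped; at least four points at four distinct
    concentrations are required.  The optimisation runs on log-concentration
    with bounds ec50 in [min_conc/10, max_conc*10] and hill in [0.1, 10];
    bottom/top are unbounded.  Initial values: bottom = response at the lowest
    concentration, top = response at the highest, ec50 = geometric mid
    concentration, hill = 1.
    """
    conc = series.as_array() if isinstance(series, DilutionSeries) else np.asarray(series, float)
    y = np.asarray(responses, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    keep = np.isfinite(y)
    conc, y = conc[keep], y[keep]
    if conc.size < 4 or np.unique(conc).size < 4:
        raise InsufficientDataError(
            f"need >= 4 non-missing responses at >= 4 distinct concentrations, "
            f"got {conc.size} points at {np.unique(conc).size} concentrations"
        )

    log_c = np.log(conc)
    if np.ptp(y) == 0.0:
        # Flat response: every 4PL with top == bottom == y fits exactly.
        ec50 = float(np.exp(log_c.mean()))
        return DoseResponseFit(
            bottom=float(y[0]), top=float(y[0]), ec50=ec50, hill=1.0,
            converged=True, rss=0.0, degenerate=True, n_points=int(y.size),
            message="constant responses",
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        b, t, log_ec50, h = theta
        # (ec50/x)**h on the log scale avoids overflow for extreme ec50 guesses.
        return b + (t - b) / (1.0 + np.exp(h * (log_ec50 - log_c))) - y

    lo_ec, hi_ec = np.log(conc.min() / 10.0), np.log(conc.max() * 10.0)
    x0 = np.array([y[np.argmin(conc)], y[np.argmax(conc)], log_c.mean(), 1.0])
    result = least_squares(
        residuals,
        x0,
        bounds=([-np.inf, -np.inf, lo_ec, 0.1], [np.inf, np.inf, hi_ec, 10.0]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=20000,
    )
    b, t, log_ec50, h = result.x
    rss = float(np.sum(result.fun**2))
    scale = max(1.0, abs(t), abs(b))
    return DoseResponseFit(
        bottom=float(b),
        top=float(t),
        ec50=float(np.exp(log_ec50)),
        hill=float(h),
        converged=bool(result.success),
        rss=rss,
        degenerate=bool(abs(t - b) <= 1e-9 * scale),
        n_points=int(y.size),
        message=str(result.message),
    )


@dataclass(frozen=True)
class ValidationCall:
    """Outcome of the dual activity/viability criterion over a dilution series."""

    is_active: bool
    best_concentration: Optional[float] = None
    best_activity: Optional[float] = None
    n_qualifying: int = 0


def _point_frame(points) -> pd.DataFrame:
    df = pd.DataFrame(points)
    required = {"concentration", "activity", "cell_count"}
    missing = required - set(df.columns)
    if missing and not df.empty:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    for col in required - set(df.columns):
        df[col] = pd.Series(dtype=float)
    return df


def classify_validated(
    points,
    band,
    activity_threshold: float = 40.0,
) -> ValidationCall:
    """Decide whether any non-cytotoxic dilution exceeds the activity threshold.

    ``points`` is a table with columns concentration, activity, cell_count;
    ``band`` is a :class:`~hcscreen.hit_calling.ViabilityBand`.  The best
    qualifying dilution is the one of maximal activity, ties broken toward the
    lower (more potent) concentration.  Invariant to row order.
    """
    df = _point_frame(points)
    if df.empty:
        return ValidationCall(is_active=False)
    ok_count = df["cell_count"] >= band.floor
    if band.ceiling is not None:
        ok_count &= df["cell_count"] <= band.ceiling
    qualifying = df[ok_count & df["activity"].notna() & (df["activity"] > activity_threshold)]
    if qualifying.empty:
        return ValidationCall(is_active=False)
    best = qualifying.sort_values(
        ["activity", "concentration"], ascending=[False, True]
    ).iloc[0]
    return ValidationCall(
        is_active=True,
        best_concentration=float(best["concentration"]),
        best_activity=float(best["activity"]),
        n_qualifying=int(len(qualifying)),
    )


def activity_vs_cellnumber(points, band=None) -> pd.DataFrame:
    """Tidy diagnostic table: one row per dilution, highest concentration first.

    The cytotoxic flag comes from ``band`` when given (count below floor or,
    for two-sided bands, above ceiling); otherwise a missing activity marks
    the dilution as cytotoxic, mirroring instruments that withhold intensity
    readouts in highly cytotoxic wells.
    """
    df = _point_frame(points)
    if df.empty:
        return pd.DataFrame(columns=["concentration", "cell_count", "activity", "cytotoxic"])
    if band is not None:
        toxic = df["cell_count"] < band.floor
        if band.ceiling is not None:
            toxic |= df["cell_count"] > band.ceiling
    else:
        toxic = df["activity"].isna()
    out = df.assign(cytotoxic=toxic)[["concentration", "cell_count", "activity", "cytotoxic"]]
    return out.sort_values("concentration", ascending=False).reset_index(drop=True)
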