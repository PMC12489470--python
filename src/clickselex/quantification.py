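"""Gel-band metrics and ligation kinetics fitting.

Implements the study's measurement formulas:

* ligation percentage for a two-band lane,
  ``Lig% = 100 * lig / (lig + unlig)``;
* circularization yield and selectivity for a three-band lane,
  ``Y% = 100 * CP / (unlig + CP + LLP)`` and ``S% = 100 * CP / (CP + LLP)``
  (CP: circular product, LLP: linear ligated product);
* a bounded nonlinear least-squares fit of the single-turnover saturation
  model ``Y(t) = Y_max * (1 - exp(-k_obs * t))`` returning the observed
  rate constant k_obs (h^-1) and plateau yield Y_max (%).

The single-exponential form is the standard single-turnover ligation model
consistent with reporting a (k_obs, Y_max) pair; the loss is unweighted
least squares since no replicate variances are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic import TimeCourse

__all__ = [
    "GelQuant",
    "KineticsFit",
    "lig_percent",
    "circ_metrics",
    "fit_kinetics",
    "compare_constructs",
]

K_OBS_MAX = 10.0  # h^-1, upper box constraint for the fit


@dataclass(frozen=True)
class GelQuant:
    """Named band intensities for one gel lane (pre-quantified, arbitrary units)."""

    lane_label: str
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"lane {self.lane_label!r}: negative band intensity")
        if not any(v > 0 for v in self.intensities.values()):
            raise ValueError(f"lane {self.lane_label!r}: all band intensities zero")


@dataclass(frozen=True)
class KineticsFit:
    """Fitted first-order ligation parameters.

    ``no_activity`` flags an all-zero time course (control-like behavior);
    in that case the parameters are NaN and ``converged`` is False.
    """

    k_obs: float
    y_max: float
    rss: float
    converged: bool
    n_points: int
    no_activity: bool = False


def lig_percent(lig: float, unlig: float) -> float:
    """Ligated band as a percentage of total lane intensity."""
    if lig < 0 or unlig < 0:
        raise ValueError("band intensities must be >= 0")
    if lig + unlig == 0:
        raise ValueError("empty lane: both bands zero")
    return 100.0 * lig / (lig + unlig)


def circ_metrics(unlig: float, cp: float, llp: float) -> tuple[float, float]:
    """Circularization yield Y% and selectivity S% from a three-band lane.

    Y% is the circular product over the whole lane; S% is the circular
    product over all ligated products. S is undefined (NaN) when no
    ligation occurred at all (CP = LLP = 0), in which case Y = 0.
    """
    if unlig < 0 or cp < 0 or llp < 0:
        raise ValueError("band intensities must be >= 0")
    total = unlig + cp + llp
    if total == 0:
        raise ValueError("empty lane: all bands zero")
    y = 100.0 * cp / total
    s = 100.0 * cp / (cp + llp) if cp + llp > 0 else math.nan
    return y, s


# ---------------------------------------------------------------------------
# Kinetics


def _model(t: np.ndarray, k: float, ymax: float) -> np.ndarray:
    return ymax * (1.0 - np.exp(-k * t))


def _initial_k_grid(t: np.ndarray, y: np.ndarray, ymax0: float) -> list[float]:
    """Multi-start rate candidates: earliest-slope estimate + log grid."""
    starts = list(np.logspace(-3, 0.5, 5))
    # from the earliest positive observation: y ~ ymax * k * t for small kt
    pos = np.nonzero(y > 0)[0]
    if pos.size:
        i = pos[0]
        k0 = y[i] / (ymax0 * t[i])
        starts.append(float(np.clip(k0, 1e-6, K_OBS_MAX)))
    return starts


def fit_kinetics(tc: TimeCourse) -> KineticsFit:
    """Fit ``Y(t) = Y_max (1 - exp(-k_obs t))`` by bounded least squares.

    Box constraints k_obs in (0, 10] h^-1 and Y_max in (0, 100]%;
    multi-start initialization over a log-spaced rate grid plus an
    earliest-slope estimate, with Y_max started at the maximum observed
    value. Ties between starts are broken by lowest residual sum of
    squares, then lowest k_obs. A t = 0 observation is allowed; at least
    three distinct positive timepoints are required.
    """
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.ligation_percent, dtype=float)
    positive = t > 0
    if np.unique(t[positive]).size < 3:
        raise ValueError("need at least 3 distinct positive timepoints")
    if np.all(y == 0):
        return KineticsFit(
            math.nan, math.nan, 0.0, converged=False,
            n_points=t.size, no_activity=True,
        )
    ymax0 = float(np.clip(y.max(), 1e-3, 100.0))

    def residuals(params: np.ndarray) -> np.ndarray:
        return _model(t, params[0], params[1]) - y

    best: tuple[float, float, np.ndarray] | None = None  # (rss, k, params)
    success = False
    for k0 in _initial_k_grid(t, y, ymax0):
        result = least_squares(
            residuals,
            x0=[k0, ymax0],
            bounds=([1e-9, 1e-9], [K_OBS_MAX, 100.0]),
            method="trf",
        )
        rss = float(np.sum(result.fun**2))
        key = (rss, float(result.x[0]))
        if best is None or key < (best[0], best[1]):
            best = (rss, float(result.x[0]), result.x)
            success = bool(result.success)
    assert best is not None
    rss, _, params = best
    return KineticsFit(
        k_obs=float(params[0]),
        y_max=float(params[1]),
        rss=rss,
        converged=success,
        n_points=int(t.size),
    )


# ---------------------------------------------------------------------------
# Construct comparison


def compare_constructs(
    values, reference: str | None = None
) -> pd.DataFrame:
    """Rank construct activities relative to a reference (wild type).

    ``values`` maps construct label to its activity readout (Lig%, or a
    fitted parameter) — a mapping or an iterable of (label, value) pairs.
    The reference defaults to the first entry; the returned table carries
    the value and the relative-to-reference ratio, sorted by descending
    value.
    """
    pairs = list(values.items()) if hasattr(values, "items") else list(values)
    if not pairs:
        raise ValueError("need at least one construct")
    labels = [lb for lb, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate construct labels")
    values = dict(pairs)
    ref_label = reference if reference is not None else labels[0]
    if ref_label not in values:
        raise ValueError(f"reference {ref_label!r} not among constructs")
    ref_value = values[ref_label]
    table = pd.DataFrame(
        {
            "construct": labels,
            "value": [values[lb] for lb in labels],
        }
    )
    table["ratio_to_reference"] = (
        table["value"] / ref_value if ref_value != 0 else np.nan
    )
    return table.sort_values("value", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
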