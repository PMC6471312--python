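"""Scalar indicators of a reflectivity graph and its raw-profile envelope.

From the averaged graph rho(x) (analytic model) and the raw profile the
following family is computed:

* ``delta_rho = rho_max - rho_min`` and its envelope counterpart
  ``delta_rho_peak`` — absolute contrast of the graph / envelope;
* ``k = rho_max / rho_min`` and ``k_peak`` — dimensionless contrast
  ratios (k is close to 1 for a correctly fired sample and drifts away
  as the oven temperature drifts from the prescribed one);
* ``grad_max = max |d rho / d x|`` and ``curv_max = max |d^2 rho/d x^2|``
  over all model segments.

Graph extremes are taken analytically from the fitted model so that the
differential indicators refer to the same object; the envelope extremes
come from the unsmoothed profile, which also carries the high-spatial-
frequency granulation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .model import PiecewiseModel
from .profile import ReflectivityProfile

__all__ = [
    "ParameterSet",
    "graph_extremes",
    "envelope_extremes",
    "delta_rho",
    "delta_rho_peak",
    "ratio_k",
    "ratio_k_peak",
    "max_gradient",
    "max_curvature",
    "model_mean",
    "compute_parameters",
    "parameters_from_model",
    "parameter_table",
    "reproduce_tables",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "rho_min_peak",
    "rho_max_peak",
    "delta_rho_peak",
    "k_peak",
    "rho_min",
    "rho_max",
    "delta_rho",
    "k",
    "grad_max",
    "curv_max",
    "mean_level",
]


@dataclass(frozen=True)
class ParameterSet:
    rho_min: float
    rho_max: float
    rho_min_peak: float
    rho_max_peak: float
    delta_rho: float
    delta_rho_peak: float
    k: float
    k_peak: float
    grad_max: float
    curv_max: float
    mean_level: float

    def __post_init__(self) -> None:
        if self.delta_rho < 0 or self.delta_rho_peak < 0:
            raise ValueError("contrast differences must be nonnegative")

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def graph_extremes(model: PiecewiseModel) -> tuple[float, float]:
    """Global (min, max) of the model, from vertices and interval ends."""
    lo, hi = np.inf, -np.inf
    for seg in model.segments:
        xs = [seg.x_lo, seg.x_hi]
        v = seg.vertex()
        if v is not None and seg.x_lo <= v <= seg.x_hi:
            xs.append(v)
        vals = [float(seg.value(x)) for x in xs]
        lo = min(lo, *vals)
        hi = max(hi, *vals)
    return lo, hi


def envelope_extremes(raw: ReflectivityProfile) -> tuple[float, float]:
    """(min, max) of the unsmoothed profile, envelope of the graph."""
    return float(np.min(raw.rho)), float(np.max(raw.rho))


def delta_rho(rho_max: float, rho_min: float) -> float:
    """Graph contrast rho_max - rho_min (gray levels)."""
    if rho_min < 0 or rho_max < rho_min:
        raise ValueError("require rho_max >= rho_min >= 0")
    return rho_max - rho_min


def delta_rho_peak(rho_max_peak: float, rho_min_peak: float) -> float:
    """Envelope contrast (rho_max)_peak - (rho_min)_peak (gray levels)."""
    return delta_rho(rho_max_peak, rho_min_peak)


def ratio_k(rho_max: float, rho_min: float) -> float:
    """Contrast ratio k = rho_max / rho_min (dimensionless)."""
    if rho_min < 0 or rho_max < rho_min:
        raise ValueError("require rho_max >= rho_min >= 0")
    if rho_min == 0:
        raise ValueError("k is undefined for rho_min = 0")
    return rho_max / rho_min


def ratio_k_peak(rho_max_peak: float, rho_min_peak: float) -> float:
    """Envelope contrast ratio (rho_max)_peak / (rho_min)_peak."""
    return ratio_k(rho_max_peak, rho_min_peak)


def max_gradient(model: PiecewiseModel) -> float:
    """max |d rho / d x| over all segments (gray levels / mm).

    The derivative of each quadratic piece is affine, so the maximum of
    its absolute value is attained at an interval endpoint.
    """
    return max(
        max(abs(float(seg.deriv1(seg.x_lo))), abs(float(seg.deriv1(seg.x_hi))))
        for seg in model.segments
    )


def max_curvature(model: PiecewiseModel) -> float:
    """max |d^2 rho / d x^2| = max |2 a| over segments (gray levels/mm^2)."""
    return max(abs(2.0 * seg.a) for seg in model.segments)


def model_mean(model: PiecewiseModel) -> float:
    """Mean level of the averaged graph, by exact segment integration."""
    total = 0.0
    for s in model.segments:
        total += (
            s.a / 3.0 * (s.x_hi**3 - s.x_lo**3)
            + s.b / 2.0 * (s.x_hi**2 - s.x_lo**2)
            + s.c * (s.x_hi - s.x_lo)
        )
    return total / model.x_max


def compute_parameters(
    raw: ReflectivityProfile,
    model: PiecewiseModel,
    extremes_from: str = "model",
    smoothed: ReflectivityProfile | None = None,
) -> ParameterSet:
    """Full parameter set from a raw profile and its fitted model.

    ``extremes_from="model"`` (default) takes rho_min/rho_max from the
    analytic model; ``"smoothed"`` takes them from the smoothed profile
    samples instead (requires ``smoothed``).
    """
    if extremes_from == "model":
        rmin, rmax = graph_extremes(model)
    elif extremes_from == "smoothed":
        if smoothed is None:
            raise ValueError("smoothed profile required for extremes_from='smoothed'")
        rmin, rmax = float(np.min(smoothed.rho)), float(np.max(smoothed.rho))
    else:
        raise ValueError("extremes_from must be 'model' or 'smoothed'")
    pmin, pmax = envelope_extremes(raw)
    return ParameterSet(
        rho_min=rmin,
        rho_max=rmax,
        rho_min_peak=pmin,
        rho_max_peak=pmax,
        delta_rho=delta_rho(rmax, rmin),
        delta_rho_peak=delta_rho_peak(pmax, pmin),
        k=ratio_k(rmax, rmin),
        k_peak=ratio_k_peak(pmax, pmin),
        grad_max=max_gradient(model),
        curv_max=max_curvature(model),
        mean_level=model_mean(model),
    )


def parameters_from_model(model: PiecewiseModel) -> ParameterSet:
    """Parameter set of a noise-free graph: the envelope collapses onto
    the graph, so the peak extremes equal the graph extremes."""
    rmin, rmax = graph_extremes(model)
    return ParameterSet(
        rho_min=rmin,
        rho_max=rmax,
        rho_min_peak=rmin,
        rho_max_peak=rmax,
        delta_rho=delta_rho(rmax, rmin),
        delta_rho_peak=delta_rho(rmax, rmin),
        k=ratio_k(rmax, rmin),
        k_peak=ratio_k(rmax, rmin),
        grad_max=max_gradient(model),
        curv_max=max_curvature(model),
        mean_level=model_mean(model),
    )


def parameter_table(entries) -> pd.DataFrame:
    """One row of rounded parameters per (label, raw profile, model)."""
    entries = list(entries)
    if not entries:
        raise ValueError("parameter_table needs at least one entry")
    rows = {}
    for label, raw, model in entries:
        rows[label] = compute_parameters(raw, model).rounded(2)
    return pd.DataFrame.from_dict(rows, orient="index")[TABLE_COLUMNS]


def reproduce_tables() -> dict[str, pd.DataFrame]:
    """Recompute the study's per-group indicator tables.

    The envelope/graph extreme readings of each group are combined with
    its built analytic model: contrasts and ratios come from the
    readings via the scalar operations, the differential indicators from
    the model.  Returns one table per cohort, values rounded to two
    decimals as in the study.
    """
    from .groups import GROUPS

    tables: dict[str, dict] = {"pressed": {}, "metal": {}}
    for g in GROUPS.values():
        model = g.build()
        tables[g.cohort][g.label] = {
            "rho_min_peak": g.rho_min_peak,
            "rho_max_peak": g.rho_max_peak,
            "delta_rho_peak": round(delta_rho_peak(g.rho_max_peak, g.rho_min_peak), 2),
            "k_peak": round(ratio_k_peak(g.rho_max_peak, g.rho_min_peak), 2),
            "rho_min": g.rho_min,
            "rho_max": g.rho_max,
            "delta_rho": round(delta_rho(g.rho_max, g.rho_min), 2),
            "k": round(ratio_k(g.rho_max, g.rho_min), 2),
            "grad_max": round(max_gradient(model), 2),
            "curv_max": round(max_curvature(model), 2),
        }
    return {
        cohort: pd.DataFrame.from_dict(rows, orient="index")
        for cohort, rows in tables.items()
    }
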