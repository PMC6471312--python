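"""Piecewise analytic models of en-face OCT reflectivity graphs.

The y-averaged, smoothed reflectivity graph rho(x) of a sintered ceramic
sample is well described by a small family of piecewise shapes built from
at most three quadratic segments.  Each segment is a parabola pinned by a
pass-through point and a stationary point (vertex), so the model anchors
are directly readable off the graph: the edge reflectivity rho0, the
extreme values rho_min / rho_max, and the abscissae where they occur.

Archetypes
----------
``valley``
    Two parabolas sharing a vertex at the global minimum: a dip from
    (0, rho0) down to (x_m, rho_min) and a rise to (x_max, rho_max).
``hump_valley``
    A parabola from (0, rho0) with a local-maximum vertex (x_M, rho_max),
    switching at the breakpoint x_i to a second parabola with its own
    vertex (x_m, rho_min).
``oscillation``
    Three congruent parabolas on thirds of [0, x_max], alternating
    vertices at rho0 - A, rho0 + A, rho0 - A (amplitude A), continuous and
    equal to rho0 at the two third-points.
``ramp_plateau``
    A parabola from (0, rho0) with vertex (x_i, rho_i), then constant
    rho_i up to x_max.
``linear_ramp``
    A single line from (0, rho0) to (x_max, rho_max).
``flat``
    A constant rho0.

All reflectivities are in 8-bit gray levels, abscissae in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ARCHETYPES",
    "AnchorSet",
    "Segment",
    "PiecewiseModel",
    "parabola_point_vertex",
    "build_model",
    "evaluate",
    "gradient",
    "curvature",
    "fit_model",
    "fit_best",
    "select_archetype",
    "model_to_dict",
    "model_from_dict",
    "scale_model",
]

ARCHETYPES = (
    "valley",
    "hump_valley",
    "oscillation",
    "ramp_plateau",
    "linear_ramp",
    "flat",
)

#: free parameters per archetype, used by the model-selection penalty
N_PARAMS = {
    "flat": 1,
    "linear_ramp": 2,
    "oscillation": 2,
    "ramp_plateau": 3,
    "valley": 4,
    "hump_valley": 7,
}

#: maximum allowed jump at an interior breakpoint of a built model
#: (gray levels; printed anchors are rounded to ~unit precision)
CONTINUITY_TOL = 0.5


@dataclass(frozen=True)
class AnchorSet:
    """Anchor points that pin a piecewise reflectivity model.

    Only the fields required by the target archetype need to be set; the
    builders raise a ``ValueError`` naming any missing symbol.
    """

    rho0: float | None = None      #: reflectivity at x = 0
    rho_min: float | None = None   #: minimum of the averaged graph
    rho_max: float | None = None   #: maximum of the averaged graph
    x_m: float | None = None       #: abscissa of the minimum vertex (mm)
    x_M: float | None = None       #: abscissa of the local-maximum vertex (mm)
    x_i: float | None = None       #: interior breakpoint (mm)
    x_max: float = 3.25            #: right end of the domain (mm)
    A: float | None = None         #: oscillation amplitude (gray levels)
    rho_i: float | None = None     #: reflectivity at x_i (pass-through value)

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass(frozen=True)
class Segment:
    """One analytic piece: a*x^2 + b*x + c on [x_lo, x_hi).

    The final segment of a model is closed at its right end.
    """

    x_lo: float
    x_hi: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.x_lo < self.x_hi:
            raise ValueError(f"empty segment interval [{self.x_lo}, {self.x_hi})")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        return (self.a * x + self.b) * x + self.c

    def deriv1(self, x):
        x = np.asarray(x, dtype=float)
        return 2.0 * self.a * x + self.b

    def deriv2(self, x):
        x = np.asarray(x, dtype=float)
        return np.full_like(x, 2.0 * self.a)

    def vertex(self) -> float | None:
        """Stationary-point abscissa, or None for a linear/constant piece."""
        if self.a == 0.0:
            return None
        return -self.b / (2.0 * self.a)


@dataclass(frozen=True)
class PiecewiseModel:
    """Ordered contiguous segments covering [0, x_max]."""

    segments: tuple[Segment, ...]
    archetype: str

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("model needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if abs(self.segments[0].x_lo) > 1e-12:
            raise ValueError("first segment must start at x = 0")
        for left, right in zip(self.segments, self.segments[1:]):
            if abs(left.x_hi - right.x_lo) > 1e-9:
                raise ValueError("segments must be contiguous")

    @property
    def x_max(self) -> float:
        return self.segments[-1].x_hi

    def _check_domain(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < -1e-9) or np.any(x > self.x_max + 1e-9):
            raise ValueError(f"x outside model domain [0, {self.x_max}]")
        return x

    def _segment_index(self, x: np.ndarray) -> np.ndarray:
        # half-open [lo, hi) pieces; the last interval is closed at x_max
        bounds = np.array([s.x_hi for s in self.segments[:-1]])
        return np.searchsorted(bounds, x, side="right")

    def _piecewise(self, x, attr: str):
        x = self._check_domain(x)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        idx = self._segment_index(xv)
        out = np.empty_like(xv)
        for i, seg in enumerate(self.segments):
            mask = idx == i
            if np.any(mask):
                out[mask] = getattr(seg, attr)(xv[mask])
        return float(out[0]) if scalar else out

    def evaluate(self, x):
        return self._piecewise(x, "value")

    def gradient(self, x):
        return self._piecewise(x, "deriv1")

    def curvature(self, x):
        return self._piecewise(x, "deriv2")


def evaluate(model: PiecewiseModel, x):
    """Reflectivity of the segment containing ``x`` (gray levels)."""
    return model.evaluate(x)


def gradient(model: PiecewiseModel, x):
    """d rho / d x of the segment containing ``x`` (gray levels / mm)."""
    return model.gradient(x)


def curvature(model: PiecewiseModel, x):
    """d^2 rho / d x^2 of the segment containing ``x`` (gray levels / mm^2)."""
    return model.curvature(x)


def parabola_point_vertex(
    point: tuple[float, float], vertex: tuple[float, float]
) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the parabola through ``point`` with
    stationary point at ``vertex``.

    a = (rho - rho_v) / (x - x_v)^2, b = -2 a x_v, c = rho_v + a x_v^2.
    A coincident point and vertex with equal values degenerates to the
    constant rho_v; unequal values admit no solution.
    """
    x, rho = float(point[0]), float(point[1])
    xv, rv = float(vertex[0]), float(vertex[1])
    if np.isclose(x, xv):
        if np.isclose(rho, rv):
            return 0.0, 0.0, rv
        raise ValueError(
            "no parabola has its vertex at the pass-through abscissa with a "
            "different value"
        )
    a = (rho - rv) / (x - xv) ** 2
    return a, -2.0 * a * xv, rv + a * xv * xv


def _segment_from_vertex(
    x_lo: float, x_hi: float, point: tuple[float, float], vertex: tuple[float, float]
) -> Segment:
    a, b, c = parabola_point_vertex(point, vertex)
    return Segment(x_lo, x_hi, a, b, c)


def _require(anchors: AnchorSet, names: Sequence[str], archetype: str) -> None:
    missing = [n for n in names if getattr(anchors, n) is None]
    if missing:
        raise ValueError(
            f"archetype {archetype!r} needs anchors: missing {', '.join(missing)}"
        )


def _check_continuity(segments: Sequence[Segment]) -> None:
    for left, right in zip(segments, segments[1:]):
        xb = left.x_hi
        gap = abs(left.value(xb) - right.value(xb))
        if gap > CONTINUITY_TOL + 1e-9:
            raise ValueError(
                f"segments discontinuous at x = {xb:g}: jump of {gap:.3g} gray levels"
            )


def build_model(archetype: str, anchors: AnchorSet) -> PiecewiseModel:
    """Construct the analytic model of an archetype from its anchors.

    Raises ``ValueError`` for an unknown archetype, missing anchors, or a
    breakpoint discontinuity beyond half a gray level.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    x_max = float(anchors.x_max)
    if x_max <= 0:
        raise ValueError("x_max must be positive")

    if archetype == "flat":
        _require(anchors, ["rho0"], archetype)
        segs = [Segment(0.0, x_max, 0.0, 0.0, float(anchors.rho0))]

    elif archetype == "linear_ramp":
        _require(anchors, ["rho0", "rho_max"], archetype)
        slope = (float(anchors.rho_max) - float(anchors.rho0)) / x_max
        segs = [Segment(0.0, x_max, 0.0, slope, float(anchors.rho0))]

    elif archetype == "valley":
        _require(anchors, ["rho0", "rho_min", "rho_max", "x_m"], archetype)
        x_m = float(anchors.x_m)
        if not 0.0 < x_m < x_max:
            raise ValueError("valley vertex x_m must lie strictly inside (0, x_max)")
        v = (x_m, float(anchors.rho_min))
        segs = [
            _segment_from_vertex(0.0, x_m, (0.0, float(anchors.rho0)), v),
            _segment_from_vertex(x_m, x_max, (x_max, float(anchors.rho_max)), v),
        ]

    elif archetype == "hump_valley":
        _require(
            anchors, ["rho0", "rho_min", "rho_max", "x_m", "x_M", "x_i"], archetype
        )
        x_M, x_i, x_m = float(anchors.x_M), float(anchors.x_i), float(anchors.x_m)
        if not 0.0 < x_M < x_i:
            raise ValueError("hump vertex x_M must lie in (0, x_i)")
        if not x_i <= x_m <= x_max:
            raise ValueError("second vertex x_m must lie in [x_i, x_max]")
        f = _segment_from_vertex(
            0.0, x_i, (0.0, float(anchors.rho0)), (x_M, float(anchors.rho_max))
        )
        rho_i = float(anchors.rho_i) if anchors.rho_i is not None else float(f.value(x_i))
        g = _segment_from_vertex(
            x_i, x_max, (x_i, rho_i), (x_m, float(anchors.rho_min))
        )
        segs = [f, g]

    elif archetype == "ramp_plateau":
        _require(anchors, ["rho0", "x_i", "rho_i"], archetype)
        x_i, rho_i = float(anchors.x_i), float(anchors.rho_i)
        if not 0.0 < x_i < x_max:
            raise ValueError("plateau onset x_i must lie strictly inside (0, x_max)")
        segs = [
            _segment_from_vertex(0.0, x_i, (0.0, float(anchors.rho0)), (x_i, rho_i)),
            Segment(x_i, x_max, 0.0, 0.0, rho_i),
        ]

    elif archetype == "oscillation":
        _require(anchors, ["rho0", "A"], archetype)
        rho0, A = float(anchors.rho0), float(anchors.A)
        b1, b2 = x_max / 3.0, 2.0 * x_max / 3.0
        segs = [
            _segment_from_vertex(0.0, b1, (0.0, rho0), (x_max / 6.0, rho0 - A)),
            _segment_from_vertex(b1, b2, (b1, rho0), (x_max / 2.0, rho0 + A)),
            _segment_from_vertex(b2, x_max, (b2, rho0), (5.0 * x_max / 6.0, rho0 - A)),
        ]

    _check_continuity(segs)
    return PiecewiseModel(tuple(segs), archetype)


# ---------------------------------------------------------------------------
# least-squares fitting


def _profile_arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    """Accept a ReflectivityProfile or an (x, rho) pair."""
    if hasattr(profile, "x") and hasattr(profile, "rho"):
        x, rho = profile.x, profile.rho
    else:
        x, rho = profile
    x = np.asarray(x, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if x.ndim != 1 or x.shape != rho.shape:
        raise ValueError("profile must provide matching 1-D x and rho arrays")
    if np.any(np.diff(x) <= 0):
        raise ValueError("profile abscissae must be strictly increasing")
    return x, rho


def _lstsq(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _fit_flat(x, rho, x_max):
    c = float(np.mean(rho))
    sse = float(np.sum((rho - c) ** 2))
    model = PiecewiseModel((Segment(0.0, x_max, 0.0, 0.0, c),), "flat")
    return model, AnchorSet(rho0=c, x_max=x_max), sse


def _fit_linear(x, rho, x_max):
    design = np.column_stack([x, np.ones_like(x)])
    (b, c), sse = _lstsq(design, rho)
    model = PiecewiseModel((Segment(0.0, x_max, 0.0, b, c),), "linear_ramp")
    anchors = AnchorSet(rho0=c, rho_max=c + b * x_max, x_max=x_max)
    return model, anchors, sse


def _fit_valley(x, rho, x_max):
    # rho = rho_min + a1 (x - x_m)^2 on [0, x_m), + a2 (x - x_m)^2 beyond;
    # shared vertex (x_m, rho_min); x_m searched over profile abscissae
    best = None
    for x_m in x[2:-2]:
        left = x < x_m
        if left.sum() < 2 or (~left).sum() < 2:
            continue
        d2 = (x - x_m) ** 2
        design = np.column_stack([np.ones_like(x), d2 * left, d2 * ~left])
        coef, sse = _lstsq(design, rho)
        if best is None or sse < best[1]:
            best = (coef, sse, float(x_m))
    if best is None:
        raise ValueError("too few points to place a valley breakpoint")
    (rho_min, a1, a2), sse, x_m = best
    segs = (
        Segment(0.0, x_m, a1, -2 * a1 * x_m, rho_min + a1 * x_m**2),
        Segment(x_m, x_max, a2, -2 * a2 * x_m, rho_min + a2 * x_m**2),
    )
    model = PiecewiseModel(segs, "valley")
    anchors = AnchorSet(
        rho0=float(segs[0].value(0.0)),
        rho_min=float(rho_min),
        rho_max=float(segs[1].value(x_max)),
        x_m=x_m,
        x_max=x_max,
    )
    return model, anchors, sse


def _clip_vertex(seg: Segment, default: float) -> float:
    v = seg.vertex()
    if v is None:
        return default
    return float(np.clip(v, seg.x_lo, seg.x_hi))


def _fit_hump_valley(x, rho, x_max):
    # unconstrained quadratic on each side of a searched breakpoint
    best = None
    for x_i in x[3:-3]:
        left = x < x_i
        if left.sum() < 3 or (~left).sum() < 3:
            continue
        cl, ssel = _lstsq(np.column_stack([x[left] ** 2, x[left], np.ones(left.sum())]), rho[left])
        r = ~left
        cr, sser = _lstsq(np.column_stack([x[r] ** 2, x[r], np.ones(r.sum())]), rho[r])
        sse = ssel + sser
        if best is None or sse < best[0]:
            best = (sse, float(x_i), cl, cr)
    if best is None:
        raise ValueError("too few points to place a hump/valley breakpoint")
    sse, x_i, (a1, b1, c1), (a2, b2, c2) = best
    f = Segment(0.0, x_i, a1, b1, c1)
    g = Segment(x_i, x_max, a2, b2, c2)
    model = PiecewiseModel((f, g), "hump_valley")
    x_M = _clip_vertex(f, x_i / 2.0)
    x_m = _clip_vertex(g, (x_i + x_max) / 2.0)
    anchors = AnchorSet(
        rho0=float(f.value(0.0)),
        rho_max=float(f.value(x_M)),
        rho_min=float(g.value(x_m)),
        x_M=x_M,
        x_m=x_m,
        x_i=x_i,
        rho_i=float(g.value(x_i)),
        x_max=x_max,
    )
    return model, anchors, sse


def _fit_ramp_plateau(x, rho, x_max):
    # rho = rho_i + a (x - x_i)^2 before the onset, rho_i after
    best = None
    for x_i in x[2:-2]:
        left = x < x_i
        if left.sum() < 2 or (~left).sum() < 2:
            continue
        d2 = (x - x_i) ** 2 * left
        design = np.column_stack([np.ones_like(x), d2])
        coef, sse = _lstsq(design, rho)
        if best is None or sse < best[1]:
            best = (coef, sse, float(x_i))
    if best is None:
        raise ValueError("too few points to place a plateau onset")
    (rho_i, a), sse, x_i = best
    segs = (
        Segment(0.0, x_i, a, -2 * a * x_i, rho_i + a * x_i**2),
        Segment(x_i, x_max, 0.0, 0.0, rho_i),
    )
    model = PiecewiseModel(segs, "ramp_plateau")
    anchors = AnchorSet(
        rho0=float(segs[0].value(0.0)), rho_i=float(rho_i), x_i=x_i, x_max=x_max
    )
    return model, anchors, sse


def _oscillation_basis(x: np.ndarray, x_max: float) -> np.ndarray:
    # model = rho0 + A * phi(x); phi is -1 at the outer vertices, +1 at the
    # central one, 0 at the third-points
    b1, b2 = x_max / 3.0, 2.0 * x_max / 3.0
    phi = np.empty_like(x)
    m1 = x < b1
    m2 = (x >= b1) & (x < b2)
    m3 = x >= b2
    s = 36.0 / x_max**2
    phi[m1] = s * (x[m1] - x_max / 6.0) ** 2 - 1.0
    phi[m2] = 1.0 - s * (x[m2] - x_max / 2.0) ** 2
    phi[m3] = s * (x[m3] - 5.0 * x_max / 6.0) ** 2 - 1.0
    return phi


def _fit_oscillation(x, rho, x_max):
    phi = _oscillation_basis(x, x_max)
    design = np.column_stack([np.ones_like(x), phi])
    (rho0, A), sse = _lstsq(design, rho)
    model = build_model("oscillation", AnchorSet(rho0=rho0, A=A, x_max=x_max))
    return model, AnchorSet(rho0=float(rho0), A=float(A), x_max=x_max), sse


_FITTERS = {
    "flat": _fit_flat,
    "linear_ramp": _fit_linear,
    "valley": _fit_valley,
    "hump_valley": _fit_hump_valley,
    "ramp_plateau": _fit_ramp_plateau,
    "oscillation": _fit_oscillation,
}


def fit_model(
    profile, archetype: str, x_max: float | None = None
) -> tuple[PiecewiseModel, AnchorSet, float]:
    """Least-squares fit of one archetype to a (smoothed) profile.

    Breakpoints are searched exhaustively over the profile abscissae;
    segment coefficients are solved by nested linear least squares, so the
    fit is deterministic.  ``x_max`` defaults to the last abscissa; pass
    the image extent when fitting pixel-center profiles.

    Returns ``(model, anchors, sse)``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    x, rho = _profile_arrays(profile)
    if x.size < 8:
        raise ValueError("need at least 8 profile points to fit")
    if x_max is None:
        x_max = float(x[-1])
    if x[-1] > x_max + 1e-9:
        raise ValueError("profile extends beyond x_max")
    return _FITTERS[archetype](x, rho, float(x_max))


def fit_best(
    profile, x_max: float | None = None, n_eff: float | None = None
) -> tuple[str, PiecewiseModel, AnchorSet, float]:
    """Fit every archetype and pick the best by penalized SSE.

    The penalty inflates the SSE by the parameter count with the
    AIC-equivalent factor ``sse * exp(2 p / n_eff)``; exact ties go to
    the simpler archetype.  ``n_eff`` is the number of statistically
    independent samples: a moving-average-smoothed profile of length n
    carries only about n/window of them, and the profile's recorded
    smoothing window is used to discount n accordingly.
    """
    x, rho = _profile_arrays(profile)
    n = x.size
    if n_eff is None:
        window = getattr(profile, "window", None)
        n_eff = n / window if window else n
    n_eff = max(float(n_eff), 8.0)
    # SSEs at numerical-noise level are indistinguishable: floor them to
    # zero so exact fits tie and the tie-break picks the simpler shape
    sse_floor = 1e-10 * n * max(1.0, float(np.mean(np.square(rho))))
    results = []
    for arch in ARCHETYPES:
        try:
            model, anchors, sse = fit_model((x, rho), arch, x_max=x_max)
        except ValueError:
            continue
        effective_sse = 0.0 if sse < sse_floor else sse
        penalized = effective_sse * float(np.exp(2.0 * N_PARAMS[arch] / n_eff))
        results.append((penalized, N_PARAMS[arch], arch, model, anchors, sse))
    if not results:
        raise ValueError("no archetype could be fitted to this profile")
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    _, _, arch, model, anchors, sse = results[0]
    return arch, model, anchors, sse


def select_archetype(
    profile, x_max: float | None = None, n_eff: float | None = None
) -> str:
    """Archetype with minimal parameter-count-penalized SSE."""
    return fit_best(profile, x_max=x_max, n_eff=n_eff)[0]


# ---------------------------------------------------------------------------
# serialization and helpers


def model_to_dict(model: PiecewiseModel, anchors: AnchorSet | None = None) -> dict:
    payload = {
        "archetype": model.archetype,
        "segments": [
            {"x_lo": s.x_lo, "x_hi": s.x_hi, "a": s.a, "b": s.b, "c": s.c}
            for s in model.segments
        ],
    }
    if anchors is not None:
        payload["anchors"] = anchors.as_dict()
    return payload


def model_from_dict(payload: dict) -> tuple[PiecewiseModel, AnchorSet | None]:
    segs = tuple(
        Segment(s["x_lo"], s["x_hi"], s["a"], s["b"], s["c"])
        for s in payload["segments"]
    )
    model = PiecewiseModel(segs, payload["archetype"])
    anchors = AnchorSet(**payload["anchors"]) if "anchors" in payload else None
    return model, anchors


def save_model(model: PiecewiseModel, path, anchors: AnchorSet | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model, anchors), fh, indent=2)


def load_model(path) -> tuple[PiecewiseModel, AnchorSet | None]:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def scale_model(model: PiecewiseModel, s: float) -> PiecewiseModel:
    """Multiply all reflectivities by ``s > 0`` (homogeneity helper)."""
    if s <= 0:
        raise ValueError("scale must be positive")
    segs = tuple(
        Segment(g.x_lo, g.x_hi, g.a * s, g.b * s, g.c * s) for g in model.segments
    )
    return PiecewiseModel(segs, model.archetype)
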