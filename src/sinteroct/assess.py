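"""Rule-based firing verdict and parameter-consistency ranking.

A correctly fired sample has a nearly homogeneous granulation, so the
contrast ratio k = rho_max/rho_min of its averaged reflectivity graph is
close to 1; k drifts away from 1 as the oven temperature drifts from
the prescribed one, in either direction.  The verdict therefore hinges
on |k - 1| against a material-calibrated band, with direction cues from
qualitative evidence: a low mean reflectivity indicates under-firing
(incomplete sintering), a raised mean or a tilted (linear, rising)
graph indicates over-firing.

The decision thresholds are engineering configuration, not physical
constants: they must be calibrated per ceramic material, and every
report records the configuration it used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .model import PiecewiseModel
from .params import ParameterSet, model_mean

__all__ = [
    "Thresholds",
    "AssessmentReport",
    "ReportBundle",
    "default_thresholds",
    "assess",
    "rank_by_consistency",
    "report",
]

VERDICTS = ("normal", "under_fired", "over_fired", "indeterminate")


@dataclass(frozen=True)
class Thresholds:
    """Decision configuration for :func:`assess`.

    ``normal_band``/``severe_band`` act on the deviation |k - 1|;
    ``low_level_cut``/``high_level_cut`` are fractions of
    ``reference_level`` (the mean graph level of a correctly fired
    sample of the same material) when ``relative_cuts`` is true,
    absolute gray levels otherwise.
    """

    normal_band: float = 0.45
    severe_band: float = 1.0
    low_level_cut: float = 0.9
    high_level_cut: float = 1.1
    reference_level: float | None = None
    relative_cuts: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def default_thresholds(cohort: str = "pressed") -> Thresholds:
    """Material-calibrated defaults for the two study cohorts.

    The reference level is the mean of the correctly fired group's
    analytic graph, computed at call time from the built-in anchors.
    The metal-ceramic normal band is tighter because that cohort's
    correctly fired k is 1.00 while its mildest deviations sit near 1.2.
    """
    from .groups import GROUPS

    if cohort == "pressed":
        ref = model_mean(GROUPS["N"].build())
        return Thresholds(normal_band=0.45, reference_level=ref)
    if cohort == "metal":
        ref = model_mean(GROUPS["N_metal"].build())
        return Thresholds(normal_band=0.15, reference_level=ref)
    raise ValueError("cohort must be 'pressed' or 'metal'")


@dataclass(frozen=True)
class AssessmentReport:
    verdict: str
    severity: str                 #: "mild" | "severe" | "n/a"
    k: float
    k_deviation: float
    evidence: tuple[str, ...]
    thresholds_used: Thresholds
    label: str = ""

    def as_dict(self) -> dict:
        d = asdict(self)
        d["evidence"] = list(self.evidence)
        return d


def assess(
    params: ParameterSet, model: PiecewiseModel, config: Thresholds | None = None
) -> AssessmentReport:
    """Verdict for one sample from its parameters and fitted model."""
    cfg = config or Thresholds()
    flags: list[str] = []

    if model.archetype == "flat" or params.delta_rho == 0:
        flags.append("flat_graph")
    tilted = (
        model.archetype == "linear_ramp"
        and float(model.gradient(0.0)) > 0
        and params.delta_rho > 0
    )
    if tilted:
        flags.append("tilted_linear_graph")
    if model.archetype == "oscillation":
        flags.append("banded_alternation")

    if cfg.relative_cuts:
        if cfg.reference_level is None:
            raise ValueError(
                "relative level cuts require a reference_level in the thresholds"
            )
        low_cut = cfg.low_level_cut * cfg.reference_level
        high_cut = cfg.high_level_cut * cfg.reference_level
    else:
        low_cut, high_cut = cfg.low_level_cut, cfg.high_level_cut
    if params.mean_level < low_cut:
        flags.append("low_mean_level")
    elif params.mean_level > high_cut:
        flags.append("high_mean_level")

    kdev = abs(params.k - 1.0)
    if kdev <= cfg.normal_band:
        verdict, severity = "normal", "n/a"
    elif tilted:
        verdict, severity = "over_fired", "severe"
    else:
        low = "low_mean_level" in flags
        high = "high_mean_level" in flags
        if low and not high:
            verdict = "under_fired"
        elif high and not low:
            verdict = "over_fired"
        else:
            verdict = "indeterminate"
        severity = "severe" if kdev > cfg.severe_band else "mild"
    return AssessmentReport(
        verdict=verdict,
        severity=severity,
        k=params.k,
        k_deviation=kdev,
        evidence=tuple(flags),
        thresholds_used=cfg,
    )


# ---------------------------------------------------------------------------
# consistency ranking


def _branch_tau(values: pd.Series, offsets: pd.Series) -> float | None:
    """Kendall tau-a of value vs |offset| over pairs with distinct |offset|."""
    absoff = offsets.abs().to_numpy(dtype=float)
    vals = values.to_numpy(dtype=float)
    num, pairs = 0.0, 0
    for i, j in combinations(range(len(vals)), 2):
        d_off = absoff[i] - absoff[j]
        if d_off == 0:
            continue
        pairs += 1
        num += np.sign(vals[i] - vals[j]) * np.sign(d_off)
    if pairs == 0:
        return None
    return num / pairs


def rank_by_consistency(cohorts) -> list[str]:
    """Order parameter names by monotone consistency with |temperature offset|.

    Each cohort is a DataFrame with an ``offset_c`` column (degC from the
    prescribed temperature) plus numeric parameter columns.  Within a
    cohort the concordance is computed separately on the under-fired
    branch (offset <= 0) and the over-fired branch (offset >= 0) — a
    consistent indicator grows as the temperature departs from normal in
    either direction — as Kendall tau-a of parameter value against
    |offset|, then averaged over branches and cohorts.  Ties are broken
    alphabetically.
    """
    cohorts = list(cohorts)
    if len(cohorts) < 2:
        raise ValueError("rank_by_consistency needs at least two cohorts")
    names: list[str] = []
    for table in cohorts:
        if "offset_c" not in table.columns:
            raise ValueError("each cohort table needs an 'offset_c' column")
        for c in table.columns:
            if c != "offset_c" and c not in names:
                names.append(c)
    scores: dict[str, list[float]] = {n: [] for n in names}
    for table in cohorts:
        off = table["offset_c"].astype(float)
        for name in names:
            if name not in table.columns:
                continue
            taus = []
            for branch in (table[off <= 0], table[off >= 0]):
                if len(branch) < 2:
                    continue
                tau = _branch_tau(branch[name], branch["offset_c"])
                if tau is not None:
                    taus.append(tau)
            if taus:
                scores[name].append(float(np.mean(taus)))
    mean_scores = {n: (np.mean(v) if v else -np.inf) for n, v in scores.items()}
    return sorted(names, key=lambda n: (-mean_scores[n], n))


@dataclass(frozen=True)
class ReportBundle:
    text: str
    summary: dict
    exit_status: int

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2)


def report(assessments) -> ReportBundle:
    """Human-readable and JSON summary of one or more assessments.

    Exit status is nonzero when any verdict differs from ``normal``.
    """
    assessments = list(assessments)
    if not assessments:
        raise ValueError("report needs at least one assessment")
    blocks, samples = [], []
    n_abnormal = 0
    for i, a in enumerate(assessments):
        label = a.label or f"sample-{i + 1}"
        if a.verdict != "normal":
            n_abnormal += 1
        flags = ", ".join(a.evidence) if a.evidence else "none"
        blocks.append(
            f"{label}: {a.verdict.upper()} (severity: {a.severity})\n"
            f"  k = {a.k:.2f}  |k-1| = {a.k_deviation:.2f} "
            f"(normal band {a.thresholds_used.normal_band:.2f})\n"
            f"  evidence: {flags}"
        )
        d = a.as_dict()
        d["label"] = label
        samples.append(d)
    summary = {
        "n_samples": len(assessments),
        "n_abnormal": n_abnormal,
        "samples": samples,
    }
    return ReportBundle("\n".join(blocks), summary, 0 if n_abnormal == 0 else 1)
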