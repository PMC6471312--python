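"""Built-in anchor sets and reference readings for the eight study groups.

Two cohorts of sintered dental prostheses are covered:

* pressed ceramics fired 50 degC below normal (L), at the prescribed
  890 degC (N), and 50 degC above (H);
* metal-ceramic veneers fired 100/30 degC below (L100, L30), at the
  prescribed 930 degC (N_metal), and 30/50 degC above (H30, H50).

Each group carries the anchors of its averaged reflectivity graph (used
by the model builders and the phantom generator) and the reference
extreme readings of the averaged graph and of the raw-profile envelope,
from which the scalar indicators (delta-rho, k, ...) are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnchorSet, PiecewiseModel, build_model

__all__ = ["StudyGroup", "GROUPS", "GROUP_LABELS", "get_group"]


@dataclass(frozen=True)
class StudyGroup:
    label: str
    cohort: str          #: "pressed" or "metal"
    offset_c: float      #: firing-temperature offset from normal (degC)
    archetype: str
    anchors: AnchorSet
    #: reference extreme readings (raw-profile envelope and averaged graph)
    rho_min_peak: float
    rho_max_peak: float
    rho_min: float
    rho_max: float

    def build(self) -> PiecewiseModel:
        return build_model(self.archetype, self.anchors)


GROUPS: dict[str, StudyGroup] = {
    "L": StudyGroup(
        "L", "pressed", -50.0, "valley",
        AnchorSet(rho0=60, rho_min=35, x_m=1.5, rho_max=82, x_max=3.25),
        rho_min_peak=34, rho_max_peak=84, rho_min=35, rho_max=82,
    ),
    "N": StudyGroup(
        "N", "pressed", 0.0, "hump_valley",
        AnchorSet(rho0=60, x_M=1.25, rho_max=75, x_i=2.0, rho_i=70,
                  x_m=3.25, rho_min=60, x_max=3.25),
        rho_min_peak=58, rho_max_peak=91, rho_min=60, rho_max=85,
    ),
    "H": StudyGroup(
        "H", "pressed", 50.0, "hump_valley",
        AnchorSet(rho0=60, x_M=0.7, rho_max=89, x_i=1.4,
                  x_m=2.33, rho_min=41, x_max=3.25),
        rho_min_peak=41, rho_max_peak=89, rho_min=41, rho_max=89,
    ),
    "L100": StudyGroup(
        "L100", "metal", -100.0, "valley",
        AnchorSet(rho0=27, rho_min=17, x_m=1.9, rho_max=27, x_max=3.25),
        rho_min_peak=16, rho_max_peak=28, rho_min=17, rho_max=27,
    ),
    "L30": StudyGroup(
        "L30", "metal", -30.0, "ramp_plateau",
        AnchorSet(rho0=25, x_i=1.4, rho_i=32, x_max=3.25),
        rho_min_peak=27, rho_max_peak=34, rho_min=25, rho_max=32,
    ),
    "N_metal": StudyGroup(
        "N_metal", "metal", 0.0, "flat",
        AnchorSet(rho0=25, x_max=3.25),
        rho_min_peak=21, rho_max_peak=32, rho_min=25, rho_max=25,
    ),
    "H30": StudyGroup(
        "H30", "metal", 30.0, "oscillation",
        AnchorSet(rho0=31, A=3, x_max=3.25),
        rho_min_peak=26, rho_max_peak=38, rho_min=26, rho_max=43,
    ),
    "H50": StudyGroup(
        "H50", "metal", 50.0, "linear_ramp",
        AnchorSet(rho0=25, rho_max=34, x_max=3.25),
        rho_min_peak=19, rho_max_peak=34, rho_min=19, rho_max=34,
    ),
}

GROUP_LABELS = tuple(GROUPS)


def get_group(label: str) -> StudyGroup:
    """Look up a study group; accepts 'N-metal'/'n_metal' style spellings."""
    key = label.strip().replace("-", "_")
    for cand in (key, key.upper(), key.capitalize(), key.title()):
        if cand in GROUPS:
            return GROUPS[cand]
    if key.lower() in ("n_metal", "nmetal", "n_m"):
        return GROUPS["N_metal"]
    raise ValueError(
        f"unknown study group {label!r}; expected one of {', '.join(GROUPS)}"
    )
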