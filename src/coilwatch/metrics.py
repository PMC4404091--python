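"""Per-subject growth and translation quantities.

Six measured volumes feed the longitudinal comparison: sac volumes at the
four sessions (V_S1-, V_S1+, V_S2-, V_S2+) and coil-mass volumes at 1+ and
2- (V_C1+, V_C2-).  Sac growth V_SG is the follow-up minus initial sac
volume; because either member of each pair may be missing in a retrospective
series, four definitions exist and are prioritized 1..4:

    V_SG1 = V_S2+ - V_S1-      V_SG2 = V_S2+ - V_S1+
    V_SG3 = V_S2- - V_S1-      V_SG4 = V_S2- - V_S1+

V_SG > 0 indicates growth.  Coil growth V_CG = V_C2- - V_C1+ (< 0 indicates
compaction).  The coil-center translation delta is the distance between the
coil-mass centers at 1+ and 2- in a common frame.  Missing volumes are
represented explicitly (absent is not zero): the subject count per
definition is part of the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: definition id -> (follow-up attr, initial attr)
VSG_DEFINITIONS = {
    1: ("vs2p", "vs1m"),
    2: ("vs2p", "vs1p"),
    3: ("vs2m", "vs1m"),
    4: ("vs2m", "vs1p"),
}


class MissingDataError(ValueError):
    """A quantity is not computable from the available scans."""


@dataclass
class SubjectVolumes:
    """Measured volumes (cc) and coil centroids (mm) for one aneurysm."""

    subject_id: str
    cohort: str  # "recurrence" | "control"
    vs1m: float | None = None
    vs1p: float | None = None
    vs2m: float | None = None
    vs2p: float | None = None
    vc1p: float | None = None
    vc2m: float | None = None
    c1p: tuple | None = None
    c2m: tuple | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("recurrence", "control"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "control" and self.vs2p is not None:
            raise ValueError("control subjects have no 2+ session, so no V_S2+")
        for name in ("vs1m", "vs1p", "vs2m", "vs2p", "vc1p", "vc2m"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass
class GrowthResult:
    """Growth/translation outcome for one aneurysm."""

    subject_id: str
    cohort: str
    vsg_cc: float
    vsg_definition: int
    pct_vsg: float
    vcg_cc: float | None = None
    pct_vcg: float | None = None
    delta_mm: float | None = None


def compute_vsg(sv: SubjectVolumes) -> tuple[float, int]:
    """Sac growth by the highest-priority computable definition."""
    missing = []
    for definition, (follow, initial) in VSG_DEFINITIONS.items():
        vf, vi = getattr(sv, follow), getattr(sv, initial)
        if vf is not None and vi is not None:
            return vf - vi, definition
        missing.append(f"definition {definition} needs {follow}, {initial}")
    raise MissingDataError(
        f"{sv.subject_id}: no sac-growth definition computable ({'; '.join(missing)})"
    )


def compute_pct_vsg(sv: SubjectVolumes, vsg_cc: float, definition: int) -> float:
    """Percent sac growth; the denominator is the definition's initial volume."""
    initial = getattr(sv, VSG_DEFINITIONS[definition][1])
    if initial is None:
        raise MissingDataError(f"initial volume for definition {definition} unavailable")
    if initial == 0:
        raise ZeroDivisionError("initial sac volume is zero")
    return 100.0 * vsg_cc / initial


def compute_vcg(sv: SubjectVolumes) -> tuple[float, float] | None:
    """Coil growth (V_C2- minus V_C1+) and its percentage, or None if the
    baseline scans needed at either session are unavailable."""
    if sv.vc1p is None or sv.vc2m is None:
        return None
    vcg = sv.vc2m - sv.vc1p
    return vcg, 100.0 * vcg / sv.vc1p


def compute_delta(c1p, c2m) -> float | None:
    """Translation of the coil-mass center between 1+ and 2- (mm)."""
    if c1p is None or c2m is None:
        return None
    return float(np.linalg.norm(np.asarray(c2m, float) - np.asarray(c1p, float)))


def clinical_size(height_mm: float, width_mm: float) -> float:
    """Clinically measured sac size: the largest of the two 2D calipers."""
    if height_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    return float(max(height_mm, width_mm))


def growth_result(sv: SubjectVolumes) -> GrowthResult:
    """All longitudinal quantities computable for one subject."""
    vsg, definition = compute_vsg(sv)
    pct = compute_pct_vsg(sv, vsg, definition)
    vcg = compute_vcg(sv)
    return GrowthResult(
        subject_id=sv.subject_id,
        cohort=sv.cohort,
        vsg_cc=vsg,
        vsg_definition=definition,
        pct_vsg=pct,
        vcg_cc=None if vcg is None else vcg[0],
        pct_vcg=None if vcg is None else vcg[1],
        delta_mm=compute_delta(sv.c1p, sv.c2m),
    )
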