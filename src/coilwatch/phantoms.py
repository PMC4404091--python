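"""Synthetic paired subtracted/baseline phantoms with programmed ground truth.

Each subject is a scene of analytic solids rasterized on the scanner grid
(0.22 mm isotropic by default):

* an aneurysm sac — an ellipsoid whose semi-axes may grow between the
  initial (1-, 1+) and follow-up (2-, 2+) sessions;
* a parent vessel — a capsule along a polyline, overlapping the sac so the
  two are contiguous;
* a coil mass — the union of capsule segments along a random walk confined
  to the sac interior, grown until a target fill fraction of the sac is
  occupied; at follow-up the same mass is rigidly translated by a programmed
  offset (the ground truth for the coil-center translation delta);
* optionally a skull-like shell (baseline scans only), Gaussian intensity
  noise, and multiplicative streak artifacts around the coil emulating metal
  artifacts.

Subtracted volumes show vessel plus sac blood (1-) or vessel plus residual
blood (1+, 2-, 2+); baseline volumes show coil plus skull.  All four time
points share one coordinate frame — the grids are generated co-registered.
Control subjects have no 2+ session.

Ground truth sac volumes are closed-form ellipsoid volumes; coil volume and
center come from the noiseless rasterized coil solid; the true translation
equals the norm of the programmed offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .volumes import ImageVolume

TIME_POINTS = ("1-", "1+", "2-", "2+")
CONTROL_TIME_POINTS = ("1-", "1+", "2-")
COIL_TIME_POINTS = ("1+", "2-", "2+")

ANEURYSM_LOCATIONS = (
    "Acom", "Basilar tip", "L MCA", "R MCA terminus", "L paraophthalmic",
    "R paraophthalmic", "L cavernous ICA", "R cavernous ICA", "R ICA",
    "R ICA terminus", "L ophthalmic", "R pcom", "L vertebral",
)


@dataclass
class Scenario:
    """Programmed parameters of one phantom subject.

    Lengths in mm; ``sac_axes_mm``/``sac_center_mm`` map time point to
    ellipsoid semi-axes and center.  ``coil_fill_fraction`` is the fraction
    of the 1+ sac volume occupied by the coil solid.  ``residual_scale``
    scales the sac ellipsoid to form the residual-blood region seen on
    post-treatment subtracted scans (None: no residual).
    """

    sac_axes_mm: dict = field(default_factory=dict)
    sac_center_mm: dict = field(default_factory=dict)
    vessel_path_mm: list = field(default_factory=list)
    vessel_radius_mm: float = 1.2
    coil_fill_fraction: float = 0.35
    coil_wire_radius_mm: float = 0.45
    coil_center_offset_mm: tuple = (0.0, 0.0, 0.0)
    residual_scale: float | None = 1.0
    noise_sd: float = 5.0
    artifact_level: float = 0.05
    include_skull: bool = True
    background_intensity: float = 10.0
    blood_intensity: float = 100.0
    coil_intensity: float = 180.0
    skull_intensity: float = 140.0
    spacing: float = 0.22
    grid_shape: tuple = (128, 128, 128)
    seed: int = 0
    cohort: str = "recurrence"
    subject_id: str = "phantom-01"

    def __post_init__(self) -> None:
        # canonical container types so scenarios survive YAML round-trips
        self.sac_axes_mm = {k: tuple(float(x) for x in v) for k, v in self.sac_axes_mm.items()}
        self.sac_center_mm = {k: tuple(float(x) for x in v) for k, v in self.sac_center_mm.items()}
        self.vessel_path_mm = [tuple(float(x) for x in p) for p in self.vessel_path_mm]
        self.coil_center_offset_mm = tuple(float(x) for x in self.coil_center_offset_mm)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)

    @property
    def time_points(self) -> tuple:
        return TIME_POINTS if self.cohort == "recurrence" else CONTROL_TIME_POINTS

    def validate(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (0.0 < self.coil_fill_fraction <= 1.0):
            raise ValueError("coil_fill_fraction must lie in (0, 1]")
        if self.cohort not in ("recurrence", "control"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        extent = np.array(self.grid_shape) * self.spacing
        margin = 2 * self.spacing
        for tp in self.time_points:
            axes = np.asarray(self.sac_axes_mm[tp], float)
            center = np.asarray(self.sac_center_mm[tp], float)
            if np.any(axes <= 0):
                raise ValueError(f"sac semi-axes must be positive at {tp}")
            if np.any(center - axes < margin) or np.any(center + axes > extent - margin):
                raise ValueError(
                    f"sac at {tp} exceeds the grid bounds (need a 2-voxel margin); "
                    f"enlarge grid_shape or shrink the sac"
                )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sac_axes_mm"] = {k: list(map(float, v)) for k, v in d["sac_axes_mm"].items()}
        d["sac_center_mm"] = {k: list(map(float, v)) for k, v in d["sac_center_mm"].items()}
        d["vessel_path_mm"] = [list(map(float, p)) for p in d["vessel_path_mm"]]
        d["coil_center_offset_mm"] = list(map(float, d["coil_center_offset_mm"]))
        d["grid_shape"] = list(d["grid_shape"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        d = yaml.safe_load(Path(path).read_text())
        d["coil_center_offset_mm"] = tuple(d["coil_center_offset_mm"])
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def default_scenario(
    sac_radius_mm: float = 4.0,
    growth_fraction: float = 0.0,
    axis_ratios: tuple = (1.0, 1.0, 1.0),
    coil_center_offset_mm: tuple = (0.0, 0.0, 0.0),
    cohort: str = "recurrence",
    seed: int = 0,
    grid_shape: tuple = (128, 128, 128),
    spacing: float = 0.22,
    **overrides,
) -> Scenario:
    """A saccular aneurysm on a straight parent vessel.

    The sac sits above the vessel at the grid center; its semi-axes are
    ``sac_radius_mm`` times ``axis_ratios`` at 1-/1+, scaled isotropically by
    ``(1 + growth_fraction)^(1/3)`` at 2-/2+ so the sac volume grows by
    exactly ``growth_fraction``.
    """
    extent = np.array(grid_shape) * spacing
    center = extent / 2.0
    axes0 = sac_radius_mm * np.asarray(axis_ratios, float)
    scale = (1.0 + growth_fraction) ** (1.0 / 3.0)
    vessel_radius = overrides.pop("vessel_radius_mm", 1.2)
    # vessel axis below the 1- sac, overlapping it by ~40% of the vessel radius
    vz = center[2] - axes0[2] - 0.6 * vessel_radius
    tps = TIME_POINTS if cohort == "recurrence" else CONTROL_TIME_POINTS
    sac_axes = {tp: tuple(axes0 * (scale if tp in ("2-", "2+") else 1.0)) for tp in tps}
    sac_center = {tp: tuple(center) for tp in tps}
    return Scenario(
        sac_axes_mm=sac_axes,
        sac_center_mm=sac_center,
        vessel_path_mm=[(0.0, center[1], vz), (extent[0], center[1], vz)],
        vessel_radius_mm=vessel_radius,
        coil_center_offset_mm=tuple(coil_center_offset_mm),
        cohort=cohort,
        seed=seed,
        grid_shape=tuple(grid_shape),
        spacing=spacing,
        **overrides,
    )


@dataclass
class GroundTruth:
    """Programmed quantities the pipeline is validated against."""

    true_sac_volume_cc: dict
    true_vsg_cc: dict                      # definition (1..4) -> cc or None
    true_delta_mm: float
    seed_point_mm: tuple
    vessel_radius_mm: float
    true_coil_volume_cc: dict | None = None   # "1+", "2-" -> cc
    true_coil_center_mm: dict | None = None


def _ellipsoid_volume_cc(axes_mm) -> float:
    a, b, c = axes_mm
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def closed_form_truth(scenario: Scenario) -> GroundTruth:
    """Ground truth derivable without rasterization (sac volumes, growth, delta)."""
    vols = {tp: _ellipsoid_volume_cc(scenario.sac_axes_mm[tp]) for tp in scenario.time_points}
    get = vols.get
    vsg = {
        1: (get("2+") - get("1-")) if "2+" in vols else None,
        2: (get("2+") - get("1+")) if "2+" in vols else None,
        3: get("2-") - get("1-"),
        4: get("2-") - get("1+"),
    }
    return GroundTruth(
        true_sac_volume_cc=vols,
        true_vsg_cc=vsg,
        true_delta_mm=float(np.linalg.norm(scenario.coil_center_offset_mm)),
        seed_point_mm=tuple(scenario.sac_center_mm["1+"]),
        vessel_radius_mm=scenario.vessel_radius_mm,
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _grid_axes(scenario: Scenario):
    s = scenario.spacing
    nx, ny, nz = scenario.grid_shape
    return (
        (np.arange(nx) * s)[:, None, None],
        (np.arange(ny) * s)[None, :, None],
        (np.arange(nz) * s)[None, None, :],
    )


def _ellipsoid_mask(scenario, center, axes) -> np.ndarray:
    X, Y, Z = _grid_axes(scenario)
    cx, cy, cz = center
    a, b, c = axes
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0


def _capsule_mask_full(scenario, p0, p1, radius) -> np.ndarray:
    """Capsule (cylinder with spherical caps) over the full grid."""
    X, Y, Z = _grid_axes(scenario)
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    px, py, pz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 == 0.0:
        return px**2 + py**2 + pz**2 <= radius**2
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    return (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2 <= radius**2


def _polyline_mask(scenario, points, radius) -> np.ndarray:
    out = np.zeros(scenario.grid_shape, dtype=bool)
    for p0, p1 in zip(points[:-1], points[1:]):
        out |= _capsule_mask_full(scenario, p0, p1, radius)
    return out


def _stamp_capsule(mask, scenario, p0, p1, radius) -> None:
    """Rasterize one capsule into ``mask`` using a local bounding-box crop."""
    s = scenario.spacing
    lo = np.floor((np.minimum(p0, p1) - radius) / s).astype(int) - 1
    hi = np.ceil((np.maximum(p0, p1) + radius) / s).astype(int) + 2
    lo = np.clip(lo, 0, np.array(mask.shape))
    hi = np.clip(hi, 0, np.array(mask.shape))
    idx = np.ix_(*(np.arange(a, b) for a, b in zip(lo, hi)))
    Xc = (idx[0] * s).astype(float)
    Yc, Zc = idx[1] * s, idx[2] * s
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    px, py, pz = Xc - p0[0], Yc - p0[1], Zc - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0) if L2 else 0.0
    inside = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2 <= radius**2
    mask[idx] |= inside


def _coil_walk(scenario: Scenario, rng: np.random.Generator):
    """Random capsule walk inside the 1+ sac until the fill fraction is met.

    The walk is confined to the 1+ sac shrunk by the wire radius, so the
    initial coil lies inside the sac exactly.  The translated follow-up coil
    may protrude slightly through the residual envelope; the protrusion is
    part of the follow-up sac (the sac is the union of coil mass and
    residual blood) and the rasterized ground truth accounts for it.
    """
    axes = np.asarray(scenario.sac_axes_mm["1+"], float)
    center = np.asarray(scenario.sac_center_mm["1+"], float)
    inner = axes - scenario.coil_wire_radius_mm
    if np.any(inner <= 0.3):
        raise ValueError("sac too small to wind a coil with the requested wire radius")

    sac_vox = int(_ellipsoid_mask(scenario, center, axes).sum())
    target = scenario.coil_fill_fraction * sac_vox
    coil = np.zeros(scenario.grid_shape, dtype=bool)
    step = 2.5 * scenario.coil_wire_radius_mm
    pos = center.copy()
    path = [pos.copy()]
    for _ in range(50000):
        if coil.sum() >= target:
            break
        for _ in range(100):  # rejection-sample a step staying inside the sac
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = pos + step * direction
            if np.sum(((cand - center) / inner) ** 2) <= 1.0:
                break
        else:
            cand = center.copy()  # restart from the middle if cornered
        _stamp_capsule(coil, scenario, pos, cand, scenario.coil_wire_radius_mm)
        path.append(cand.copy())
        pos = cand
    else:
        raise ValueError("coil walk failed to reach the requested fill fraction")
    return np.array(path)


def _rasterize_coil(scenario, path, offset) -> np.ndarray:
    coil = np.zeros(scenario.grid_shape, dtype=bool)
    pts = path + np.asarray(offset, float)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        _stamp_capsule(coil, scenario, p0, p1, scenario.coil_wire_radius_mm)
    return coil


def _skull_mask(scenario) -> np.ndarray | None:
    """Skull-like shell near the grid boundary, or None when the grid is too
    small for the shell to clear the peri-aneurysmal region (a real skull is
    far from the sac; on desk-scale grids it must not crowd the coil)."""
    extent = np.array(scenario.grid_shape) * scenario.spacing
    center = extent / 2.0
    r_outer = 0.47 * float(extent.min())
    max_axis = max(max(a) for a in scenario.sac_axes_mm.values())
    if r_outer - 0.8 < max_axis + 7.0:
        return None
    X, Y, Z = _grid_axes(scenario)
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    return (r >= r_outer - 0.8) & (r <= r_outer)


def _artifact_field(scenario, coil_center) -> np.ndarray:
    """Multiplicative radial streak pattern centered on the coil mass."""
    X, Y, Z = _grid_axes(scenario)
    dx, dy, dz = X - coil_center[0], Y - coil_center[1], Z - coil_center[2]
    phi = np.arctan2(dy, dx)
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    return 1.0 + scenario.artifact_level * np.sin(8.0 * phi) * np.exp(-dist / 4.0)


def make_subject(scenario: Scenario):
    """Rasterize one subject's paired subtracted/baseline volumes.

    Returns ``(images, truth)`` where ``images[tp]`` is a dict with a
    ``"subtracted"`` ImageVolume for every session and a ``"baseline"``
    ImageVolume for the post-treatment sessions.  Identical scenarios (and
    seeds) produce voxelwise-identical volumes.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    truth = closed_form_truth(scenario)

    path = _coil_walk(scenario, rng)
    coil = {"1+": _rasterize_coil(scenario, path, (0.0, 0.0, 0.0))}
    coil["2-"] = _rasterize_coil(scenario, path, scenario.coil_center_offset_mm)
    if "2+" in scenario.time_points:
        coil["2+"] = coil["2-"]

    vox_cc = scenario.spacing**3 / 1000.0
    spacing3 = (scenario.spacing,) * 3

    def centroid_mm(m):
        return tuple(np.array(np.nonzero(m)).mean(axis=1) * scenario.spacing)

    truth.true_coil_volume_cc = {tp: float(coil[tp].sum()) * vox_cc for tp in ("1+", "2-")}
    truth.true_coil_center_mm = {tp: centroid_mm(coil[tp]) for tp in ("1+", "2-")}

    # The follow-up sac is the union of the residual envelope and the coil
    # mass; a translated coil may protrude beyond the ellipsoid, so the 2-/2+
    # truth is the rasterized union volume rather than the closed form.
    for tp in ("2-", "2+"):
        if tp in scenario.time_points:
            env = _ellipsoid_mask(scenario, scenario.sac_center_mm[tp], scenario.sac_axes_mm[tp])
            truth.true_sac_volume_cc[tp] = float((env | coil[tp]).sum()) * vox_cc
    get = truth.true_sac_volume_cc.get
    truth.true_vsg_cc = {
        1: (get("2+") - get("1-")) if get("2+") else None,
        2: (get("2+") - get("1+")) if get("2+") else None,
        3: get("2-") - get("1-"),
        4: get("2-") - get("1+"),
    }

    vessel = _polyline_mask(scenario, scenario.vessel_path_mm, scenario.vessel_radius_mm)
    skull = _skull_mask(scenario) if scenario.include_skull else None

    images: dict[str, dict[str, ImageVolume]] = {}
    for tp in scenario.time_points:
        sac = _ellipsoid_mask(
            scenario, scenario.sac_center_mm[tp], scenario.sac_axes_mm[tp]
        )
        if tp == "1-":
            blood = vessel | sac
        else:
            if scenario.residual_scale is None:
                blood = vessel.copy()
            else:
                residual = _ellipsoid_mask(
                    scenario,
                    scenario.sac_center_mm[tp],
                    np.asarray(scenario.sac_axes_mm[tp]) * scenario.residual_scale,
                )
                blood = vessel | (residual & ~coil[tp])
        sub = np.full(scenario.grid_shape, scenario.background_intensity)
        sub[blood] = scenario.blood_intensity
        sub += rng.normal(0.0, scenario.noise_sd, size=sub.shape)
        entry = {"subtracted": ImageVolume(sub, spacing=spacing3, modality="subtracted")}

        if tp in coil:
            base = np.full(scenario.grid_shape, scenario.background_intensity)
            base[coil[tp]] = scenario.coil_intensity
            if skull is not None:
                base[skull & ~coil[tp]] = scenario.skull_intensity
            if scenario.artifact_level > 0:
                artifact_tp = tp if tp in truth.true_coil_center_mm else "2-"
                base *= _artifact_field(scenario, truth.true_coil_center_mm[artifact_tp])
            base += rng.normal(0.0, scenario.noise_sd, size=base.shape)
            entry["baseline"] = ImageVolume(base, spacing=spacing3, modality="baseline")
        images[tp] = entry

    return images, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortEffects:
    """Generating distributions for the two cohorts.

    Recurrence subjects draw a positive mean relative sac growth and a large
    coil-center translation; controls draw near-zero growth and a small
    translation.  Growth is a volume fraction; translations in mm.
    """

    growth_mean: float = 0.20
    growth_sd: float = 0.10
    control_growth_sd: float = 0.005
    delta_mean_mm: float = 2.0
    delta_sd_mm: float = 0.5
    control_delta_mean_mm: float = 0.5
    control_delta_sd_mm: float = 0.2
    sac_radius_range_mm: tuple = (3.2, 4.6)
    coil_fill_range: tuple = (0.25, 0.40)
    noise_sd: float = 5.0
    artifact_level: float = 0.05
    grid_shape: tuple = (128, 128, 128)
    spacing: float = 0.22


def make_cohort(
    n_recurrence: int,
    n_control: int,
    effects: CohortEffects | None = None,
    seed: int = 0,
):
    """Draw scenarios for a two-cohort study and a demographics table.

    Returns ``(subjects, metadata)``: a list of ``(Scenario, GroundTruth)``
    pairs (ground truth closed-form; rasterize with :func:`make_subject`) and
    a metadata table mirroring a clinical demographics sheet (subject id,
    age, sex, location, size "HxW" in mm, rupture status, follow-up months,
    cohort).
    """
    if n_recurrence < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    effects = effects or CohortEffects()
    rng = np.random.default_rng(seed)

    subjects, rows = [], []
    labels = ["recurrence"] * n_recurrence + ["control"] * n_control
    for i, cohort in enumerate(labels, start=1):
        if cohort == "recurrence":
            growth = float(np.clip(rng.normal(effects.growth_mean, effects.growth_sd), -0.05, 1.5))
            delta = float(np.clip(rng.normal(effects.delta_mean_mm, effects.delta_sd_mm), 0.1, 4.0))
        else:
            growth = float(np.clip(rng.normal(0.0, effects.control_growth_sd), -0.05, 0.05))
            delta = float(
                np.clip(rng.normal(effects.control_delta_mean_mm, effects.control_delta_sd_mm), 0.0, 4.0)
            )
        direction = rng.normal(size=3)
        direction[2] = abs(direction[2])  # coil shifts deeper into the dome, away from the neck
        direction /= np.linalg.norm(direction)
        radius = float(rng.uniform(*effects.sac_radius_range_mm))
        ratios = rng.uniform(0.9, 1.1, size=3)
        ratios /= ratios.max()
        sid = f"{i:02d} ({'RE' if cohort == 'recurrence' else 'C'})"
        scenario = default_scenario(
            sac_radius_mm=radius,
            growth_fraction=growth,
            axis_ratios=tuple(ratios),
            coil_center_offset_mm=tuple(delta * direction),
            cohort=cohort,
            seed=int(rng.integers(2**31)),
            grid_shape=effects.grid_shape,
            spacing=effects.spacing,
            coil_fill_fraction=float(rng.uniform(*effects.coil_fill_range)),
            noise_sd=effects.noise_sd,
            artifact_level=effects.artifact_level,
            subject_id=sid,
        )
        truth = closed_form_truth(scenario)
        subjects.append((scenario, truth))
        axes = np.asarray(scenario.sac_axes_mm["1-"])
        rows.append(
            {
                "subject": sid,
                "age": int(np.clip(rng.normal(53, 13), 16, 85)),
                "sex": "F" if rng.random() < 0.78 else "M",
                "location": ANEURYSM_LOCATIONS[int(rng.integers(len(ANEURYSM_LOCATIONS)))],
                "size_mm": f"{max(1, round(2 * axes.max()))}x{max(1, round(2 * axes.min()))}",
                "ruptured": "Ruptured" if rng.random() < 0.4 else "Unruptured",
                "followup_months": round(float(np.clip(rng.lognormal(2.15, 0.5), 2.0, 25.0)), 1),
                "cohort": cohort,
            }
        )
    return subjects, pd.DataFrame(rows)
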