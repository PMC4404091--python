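"""Per-subject measurement chain and study-level analysis.

``run_subject`` walks the session-by-session workflow: at 1- the sac model
comes from the vascular segmentation of the subtracted scan; at 1+, 2- and
2+ the coil mass is segmented from the baseline scan, the vessels and any
residual blood from the subtracted scan, and the sac is isolated from their
Boolean union.  Coil-mass volumes and mass centers are measured at 1+ and 2-
for the compaction and translation analyses.  Missing scans are first-class:
the corresponding volumes are simply unavailable, and each growth definition
counts only the subjects for which it is computable.

``run_study`` aggregates per-subject results into cohort growth summaries,
the between-cohort translation test, and ROC curves for the translation and
for clinically measured sac size.

Coil-center translation assumes the two sessions share one coordinate
frame; no inter-session registration is attempted, and results are only
meaningful for co-registered inputs (phantom grids are generated
co-registered by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .geometry import build_posttreatment_sac, extract_surface, isolate_sac, mesh_centroid, mesh_volume
from .metrics import MissingDataError, SubjectVolumes, growth_result
from .phantoms import Scenario, make_subject
from .segmentation import (
    LevelSetParams,
    SeedError,
    segment_coil,
    segment_vascular,
)
from .stats import RocResult, mann_whitney_one_tailed, r_squared, roc, summary_frame
from .volumes import ImageVolume, crop_box, write_volume

COIL_SESSIONS = ("1+", "2-")


@dataclass
class PipelineConfig:
    """Tunable parameters of the measurement chain (lengths in mm)."""

    opening_radius_vox: int = 1
    closing_radius_vox: int = 1
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    # no curvature smoothing on the irregular coil boundary (volume bias)
    coil_levelset: LevelSetParams = field(
        default_factory=lambda: LevelSetParams(curvature_weight=0.0)
    )
    coil_voi_halfwidth_mm: float = 6.5
    working_halfwidth_mm: float | None = 10.0   # crop around the seed; None: full grid
    seed_snap_radius_mm: float = 5.0
    tube_scale: float = 1.1
    vessel_factor: float = 1.5
    vessel_radius_mm: float | None = None   # None: estimate from the centerline
    measure_on: str = "mesh"                # "mesh" | "mask" coil volumetry

    @property
    def vessel_info(self) -> dict | None:
        if self.vessel_radius_mm is None:
            return None
        return {"radius_mm": self.vessel_radius_mm}


@dataclass
class SubjectRecord:
    """Input bundle for one aneurysm: images per session plus a sac seed."""

    subject_id: str
    cohort: str
    images: dict  # tp -> {"subtracted": ImageVolume, "baseline": ImageVolume}
    seed_point_mm: tuple


def _snap_seed(vol: ImageVolume, seed_mm, fg: np.ndarray, radius_mm: float):
    """Nearest foreground voxel to the seed (the 're-seed' a user would do
    when the original seed lands inside the coil shadow)."""
    idx = np.array(np.nonzero(fg))
    if idx.size == 0:
        return seed_mm
    pts = vol.index_to_physical(idx.T)
    d = np.linalg.norm(pts - np.asarray(seed_mm, float), axis=1)
    j = int(np.argmin(d))
    if d[j] > radius_mm:
        raise SeedError(
            f"no angiographic foreground within {radius_mm} mm of the seed"
        )
    return tuple(pts[j])


def _segment_angio(
    subtracted: ImageVolume,
    seed_mm,
    config: PipelineConfig,
    keep: str = "seed",
    levelset: LevelSetParams | None = None,
):
    """Vascular segmentation with automatic re-seeding on SeedError."""
    levelset = levelset if levelset is not None else config.levelset
    try:
        return segment_vascular(
            subtracted, seed_mm,
            opening_radius=config.opening_radius_vox, levelset=levelset,
            keep=keep,
        )
    except SeedError:
        from .segmentation import grayscale_open, otsu_threshold

        opened = grayscale_open(subtracted, config.opening_radius_vox)
        thr = otsu_threshold(opened.values)
        snapped = _snap_seed(opened, seed_mm, opened.values > thr, config.seed_snap_radius_mm)
        return segment_vascular(
            subtracted, snapped,
            opening_radius=config.opening_radius_vox, levelset=levelset,
            keep=keep,
        )


def run_subject(
    record: SubjectRecord,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SubjectVolumes:
    """Measure all available sac/coil volumes and coil centers for a subject.

    A session absent from ``record.images`` leaves its volumes unavailable;
    the subject errors out only if no growth definition is computable (both
    follow-up sessions missing, or both initial sessions missing).
    """
    config = config or PipelineConfig()
    images = record.images
    if not ({"1-", "1+"} & images.keys()) or not ({"2-", "2+"} & images.keys()):
        missing = sorted({"1-", "1+", "2-", "2+"} - images.keys())
        raise MissingDataError(
            f"{record.subject_id}: no growth definition computable; "
            f"missing sessions {missing}"
        )
    seed = record.seed_point_mm
    out = {}
    coil_meshes = {}
    persist = Path(out_dir) if out_dir else None
    if persist:
        persist.mkdir(parents=True, exist_ok=True)

    for tp, entry in images.items():
        if config.working_halfwidth_mm is not None:
            entry = {
                k: crop_box(v, seed, config.working_halfwidth_mm) for k, v in entry.items()
            }
        slug = tp.replace("+", "p").replace("-", "m")
        coil_mask = None
        if "baseline" in entry:
            lo = np.asarray(seed) - config.coil_voi_halfwidth_mm
            hi = np.asarray(seed) + config.coil_voi_halfwidth_mm
            coil_mask = segment_coil(
                entry["baseline"], voi_mm=(lo, hi),
                closing_radius=config.closing_radius_vox, levelset=config.coil_levelset,
            )
            if tp in COIL_SESSIONS:
                mesh = extract_surface(coil_mask)
                coil_meshes[tp] = mesh
                if config.measure_on == "mask":
                    out["vc" + slug[0] + slug[1]] = coil_mask.volume_cc()
                if persist:
                    mesh.save(persist / f"coil_{slug}.stl")
                    write_volume(coil_mask, persist / f"coil_{slug}.nii.gz")

        if "subtracted" in entry:
            if tp == "1-":
                angio_mask = _segment_angio(entry["subtracted"], seed, config)
                sac = isolate_sac(
                    angio_mask, seed, config.vessel_info,
                    tube_scale=config.tube_scale, vessel_factor=config.vessel_factor,
                )
            elif coil_mask is not None:
                # Post-treatment scans may hold residual pockets detached
                # from the vessel: keep all contrast foreground.  Skip the
                # contour refinement — the thin residual shell around the
                # coil would be eroded by the curvature force, and the union
                # with the coil mass is consolidated afterwards anyway.
                angio_mask = _segment_angio(
                    entry["subtracted"], seed, config, keep="all",
                    levelset=LevelSetParams(iterations=0),
                )
                sac = build_posttreatment_sac(
                    coil_mask, angio_mask, seed, config.vessel_info,
                    tube_scale=config.tube_scale, vessel_factor=config.vessel_factor,
                )
            else:
                continue  # post-treatment sac needs the coil: volume unavailable
            out["vs" + slug] = sac.volume_cc
            if persist:
                sac.mesh.save(persist / f"sac_{slug}.stl")

    sv = SubjectVolumes(
        subject_id=record.subject_id,
        cohort=record.cohort,
        vs1m=out.get("vs1m"),
        vs1p=out.get("vs1p"),
        vs2m=out.get("vs2m"),
        vs2p=out.get("vs2p"),
    )
    if "1+" in coil_meshes:
        sv.vc1p = out.get("vc1p", mesh_volume(coil_meshes["1+"]))
        sv.c1p = tuple(mesh_centroid(coil_meshes["1+"]))
    if "2-" in coil_meshes:
        sv.vc2m = out.get("vc2m", mesh_volume(coil_meshes["2-"]))
        sv.c2m = tuple(mesh_centroid(coil_meshes["2-"]))
    return sv


def run_phantom_subject(
    scenario: Scenario, config: PipelineConfig | None = None
):
    """Generate a phantom subject and push it through the measurement chain.

    Returns ``(measured SubjectVolumes, GroundTruth)``.
    """
    images, truth = make_subject(scenario)
    record = SubjectRecord(
        subject_id=scenario.subject_id,
        cohort=scenario.cohort,
        images=images,
        seed_point_mm=truth.seed_point_mm,
    )
    return run_subject(record, config), truth


@dataclass
class StudyResult:
    """Study-level outputs: tables, tests and ROC curves."""

    per_subject: pd.DataFrame
    summaries: pd.DataFrame
    delta_u: float | None
    delta_p: float | None
    roc_delta: RocResult | None
    roc_size: RocResult | None
    range_stats: pd.DataFrame
    subject_volumes: list


def _range_rows(results) -> pd.DataFrame:
    rows = []
    frame = pd.DataFrame(
        {
            "cohort": r.cohort,
            "vsg": r.vsg_cc,
            "vcg": r.vcg_cc,
            "delta": r.delta_mm,
        }
        for r in results
    )
    for cohort, grp in frame.groupby("cohort"):
        for quantity in ("vsg", "vcg", "delta"):
            vals = grp[quantity].dropna()
            if len(vals):
                rows.append(
                    {
                        "cohort": cohort,
                        "quantity": quantity,
                        "min": vals.min(),
                        "median": vals.median(),
                        "max": vals.max(),
                        "n": len(vals),
                    }
                )
    return pd.DataFrame(rows)


def run_study(
    subject_volumes: list[SubjectVolumes],
    clinical_sizes: dict | None = None,
) -> StudyResult:
    """Cohort analysis over measured per-subject volumes.

    Growth summaries per definition and cohort; one-tailed Mann-Whitney for
    the coil-center translation (recurrence larger); ROC of the translation
    and — when ``clinical_sizes`` maps subject id to mm — of clinically
    measured sac size, for the biomarker comparison.
    """
    results = [growth_result(sv) for sv in subject_volumes]
    per_subject = pd.DataFrame(
        {
            "subject_id": r.subject_id,
            "cohort": r.cohort,
            "vs1m": sv.vs1m, "vs1p": sv.vs1p, "vs2m": sv.vs2m, "vs2p": sv.vs2p,
            "vc1p": sv.vc1p, "vc2m": sv.vc2m,
            "vsg_cc": r.vsg_cc,
            "vsg_definition": r.vsg_definition,
            "pct_vsg": r.pct_vsg,
            "vcg_cc": r.vcg_cc,
            "pct_vcg": r.pct_vcg,
            "delta_mm": r.delta_mm,
        }
        for sv, r in zip(subject_volumes, results)
    )
    summaries = summary_frame(subject_volumes)

    deltas = {"recurrence": [], "control": []}
    for r in results:
        if r.delta_mm is not None:
            deltas[r.cohort].append(r.delta_mm)
    delta_u = delta_p = roc_delta = None
    if deltas["recurrence"] and deltas["control"]:
        delta_u, delta_p = mann_whitney_one_tailed(
            deltas["recurrence"], deltas["control"], alternative="greater"
        )
        scores = deltas["recurrence"] + deltas["control"]
        labels = [True] * len(deltas["recurrence"]) + [False] * len(deltas["control"])
        roc_delta = roc(scores, labels)

    roc_size = None
    if clinical_sizes:
        scored = [(clinical_sizes[r.subject_id], r.cohort == "recurrence")
                  for r in results if r.subject_id in clinical_sizes]
        if scored:
            roc_size = roc([s for s, _ in scored], [l for _, l in scored])

    return StudyResult(
        per_subject=per_subject,
        summaries=summaries,
        delta_u=delta_u,
        delta_p=delta_p,
        roc_delta=roc_delta,
        roc_size=roc_size,
        range_stats=_range_rows(results),
        subject_volumes=list(subject_volumes),
    )


def run_phantom_study(
    subjects: list,
    config: PipelineConfig | None = None,
    clinical_sizes: dict | None = None,
    progress: bool = False,
) -> tuple[StudyResult, list]:
    """Measure a list of ``(Scenario, GroundTruth)`` phantoms and analyze.

    Phantoms are rasterized one at a time (the volumes are large); returns
    the study result plus the completed ground truths.
    """
    measured, truths, failed = [], [], []
    for scenario, _ in subjects:
        try:
            sv, truth = run_phantom_subject(scenario, config)
        except (MissingDataError, SeedError, ValueError) as err:
            failed.append((scenario.subject_id, str(err)))
            continue
        measured.append(sv)
        truths.append(truth)
        if progress:
            print(f"  measured {scenario.subject_id} ({scenario.cohort})")
    if failed:
        print(f"  warning: {len(failed)} subject(s) failed: {failed}")
    return run_study(measured, clinical_sizes), truths


def investigator_study(
    subjects: list,
    config: PipelineConfig | None = None,
    jitter_mm: float = 0.7,
    seed: int = 0,
) -> dict:
    """Blinded second-reader emulation on phantom subjects.

    Each subject is measured twice: once from the nominal sac seed and once
    from a seed displaced by ``jitter_mm`` in a random direction (the second
    investigator's click).  Returns the :func:`compare_investigators` report.
    """
    rng = np.random.default_rng(seed)
    run_a, run_b = [], []
    for scenario, _ in subjects:
        images, truth = make_subject(scenario)
        record = SubjectRecord(
            scenario.subject_id, scenario.cohort, images, truth.seed_point_mm
        )
        run_a.append(run_subject(record, config))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        record_b = SubjectRecord(
            scenario.subject_id,
            scenario.cohort,
            images,
            tuple(np.asarray(truth.seed_point_mm) + jitter_mm * direction),
        )
        run_b.append(run_subject(record_b, config))
    return compare_investigators(run_a, run_b)


def compare_investigators(run_a: list[SubjectVolumes], run_b: list[SubjectVolumes]) -> dict:
    """Investigator-sensitivity comparison of two measurement runs.

    Pairs every sac volume and every coil volume measured by both runs for
    the same subject/session and returns the paired data with coefficients
    of determination for sac and coil volumes separately.
    """
    b_by_id = {sv.subject_id: sv for sv in run_b}
    sac_a, sac_b, coil_a, coil_b = [], [], [], []
    for a in run_a:
        b = b_by_id.get(a.subject_id)
        if b is None:
            continue
        for name in ("vs1m", "vs1p", "vs2m", "vs2p"):
            va, vb = getattr(a, name), getattr(b, name)
            if va is not None and vb is not None:
                sac_a.append(va)
                sac_b.append(vb)
        for name in ("vc1p", "vc2m"):
            va, vb = getattr(a, name), getattr(b, name)
            if va is not None and vb is not None:
                coil_a.append(va)
                coil_b.append(vb)
    if not sac_a and not coil_a:
        raise ValueError("no overlapping measurements between the two runs")
    out = {
        "sac_pairs": (np.array(sac_a), np.array(sac_b)),
        "coil_pairs": (np.array(coil_a), np.array(coil_b)),
    }
    out["r2_sac"] = r_squared(sac_a, sac_b) if len(sac_a) >= 2 else None
    out["r2_coil"] = r_squared(coil_a, coil_b) if len(coil_a) >= 2 else None
    return out
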