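"""Synthetic beating-heart cine phantoms.

Each phantom is a short-axis cross-section of the left ventricle: a bright
blood pool surrounded by an annular myocardial wall on a dark background,
contracting quasi-periodically over one cardiac cycle of ``n_frames`` frames.
When a "scar" is present, an angular sector of the wall contracts with a
reduced excursion (``scar_motion_ratio``), mimicking the regional hypo- or
akinesia that fibrotic tissue induces.  The per-pixel videointensity time
series produced this way carries exactly the periodic modulation that the
Fourier and monogenic parametric images summarise, so every downstream stage
of the pipeline can be exercised without clinical data.

The temporal motion law is a raised cosine, ``r(t) = r_ed - excursion *
(1 - cos(2*pi*t/T)) / 2``: a single exact cycle, so frame 0 is end-diastole
(largest cavity), frame T/2 is end-systole, and each pixel's intensity series
is periodic with fundamental frequency ``2*pi/T`` — the model the first
harmonic fit assumes, which makes closed-form oracles available in tests.
The wall deforms incompressibly: the epicardial radius follows
``r_epi = sqrt(r_endo^2 + (r_epi_ed^2 - r_endo_ed^2))`` per angle, so
cross-sectional wall area is conserved and epicardial motion is milder than
endocardial motion, as in a real ventricle.

Region fills are anti-aliased by linear ramping of the pixel value over a
one-pixel band around each circular boundary (an analytic area-coverage
approximation), so boundary stair-steps do not dominate the band-pass
monogenic response.  Noise is i.i.d. additive Gaussian per pixel and frame.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .io import CineLoop, ContourSet

SCAR = "SCAR"
NL = "NL"

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion, intensity and noise parameters of one phantom slice.

    Lengths are in pixels, angles in radians, intensities in arbitrary gray
    levels.  ``contraction_fraction`` is the fractional endocardial radial
    excursion of normal myocardium; inside the scar sector it is scaled by
    ``scar_motion_ratio`` (0 = akinetic, 1 = indistinguishable from normal).
    """

    grid_size: int = 128
    n_frames: int = 30
    center: tuple[float, float] = (64.0, 64.0)  # (row, col), subpixel
    r_endo_ed: float = 24.0
    wall_thickness_ed: float = 10.0
    contraction_fraction: float = 0.25
    scar_present: bool = False
    scar_sector: tuple[float, float] = (0.0, math.pi / 2)  # (theta_start, theta_width)
    scar_motion_ratio: float = 0.0
    intensity_blood: float = 200.0
    intensity_myo: float = 80.0
    intensity_bg: float = 20.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.r_endo_ed > 0:
            raise ValueError("r_endo_ed must be positive")
        if not self.wall_thickness_ed > 0:
            raise ValueError("wall_thickness_ed must be positive")
        if not self.r_endo_ed + self.wall_thickness_ed < self.grid_size / 2:
            raise ValueError(
                "r_endo_ed + wall_thickness_ed must fit inside half the grid_size"
            )
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if not 0.0 <= self.contraction_fraction <= 0.5:
            raise ValueError("contraction_fraction must lie in [0, 0.5]")
        if not 0.0 <= self.scar_motion_ratio <= 1.0:
            raise ValueError("scar_motion_ratio must lie in [0, 1]")
        if not 0.0 <= self.scar_sector[1] < _TWO_PI:
            raise ValueError("scar_sector width must lie in [0, 2*pi)")


@dataclass
class PhantomPatient:
    """One synthetic patient: an ordered stack of phantom slices.

    The patient label is SCAR iff at least one slice is SCAR, mirroring how
    patient-level ground truth is defined from per-slice labels.
    """

    patient_id: str
    slices: list[tuple[CineLoop, ContourSet, str]] = field(default_factory=list)

    @property
    def patient_label(self) -> str:
        return SCAR if any(lbl == SCAR for (_, _, lbl) in self.slices) else NL


def _in_sector(theta: np.ndarray, start: float, width: float) -> np.ndarray:
    """Membership of angles in the half-open sector [start, start+width)."""
    rel = np.mod(theta - start, _TWO_PI)
    return rel < width


def _radii_at(cfg: PhantomConfig, t: int, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Endo/epi radii at frame t for angles theta (vectorised)."""
    a = np.full_like(theta, cfg.contraction_fraction, dtype=float)
    if cfg.scar_present and cfg.scar_sector[1] > 0:
        scar = _in_sector(theta, cfg.scar_sector[0], cfg.scar_sector[1])
        a[scar] = cfg.scar_motion_ratio * cfg.contraction_fraction
    phase = 0.5 * (1.0 - math.cos(_TWO_PI * t / cfg.n_frames))
    r_endo = cfg.r_endo_ed - a * cfg.r_endo_ed * phase
    r_epi_ed = cfg.r_endo_ed + cfg.wall_thickness_ed
    # incompressible wall: conserve annular area per angle
    r_epi = np.sqrt(r_endo**2 + (r_epi_ed**2 - cfg.r_endo_ed**2))
    return r_endo, r_epi


def _contour_polygon(cfg: PhantomConfig, t: int, which: str, n_vertices: int = 72) -> np.ndarray:
    """Analytic (x, y) polygon of the endo or epi boundary at frame t."""
    theta = np.arange(n_vertices) * (_TWO_PI / n_vertices)
    r_endo, r_epi = _radii_at(cfg, t, theta)
    r = r_endo if which == "endo" else r_epi
    row0, col0 = cfg.center
    x = col0 + r * np.cos(theta)
    y = row0 + r * np.sin(theta)
    return np.stack([x, y], axis=1)


def generate_loop(config: PhantomConfig) -> tuple[CineLoop, ContourSet, str]:
    """Render one phantom cine loop with analytic contours and a GT label.

    Returns a T x H x W intensity stack (frame 0 = end-diastole by
    construction), per-frame endocardial/epicardial polygons (72 vertices),
    and the slice label: SCAR iff ``scar_present`` with a non-empty sector.
    Deterministic given ``config.seed``.
    """
    config.validate()
    n = config.grid_size
    T = config.n_frames
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    dr = rows - config.center[0]
    dc = cols - config.center[1]
    radius = np.hypot(dr, dc)
    theta = np.mod(np.arctan2(dr, dc), _TWO_PI)

    frames = np.empty((T, n, n), dtype=float)
    endo_polys: list[np.ndarray] = []
    epi_polys: list[np.ndarray] = []
    for t in range(T):
        r_endo, r_epi = _radii_at(config, t, theta)
        # linear one-pixel coverage ramp across each circular boundary
        cov_endo = np.clip(r_endo - radius + 0.5, 0.0, 1.0)
        cov_epi = np.clip(r_epi - radius + 0.5, 0.0, 1.0)
        frames[t] = (
            config.intensity_bg
            + (config.intensity_myo - config.intensity_bg) * cov_epi
            + (config.intensity_blood - config.intensity_myo) * cov_endo
        )
        endo_polys.append(_contour_polygon(config, t, "endo"))
        epi_polys.append(_contour_polygon(config, t, "epi"))

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        frames = frames + rng.normal(0.0, config.noise_sigma, size=frames.shape)

    loop = CineLoop(frames=frames, pixel_spacing=(1.0, 1.0), patient_id="", slice_index=0)
    contours = ContourSet(
        endo={t: endo_polys[t] for t in range(T)},
        epi={t: epi_polys[t] for t in range(T)},
    )
    label = SCAR if (config.scar_present and config.scar_sector[1] > 0) else NL
    return loop, contours, label


def generate_cohort(
    n_scar_patients: int,
    n_control_patients: int,
    slices_per_patient: int,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[PhantomPatient]:
    """Generate a cohort with per-patient anatomical and intensity jitter.

    Scar patients carry at least one SCAR slice (each slice is scarred with
    probability 0.7, and one is forced if the draw yields none); control
    patients carry none.  Jitter covers centre position, radii, wall
    thickness, gray levels and scar-sector position.  Reproducible given
    ``seed``.
    """
    if n_scar_patients < 0 or n_control_patients < 0:
        raise ValueError("patient counts must be >= 0")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    base = base_config if base_config is not None else PhantomConfig()
    rng = np.random.default_rng(seed)
    patients: list[PhantomPatient] = []
    labels = [SCAR] * n_scar_patients + [NL] * n_control_patients
    for p_idx, group in enumerate(labels):
        pid = f"PH{p_idx:04d}"
        patient = PhantomPatient(patient_id=pid)
        # patient-level jitter, shared across the patient's slices
        jitter_center = rng.uniform(-2.0, 2.0, size=2)
        r_endo = base.r_endo_ed * rng.uniform(0.85, 1.15)
        wall = base.wall_thickness_ed * rng.uniform(0.85, 1.15)
        blood = base.intensity_blood * rng.uniform(0.9, 1.1)
        myo = base.intensity_myo * rng.uniform(0.9, 1.1)
        sector_start = rng.uniform(0.0, _TWO_PI)
        if group == SCAR:
            scar_flags = rng.random(slices_per_patient) < 0.7
            if not scar_flags.any():
                scar_flags[int(rng.integers(slices_per_patient))] = True
        else:
            scar_flags = np.zeros(slices_per_patient, dtype=bool)
        for s_idx in range(slices_per_patient):
            cfg = dataclasses.replace(
                base,
                center=(base.center[0] + jitter_center[0], base.center[1] + jitter_center[1]),
                r_endo_ed=r_endo,
                wall_thickness_ed=wall,
                intensity_blood=blood,
                intensity_myo=myo,
                scar_present=bool(scar_flags[s_idx]),
                scar_sector=(sector_start, base.scar_sector[1]),
                seed=int(rng.integers(2**31 - 1)),
            )
            loop, contours, label = generate_loop(cfg)
            loop.patient_id = pid
            loop.slice_index = s_idx
            patient.slices.append((loop, contours, label))
        if group == SCAR and patient.patient_label != SCAR:
            raise AssertionError("scar patient generated without a SCAR slice")
        patients.append(patient)
    return patients


def write_cohort(patients: Sequence[PhantomPatient], out_dir: str | Path) -> Path:
    """Write loops as NIfTI + JSON sidecars and a JSON-lines manifest.

    Returns the manifest path.  Each manifest line holds patient_id,
    slice_index, loop_path, contour_path and gt_label, one record per slice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as mf:
        for patient in patients:
            for loop, contours, label in patient.slices:
                stem = f"{patient.patient_id}_s{loop.slice_index:02d}"
                nii_path = out / f"{stem}.nii"
                sidecar_path = out / f"{stem}.json"
                img = nib.Nifti1Image(
                    np.asarray(loop.frames, dtype=np.float32), affine=np.eye(4)
                )
                nib.save(img, nii_path)
                sidecar = {
                    "time_axis": 0,
                    "pixel_spacing": list(loop.pixel_spacing),
                    "patient_id": patient.patient_id,
                    "slice_index": loop.slice_index,
                    "gt_label": label,
                    "endo": {str(t): poly.tolist() for t, poly in contours.endo.items()},
                    "epi": {str(t): poly.tolist() for t, poly in contours.epi.items()},
                }
                sidecar_path.write_text(json.dumps(sidecar))
                record = {
                    "patient_id": patient.patient_id,
                    "slice_index": loop.slice_index,
                    "loop_path": str(nii_path.name),
                    "contour_path": str(sidecar_path.name),
                    "gt_label": label,
                }
                mf.write(json.dumps(record, sort_keys=True) + "\n")
    return manifest_path
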