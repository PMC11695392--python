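"""Cine-loop and contour I/O, mask rasterization, ED/ES frame selection.

Coordinate convention used package-wide: 0-based pixel indices, ``x`` is the
column and ``y`` the row, and a pixel "contains" a point when the point falls
on the pixel's centre (integer coordinates).  Polygon membership uses the
even-odd (ray crossing) rule with the standard half-open edge treatment, so
a pixel centre lying exactly on a boundary belongs to exactly one of two
abutting polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

SCAR = "SCAR"
NL = "NL"


@dataclass
class CineLoop:
    """One slice's T x H x W videointensity stack plus geometry metadata."""

    frames: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    patient_id: str = ""
    slice_index: int = 0
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        T, H, W = self.frames.shape
        if T < 3:
            raise ValueError("a cine loop needs at least 3 frames")
        if H < 16 or W < 16:
            raise ValueError("frames must be at least 16 x 16 pixels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ContourSet:
    """Endocardial/epicardial polygons per frame, (x, y) subpixel vertices."""

    endo: dict[int, np.ndarray] = field(default_factory=dict)
    epi: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def frames_present(self) -> list[int]:
        return sorted(set(self.endo) & set(self.epi))


@dataclass(frozen=True)
class SliceRecord:
    """One manifest row: where a slice's loop and contours live, plus GT."""

    patient_id: str
    slice_index: int
    loop_path: Path
    contour_path: Path
    gt_label: str


_MANIFEST_FIELDS = ("patient_id", "slice_index", "loop_path", "contour_path", "gt_label")


def read_manifest(path: str | Path) -> list[SliceRecord]:
    """Parse a JSON-lines manifest into slice records, in file order."""
    path = Path(path)
    records: list[SliceRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"manifest line {lineno}: invalid JSON ({exc})") from exc
            missing = [f for f in _MANIFEST_FIELDS if f not in obj]
            if missing:
                raise ValueError(
                    f"manifest line {lineno}: missing field(s) {', '.join(missing)}"
                )
            if obj["gt_label"] not in (SCAR, NL):
                raise ValueError(
                    f"manifest line {lineno}: gt_label must be SCAR or NL"
                )
            records.append(
                SliceRecord(
                    patient_id=str(obj["patient_id"]),
                    slice_index=int(obj["slice_index"]),
                    loop_path=path.parent / obj["loop_path"],
                    contour_path=path.parent / obj["contour_path"],
                    gt_label=obj["gt_label"],
                )
            )
    return records


def _load_sidecar_contours(sidecar: dict) -> ContourSet:
    contours = ContourSet()
    for key, store in (("endo", contours.endo), ("epi", contours.epi)):
        for t, poly in sidecar.get(key, {}).items():
            store[int(t)] = np.asarray(poly, dtype=float)
    return contours


def load_loop(record: SliceRecord) -> tuple[CineLoop, ContourSet]:
    """Load a slice's cine loop (NIfTI or DICOM series) and its contours.

    NIfTI volumes must declare the time axis in the JSON sidecar
    (``"time_axis": 0`` or ``2``); frames are normalised to T x H x W.
    A directory path is read as a DICOM series sorted by instance number,
    with vendor rescale slope/intercept applied and nothing else.
    """
    if not Path(record.contour_path).exists():
        raise FileNotFoundError(f"contour sidecar not found: {record.contour_path}")
    sidecar = json.loads(Path(record.contour_path).read_text())
    contours = _load_sidecar_contours(sidecar)

    loop_path = Path(record.loop_path)
    if not loop_path.exists():
        raise FileNotFoundError(f"loop not found: {loop_path}")
    if loop_path.is_dir():
        frames, spacing = _read_dicom_series(loop_path)
    else:
        img = nib.load(loop_path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4:  # singleton spatial dim from 4-D writers
            data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D cine volume, got shape {data.shape}")
        if "time_axis" not in sidecar:
            raise ValueError(
                "NIfTI loop without 'time_axis' declaration in sidecar: "
                "cannot disambiguate the temporal axis"
            )
        time_axis = int(sidecar["time_axis"])
        if time_axis not in (0, 2):
            raise ValueError("time_axis must be 0 (leading) or 2 (trailing)")
        frames = np.moveaxis(data, time_axis, 0)
        spacing = tuple(sidecar.get("pixel_spacing", (1.0, 1.0)))

    loop = CineLoop(
        frames=frames,
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        patient_id=record.patient_id,
        slice_index=record.slice_index,
    )
    return loop, contours


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple[float, float]]:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    datasets = [pydicom.dcmread(p) for p in files if p.is_file()]
    if not datasets:
        raise FileNotFoundError(f"no DICOM files in {directory}")

    def sort_key(ds):
        trigger = getattr(ds, "TriggerTime", None)
        instance = getattr(ds, "InstanceNumber", 0)
        return (float(trigger), int(instance)) if trigger is not None else (0.0, int(instance))

    datasets.sort(key=sort_key)
    frames = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
    spacing = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    return np.stack(frames, axis=0), (float(spacing[0]), float(spacing[1]))


def rasterize_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon to a boolean mask on an H x W grid.

    A pixel (r, c) is inside iff its centre (x=c, y=r) is inside the polygon
    under the even-odd rule; edges are treated half-open by the classic ray
    crossing test, so shared boundaries never double-count.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[0] < 3 or polygon.shape[1] != 2:
        raise ValueError("polygon must be an N x 2 array with N >= 3")
    H, W = shape
    cols, rows = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    px = cols.ravel()
    py = rows.ravel()
    inside = np.zeros(px.shape, dtype=bool)
    x = polygon[:, 0]
    y = polygon[:, 1]
    xj = np.roll(x, 1)
    yj = np.roll(y, 1)
    for xi, yi, xjj, yjj in zip(x, y, xj, yj):
        crosses = (yi > py) != (yjj > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (xjj - xi) * (py - yi) / (yjj - yi) + xi
        inside ^= crosses & (px < x_at)
    return inside.reshape(H, W)


def myocardium_mask(
    contours: ContourSet, frame: int, shape: tuple[int, int]
) -> np.ndarray:
    """Myocardium = inside epicardium AND outside endocardium."""
    epi = rasterize_mask(contours.epi[frame], shape)
    endo = rasterize_mask(contours.endo[frame], shape)
    return epi & ~endo


def _polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of an (x, y) polygon."""
    x = poly[:, 0]
    y = poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _blood_pool_areas(loop: CineLoop, contours: ContourSet) -> np.ndarray:
    """Per-frame blood-pool area: analytic from endo contours if available at
    every frame, otherwise by thresholding within the epicardium (Otsu)."""
    T = loop.n_frames
    if all(t in contours.endo for t in range(T)):
        return np.array([_polygon_area(contours.endo[t]) for t in range(T)])
    if not contours.epi:
        raise ValueError(
            "ED/ES selection needs endo contours at every frame or at least "
            "one epicardial contour for the thresholding fallback"
        )
    from skimage.filters import threshold_otsu

    epi_frame = sorted(contours.epi)[0]
    epi = rasterize_mask(contours.epi[epi_frame], loop.shape)
    areas = np.empty(T)
    for t in range(T):
        vals = loop.frames[t][epi]
        thr = threshold_otsu(vals)
        areas[t] = float(np.count_nonzero(vals > thr))
    return areas


def select_ed_frame(loop: CineLoop, contours: ContourSet) -> int:
    """End-diastolic frame: the one with the largest LV blood pool.

    Ties break to the smallest frame index.
    """
    areas = _blood_pool_areas(loop, contours)
    return int(np.argmax(areas))


def select_es_frame(loop: CineLoop, contours: ContourSet) -> int:
    """End-systolic frame: smallest blood pool; ties to the smallest index."""
    areas = _blood_pool_areas(loop, contours)
    return int(np.argmin(areas))
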