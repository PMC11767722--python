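"""Binary lumen-mask ingestion, area measurement and remodeling-stage labeling.

A lumen mask is a 2D binary raster in which ``True`` marks pixels occupied by
the perfusable lumen of an in vitro microvascular network at one time point.
This module cleans raw masks (small-object removal, hole filling), measures
the total lumen area — the basic morphological readout of the culture — and
classifies each frame of a time-lapse into the five canonical morphological
stages of long-term perfusion culture:

    meshwork -> sprouting -> remodeling -> stable -> erosion

The stage classifier is an operationalization of what is, experimentally, a
qualitative taxonomy: the smoothed area derivative separates rising / falling
/ flat phases, and the skeleton-orientation anisotropy separates the isotropic
meshwork from directional sprouting.  A day-range fallback labeling is also
provided for runs where only acquisition days are trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "Stage",
    "STAGE_ORDER",
    "LumenMask",
    "AreaMeasurement",
    "StageLabel",
    "StageParams",
    "MaskError",
    "clean_mask",
    "measure_area",
    "classify_stages",
    "classify_stages_by_day",
    "otsu_threshold_mask",
    "read_mask",
    "read_mask_dir",
    "write_mask",
    "areas_to_frame",
]


class MaskError(ValueError):
    """Raised when a mask is empty or otherwise unusable."""


class Stage(str, Enum):
    MESHWORK = "meshwork"
    SPROUTING = "sprouting"
    REMODELING = "remodeling"
    STABLE = "stable"
    EROSION = "erosion"


#: Canonical temporal order of the morphological stages.
STAGE_ORDER: tuple[Stage, ...] = (
    Stage.MESHWORK,
    Stage.SPROUTING,
    Stage.REMODELING,
    Stage.STABLE,
    Stage.EROSION,
)

# Observational day ranges for the fallback labeling mode (start day of each
# stage; the last stage is open-ended).
_STAGE_START_DAYS = {
    Stage.MESHWORK: 0.0,
    Stage.SPROUTING: 8.0,
    Stage.REMODELING: 20.0,
    Stage.STABLE: 30.0,
    Stage.EROSION: 45.0,
}


@dataclass
class LumenMask:
    """Binary lumen raster at one time point.

    pixels
        2D boolean grid, row-major, row 0 at the top.
    pixel_size_um
        Physical edge length of one pixel, micrometres.
    time_point
        Acquisition time in days (float).
    frame_id
        Integer index of the frame within its time-lapse.
    """

    pixels: np.ndarray
    pixel_size_um: float
    time_point: float = 0.0
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise MaskError(f"mask must be 2D, got shape {self.pixels.shape}")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels != 0
        if self.pixel_size_um <= 0:
            raise MaskError("pixel_size_um must be positive")
        if not self.pixels.any():
            raise MaskError("no lumen pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_size_m(self) -> float:
        return self.pixel_size_um * 1e-6


@dataclass(frozen=True)
class AreaMeasurement:
    """Total lumen area of one frame (exact pixel count + physical units)."""

    area_px: int
    area_um2: float
    time_point: float
    frame_id: int = 0


@dataclass(frozen=True)
class StageLabel:
    """One contiguous run of frames assigned to a single stage."""

    stage: Stage
    frame_range: tuple[int, int]  # inclusive [start, end]


@dataclass
class StageParams:
    """Tunables of the slope/anisotropy stage classifier.

    smooth_window
        Centered moving-average window (frames) applied to the area series
        before differentiating.
    flat_tol
        |d(area)/d(frame)| below ``flat_tol * max(area)`` counts as flat.
    min_stage_frames
        Minimum persistence of a stage; shorter runs are merged into their
        predecessor.
    aniso_threshold
        Skeleton-orientation coherence (1 - circular variance of doubled
        angles) above which a rising phase is called sprouting rather than
        meshwork.
    """

    smooth_window: int = 3
    flat_tol: float = 0.01
    min_stage_frames: int = 2
    aniso_threshold: float = 0.3


# ---------------------------------------------------------------------------
# Cleaning and measurement
# ---------------------------------------------------------------------------

def remove_small_components(
    m: np.ndarray, min_size: int, connectivity: int = 2
) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` pixels.

    8-connectivity by default (``connectivity=2``), matching the standard
    digital-topology pairing of 8-connected objects / 4-connected background.
    """
    if min_size <= 1 or not m.any():
        return m
    structure = np.ones((3, 3), bool) if connectivity == 2 else None
    lab, n = ndi.label(m, structure=structure)
    if n == 0:
        return m
    counts = np.bincount(lab.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[lab]


def clean_mask(
    raw: np.ndarray,
    min_object_px: int = 50,
    fill_holes: bool = True,
    pixel_size_um: float = 1.5625,
    time_point: float = 0.0,
    frame_id: int = 0,
) -> LumenMask:
    """Binarize and clean a raw mask.

    Connected components (8-connectivity) smaller than ``min_object_px`` are
    removed; interior holes (4-connected background) are filled when
    ``fill_holes`` is set.  Raises :class:`MaskError` naming the cause when
    nothing survives.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise MaskError(f"mask must be 2D, got shape {raw.shape}")
    m = raw != 0
    if not m.any():
        raise MaskError("no lumen pixels")
    if min_object_px > 1:
        m = remove_small_components(m, min_object_px)
    if fill_holes:
        m = ndi.binary_fill_holes(m)
    if not m.any():
        raise MaskError(
            f"no lumen pixels left after removing objects < {min_object_px} px"
        )
    return LumenMask(m, pixel_size_um, time_point=time_point, frame_id=frame_id)


def measure_area(mask: LumenMask) -> AreaMeasurement:
    """Total lumen area as the exact count of true pixels (+ µm² conversion)."""
    n = int(np.count_nonzero(mask.pixels))
    return AreaMeasurement(
        area_px=n,
        area_um2=n * mask.pixel_size_um**2,
        time_point=mask.time_point,
        frame_id=mask.frame_id,
    )


def otsu_threshold_mask(image: np.ndarray) -> np.ndarray:
    """Otsu-threshold baseline segmentation for grayscale renders.

    Provided only as a trivial baseline for noisy synthetic renders; real
    brightfield segmentation is out of scope (the pipeline consumes binary
    masks).
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    return image > threshold_otsu(image)


# ---------------------------------------------------------------------------
# Stage classification
# ---------------------------------------------------------------------------

# Trend each stage is expected to show: +1 rising, -1 falling, 0 flat.
_STAGE_TREND = {
    Stage.MESHWORK: 1,
    Stage.SPROUTING: 1,
    Stage.REMODELING: -1,
    Stage.STABLE: 0,
    Stage.EROSION: 1,
}


def _runs_to_labels(labels: list[Stage]) -> list[StageLabel]:
    out: list[StageLabel] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            out.append(StageLabel(labels[start], (start, i - 1)))
            start = i
    return out


def classify_stages(
    areas: Sequence[AreaMeasurement],
    anisotropy: Sequence[float],
    params: StageParams | None = None,
) -> list[StageLabel]:
    """Label each frame with a morphological stage.

    The smoothed area derivative is thresholded into rising/falling/flat; a
    forward state machine then walks the canonical stage order: a rising phase
    is meshwork until the orientation anisotropy exceeds
    ``params.aniso_threshold`` (then sprouting), a falling phase is
    remodeling, a flat phase is stable, and a rise after a stable run is
    erosion.  Stages never reorder; runs shorter than
    ``params.min_stage_frames`` are merged into their predecessor.
    """
    params = params or StageParams()
    n = len(areas)
    if n < 5:
        raise ValueError(f"need at least 5 frames, got {n}")
    if n < params.smooth_window:
        raise ValueError("fewer frames than the smoothing window")
    if len(anisotropy) != n:
        raise ValueError("anisotropy must have one value per frame")

    a = np.array([m.area_px for m in areas], dtype=float)
    smooth = ndi.uniform_filter1d(a, size=params.smooth_window, mode="nearest")
    slope = np.gradient(smooth)
    tol = params.flat_tol * a.max()
    trend = np.zeros(n, dtype=int)
    trend[slope > tol] = 1
    trend[slope < -tol] = -1

    aniso = np.asarray(anisotropy, dtype=float)
    # Allowed forward transitions.  Stable is only reachable once the area
    # has actually fallen (remodeling), so a single smoothing-flattened frame
    # at the sprouting peak cannot skip the remodeling stage; erosion is only
    # reachable after a stable run.
    allowed = {
        Stage.MESHWORK: (Stage.REMODELING,),
        Stage.SPROUTING: (Stage.REMODELING,),
        Stage.REMODELING: (Stage.STABLE,),
        Stage.STABLE: (Stage.EROSION,),
        Stage.EROSION: (),
    }
    labels: list[Stage] = []
    cur = Stage.MESHWORK
    for i in range(n):
        t = trend[i]
        if cur is Stage.MESHWORK and t >= 0 and aniso[i] > params.aniso_threshold:
            cur = Stage.SPROUTING
        if _STAGE_TREND[cur] != t:
            for cand in allowed[cur]:
                if _STAGE_TREND[cand] == t:
                    cur = cand
                    break
            # no consistent transition -> stay put (stages never reorder)
        labels.append(cur)

    # Enforce minimum stage persistence by merging short runs backwards.
    merged = True
    while merged:
        merged = False
        runs = _runs_to_labels(labels)
        for k, run in enumerate(runs):
            length = run.frame_range[1] - run.frame_range[0] + 1
            if length < params.min_stage_frames and len(runs) > 1:
                target = runs[k - 1].stage if k > 0 else runs[k + 1].stage
                for j in range(run.frame_range[0], run.frame_range[1] + 1):
                    labels[j] = target
                merged = True
                break
    return _runs_to_labels(labels)


def classify_stages_by_day(
    time_points: Sequence[float],
) -> list[StageLabel]:
    """Fallback labeling from the observational day ranges of the culture."""
    labels: list[Stage] = []
    bounds = sorted(_STAGE_START_DAYS.items(), key=lambda kv: kv[1])
    for t in time_points:
        stage = bounds[0][0]
        for s, start in bounds:
            if t >= start:
                stage = s
        labels.append(stage)
    return _runs_to_labels(labels)


def labels_per_frame(labels: Sequence[StageLabel], n_frames: int) -> list[Stage]:
    """Expand contiguous stage ranges to one stage per frame."""
    out: list[Stage | None] = [None] * n_frames
    for lab in labels:
        for i in range(lab.frame_range[0], lab.frame_range[1] + 1):
            out[i] = lab.stage
    if any(s is None for s in out):
        raise ValueError("stage ranges do not tile the frame axis")
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_mask(
    path: str | Path,
    pixel_size_um: float,
    time_point: float = 0.0,
    frame_id: int = 0,
    **clean_kwargs,
) -> LumenMask:
    """Read an 8-bit single-channel TIFF/PNG mask (nonzero = lumen)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    if raw.ndim == 3:  # collapse an accidental channel axis
        raw = raw[..., 0]
    return clean_mask(
        raw,
        pixel_size_um=pixel_size_um,
        time_point=time_point,
        frame_id=frame_id,
        **clean_kwargs,
    )


def write_mask(path: str | Path, mask: LumenMask) -> None:
    """Write a mask as 8-bit single-channel TIFF (0 = non-lumen, 255 = lumen)."""
    import tifffile

    tifffile.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


def read_mask_dir(
    directory: str | Path,
    pixel_size_um: float,
    pattern: str = "frame_*.tif",
    **clean_kwargs,
) -> list[LumenMask]:
    """Read a time-ordered directory of ``frame_####.tif`` masks."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no masks matching {pattern!r} in {directory}")
    return [
        read_mask(p, pixel_size_um, time_point=float(i), frame_id=i, **clean_kwargs)
        for i, p in enumerate(paths)
    ]


def areas_to_frame(
    areas: Sequence[AreaMeasurement],
    labels: Sequence[StageLabel] | None = None,
) -> pd.DataFrame:
    """Tidy table of the per-frame area series (and stages when given)."""
    df = pd.DataFrame(
        {
            "frame_id": [m.frame_id for m in areas],
            "day": [m.time_point for m in areas],
            "area_px": [m.area_px for m in areas],
            "area_um2": [m.area_um2 for m in areas],
        }
    )
    if labels is not None:
        per_frame = labels_per_frame(labels, len(areas))
        df["stage"] = [s.value for s in per_frame]
    return df
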