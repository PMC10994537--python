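"""Core containers for dynamic PET data: frame schedules, 4D images, masks,
region label maps and time-activity curves (TACs), plus the per-frame
normalization used throughout the quantification pipeline.

Conventions
-----------
* Frame times are stored in **seconds**; kinetic rate constants elsewhere in
  the package are per **minute**.
* A frame schedule is contiguous and starts at t = 0; a single representative
  time per frame is always the mid-frame time.
* 4D arrays are laid out ``(x, y, z, frame)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FrameScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations (seconds) of a dynamic acquisition.

    Frames must be contiguous: ``starts[i+1] == starts[i] + durations[i]``.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise FrameScheduleError("starts and durations must be 1-D and equal length")
        if len(starts) == 0:
            raise FrameScheduleError("schedule must contain at least one frame")
        if np.any(durations <= 0):
            raise FrameScheduleError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise FrameScheduleError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise FrameScheduleError("frames must be contiguous")

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    @property
    def mids(self) -> np.ndarray:
        """Mid-frame times in seconds."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """Total scan length in seconds."""
        return float(self.ends[-1] - self.starts[0])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.durations, other.durations)
        )


def build_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from an ordered list of (count, duration-s).

    E.g. the 60-min protocol ``[(6, 10), (8, 30), (5, 60), (5, 120), (8, 300)]``
    yields 32 frames totalling 3600 s.
    """
    if not spec:
        raise FrameScheduleError("empty frame specification")
    durations = []
    for count, dur in spec:
        if count < 1:
            raise FrameScheduleError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise FrameScheduleError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    durations = np.array(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass(frozen=True)
class TAC:
    """A time-activity curve: one activity value per frame."""

    values: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != self.schedule.n_frames:
            raise ValueError("TAC length must match its schedule")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")


@dataclass(frozen=True)
class DynamicImage:
    """A 4D dynamic PET volume bound to a frame schedule and voxel geometry."""

    values: np.ndarray  # (x, y, z, frame)
    schedule: FrameSchedule
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if values.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"image has {values.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        affine = self.affine
        if affine is None:
            affine = np.eye(4)
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass(frozen=True)
class LabelMap:
    """Integer region labels on an image grid; 0 is reserved for background."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        object.__setattr__(self, "labels", labels)
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        affine = np.eye(4) if self.affine is None else np.asarray(self.affine, float)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the named region."""
        ids = [i for i, n in self.names.items() if n == name]
        if not ids:
            raise KeyError(f"region {name!r} not in label map")
        return np.isin(self.labels, ids)

    def brain_mask(self) -> np.ndarray:
        return self.labels != 0

    @property
    def region_names(self) -> list[str]:
        return [self.names[i] for i in sorted(self.names)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def extract_tac(image: DynamicImage, mask: np.ndarray) -> TAC:
    """Mean time-activity curve over a voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask grid does not match image grid")
    if not mask.any():
        raise ValueError("cannot extract a TAC from an empty mask")
    return TAC(image.values[mask].mean(axis=0), image.schedule)


def normalize_frames(image: DynamicImage, brain_mask: np.ndarray) -> DynamicImage:
    """Z-score each frame over the brain: subtract the within-brain mean and
    divide by the within-brain (population) standard deviation of that frame.

    Voxels outside ``brain_mask`` are set to 0; the brain mask itself is the
    validity mask and must accompany the result — zeros outside it are a
    storage sentinel, not data.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != image.shape:
        raise ValueError("brain mask grid does not match image grid")
    if brain_mask.sum() < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    out = np.zeros_like(image.values)
    brain = image.values[brain_mask]  # (n_voxels, n_frames)
    means = brain.mean(axis=0)
    sds = brain.std(axis=0)  # population SD (ddof=0)
    bad = np.flatnonzero(sds <= 1e-12 * np.maximum(1.0, np.abs(means)))
    if bad.size:
        raise ValueError(f"zero within-brain standard deviation in frame {bad[0]}")
    out[brain_mask] = (brain - means) / sds
    return DynamicImage(out, image.schedule, image.affine)


_STRUCT_6CONN = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary erosion with a 6-connected (face-neighbour) structuring element.

    Used to shave region borders before class extraction, limiting partial
    volume contamination. ``iterations=0`` is the identity; an empty result is
    allowed and left to the caller to check.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_STRUCT_6CONN, iterations=iterations)


def sphere_voi(centre: np.ndarray, radius: float, shape: tuple, affine: np.ndarray) -> np.ndarray:
    """Spherical VOI: voxels whose centre lies within ``radius`` mm of a world
    point. Used for the 5-mm lesion sample VOIs.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centre = np.asarray(centre, dtype=float)
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    d2 = ((world - centre[:, None]) ** 2).sum(axis=0)
    mask = (d2 <= radius**2).reshape(shape)
    if not mask.any():
        raise ValueError("sphere lies entirely outside the image grid")
    return mask


# ---------------------------------------------------------------------------
# I/O — NIfTI-1 with a JSON frame-timing sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_dynamic(image: DynamicImage, path: str | Path) -> None:
    """Write a 4D NIfTI plus a JSON sidecar holding the frame schedule
    (NIfTI-1 has no universally honoured frame-timing field).
    """
    path = Path(path)
    nib.save(nib.Nifti1Image(image.values, image.affine), str(path))
    sidecar = {
        "frame_starts_s": image.schedule.starts.tolist(),
        "frame_durations_s": image.schedule.durations.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_dynamic(path: str | Path) -> DynamicImage:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    meta = json.loads(_sidecar_path(path).read_text())
    schedule = FrameSchedule(
        np.array(meta["frame_starts_s"]), np.array(meta["frame_durations_s"])
    )
    if values.ndim != 4 or values.shape[3] != schedule.n_frames:
        n = values.shape[3] if values.ndim == 4 else "non-4D"
        raise ValueError(
            f"image has {n} frames but sidecar schedule has {schedule.n_frames}"
        )
    return DynamicImage(values, schedule, img.affine)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write labels as NIfTI and names as a TSV (id, name) next to it."""
    path = Path(path)
    nib.save(nib.Nifti1Image(label_map.labels.astype(np.int16), label_map.affine), str(path))
    tsv = _sidecar_path(path).with_suffix(".tsv")
    lines = ["id\tname"] + [f"{i}\t{label_map.names[i]}" for i in sorted(label_map.names)]
    tsv.write_text("\n".join(lines) + "\n")


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    tsv = _sidecar_path(path).with_suffix(".tsv")
    names = {}
    for line in tsv.read_text().strip().splitlines()[1:]:
        i, name = line.split("\t")
        names[int(i)] = name
    return LabelMap(labels, names, img.affine)
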