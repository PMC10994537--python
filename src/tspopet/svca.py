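"""Supervised cluster analysis (SVCA) kinetic class construction.

From frame-normalized control images, four kinetic class curves are built per
binding-affinity group (HAB and MAB, independently):

* **blood** — the 40 voxels with the most activity in the first 3 min,
* **specific binding grey matter** — the eroded thalamus,
* **non-specific binding grey matter** — the eroded cerebellar grey matter,
* **white matter** — the eroded supratentorial white matter.

Per-subject class curves are averaged across retained control subjects;
controls whose non-specific grey matter profile deviates grossly from the
group are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TAC, DynamicImage, FrameSchedule, LabelMap, erode_mask, extract_tac

CLASS_NAMES = ("blood", "specific_gm", "nonspecific_gm", "white_matter")

#: region of the label map backing each anatomical class
CLASS_REGIONS = {
    "specific_gm": "thalamus",
    "nonspecific_gm": "cerebellum_gm",
    "white_matter": "white_matter",
}


@dataclass(frozen=True)
class KineticClassSet:
    """The four SVCA class TACs for one binding-affinity group."""

    blood: TAC
    specific_gm: TAC
    nonspecific_gm: TAC
    white_matter: TAC
    affinity_group: str
    n_controls_used: int

    def __post_init__(self):
        sched = self.blood.schedule
        for name in ("specific_gm", "nonspecific_gm", "white_matter"):
            if getattr(self, name).schedule != sched:
                raise ValueError("all class TACs must share one schedule")

    @property
    def schedule(self) -> FrameSchedule:
        return self.blood.schedule

    def as_matrix(self) -> np.ndarray:
        """(n_frames, 4) design matrix in canonical class order."""
        return np.column_stack([getattr(self, n).values for n in CLASS_NAMES])

    def to_dict(self) -> dict:
        return {
            "affinity_group": self.affinity_group,
            "n_controls_used": self.n_controls_used,
            "frame_starts_s": self.schedule.starts.tolist(),
            "frame_durations_s": self.schedule.durations.tolist(),
            "curves": {n: getattr(self, n).values.tolist() for n in CLASS_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticClassSet":
        sched = FrameSchedule(
            np.array(d["frame_starts_s"]), np.array(d["frame_durations_s"])
        )
        curves = {n: TAC(np.array(d["curves"][n]), sched) for n in CLASS_NAMES}
        return cls(
            affinity_group=d["affinity_group"],
            n_controls_used=d["n_controls_used"],
            **curves,
        )


def select_blood_voxels(
    norm_image: DynamicImage,
    brain_mask: np.ndarray,
    n: int = 40,
    window_s: float = 180.0,
) -> np.ndarray:
    """Mask of the ``n`` brain voxels with the most activity within the first
    ``window_s`` seconds (duration-weighted sum over frames ending inside the
    window). Ties break deterministically on lexicographic voxel index.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != norm_image.shape:
        raise ValueError("brain mask grid does not match image grid")
    n_avail = int(brain_mask.sum())
    if n_avail < n:
        raise ValueError(f"brain mask has {n_avail} voxels, need at least {n}")
    sched = norm_image.schedule
    early = sched.ends <= window_s
    if not early.any():
        raise ValueError("no frame ends within the selection window")
    score = (norm_image.values[..., early] * sched.durations[early]).sum(axis=-1)
    flat_idx = np.flatnonzero(brain_mask.ravel())
    order = np.argsort(-score.ravel()[flat_idx], kind="stable")
    chosen = flat_idx[order[:n]]
    mask = np.zeros(norm_image.values.shape[:3], dtype=bool)
    mask.ravel()[chosen] = True
    return mask


def default_class_masks(
    norm_image: DynamicImage,
    label_map: LabelMap,
    erosion_iterations: int = 1,
    n_blood: int = 40,
) -> dict[str, np.ndarray]:
    """Build the four class masks from a label map: blood by early-activity
    selection, the anatomical classes from eroded regions."""
    masks = {"blood": select_blood_voxels(norm_image, label_map.brain_mask(), n=n_blood)}
    for cls, region in CLASS_REGIONS.items():
        masks[cls] = erode_mask(label_map.mask(region), erosion_iterations)
    return masks


def subject_class_curves(
    norm_image: DynamicImage, masks: dict[str, np.ndarray]
) -> dict[str, TAC]:
    """Mean normalized TAC per kinetic class for one subject."""
    curves = {}
    for name in CLASS_NAMES:
        if name not in masks:
            raise ValueError(f"missing mask for class {name!r}")
        mask = np.asarray(masks[name], dtype=bool)
        if not mask.any():
            raise ValueError(f"class {name!r} has an empty mask (after erosion?)")
        curves[name] = extract_tac(norm_image, mask)
    return curves


def aggregate_classes(
    per_subject_sets: list[dict[str, TAC]],
    affinity_group: str,
    outlier_threshold: float = 3.0,
) -> tuple[KineticClassSet, list[int]]:
    """Average per-subject class curves into one class set, excluding
    controls with a deviant non-specific grey matter profile.

    A subject is excluded when the RMS deviation of its non-specific-GM curve
    from the leave-one-out mean of the others exceeds ``outlier_threshold``
    times the group's median RMS deviation. Returns the class set and the
    indices of excluded subjects.
    """
    n = len(per_subject_sets)
    if n < 2:
        raise ValueError("need at least 2 subjects to aggregate classes")
    sched = per_subject_sets[0]["blood"].schedule
    nonspec = np.stack([s["nonspecific_gm"].values for s in per_subject_sets])
    total = nonspec.sum(axis=0)
    loo_means = (total[None, :] - nonspec) / (n - 1)
    rms = np.sqrt(((nonspec - loo_means) ** 2).mean(axis=1))
    med = np.median(rms)
    if med == 0:
        excluded = []  # identical subjects: nothing to exclude
    else:
        excluded = list(np.flatnonzero(rms > outlier_threshold * med))
    retained = [i for i in range(n) if i not in excluded]
    if not retained:
        raise ValueError("all subjects excluded by the outlier rule")
    curves = {}
    for name in CLASS_NAMES:
        stack = np.stack([per_subject_sets[i][name].values for i in retained])
        curves[name] = TAC(stack.mean(axis=0), sched)
    return (
        KineticClassSet(
            affinity_group=affinity_group, n_controls_used=len(retained), **curves
        ),
        excluded,
    )
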