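"""End-to-end quantification: normalized images -> SVCA classes -> NNLS
unmixing -> subject reference curve -> SRTM2 parametric map.

Class sets are built per binding-affinity group (HAB/MAB) from control
subjects only; every subject is then quantified against the class set of
their own genotype. Low-affinity binders are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DynamicImage, LabelMap, normalize_frames
from .kinetics import FitConfig, ParametricMap, parametric_map
from .svca import (
    KineticClassSet,
    aggregate_classes,
    default_class_masks,
    subject_class_curves,
)
from .synthetic import Cohort, SubjectRecord
from .unmix import nnls_unmix, reference_mask, reference_tac


@dataclass(frozen=True)
class QuantConfig:
    erosion_iterations: int = 1
    n_blood_voxels: int = 40
    weight_ratio_threshold: float = 0.9
    outlier_threshold: float = 3.0
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass(frozen=True)
class SubjectQuantification:
    record: SubjectRecord
    pmap: ParametricMap
    n_reference_voxels: int


def build_affinity_class_sets(
    controls: list[tuple[SubjectRecord, DynamicImage]],
    label_map: LabelMap,
    config: QuantConfig | None = None,
) -> dict[str, KineticClassSet]:
    """SVCA class sets per affinity group, from control subjects only.
    HAB and MAB sets are built from disjoint subject sets; LAB controls are
    ignored."""
    config = config or QuantConfig()
    brain = label_map.brain_mask()
    out = {}
    for affinity in ("HAB", "MAB"):
        per_subject = []
        for record, image in controls:
            if record.group != "control" or record.genotype != affinity:
                continue
            norm = normalize_frames(image, brain)
            masks = default_class_masks(
                norm, label_map,
                erosion_iterations=config.erosion_iterations,
                n_blood=config.n_blood_voxels,
            )
            per_subject.append(subject_class_curves(norm, masks))
        if len(per_subject) >= 2:
            class_set, _excluded = aggregate_classes(
                per_subject, affinity, config.outlier_threshold
            )
            out[affinity] = class_set
    if not out:
        raise ValueError("no affinity group has >= 2 control subjects")
    return out


def quantify_subject(
    image: DynamicImage,
    label_map: LabelMap,
    class_set: KineticClassSet,
    config: QuantConfig | None = None,
) -> tuple[ParametricMap, int]:
    """Quantify one subject: normalize, unmix onto the class set, build the
    pseudo-reference, fit SRTM2 voxel-wise. Returns the parametric map and
    the reference-region voxel count."""
    config = config or QuantConfig()
    brain = label_map.brain_mask()
    norm = normalize_frames(image, brain)
    weights = nnls_unmix(norm, class_set, brain)
    ref_mask = reference_mask(weights, config.weight_ratio_threshold)
    ref = reference_tac(image, ref_mask)
    # k2' pooled over high-SNR anatomical region TACs (blood pool excluded)
    regions = [
        label_map.mask(n) for n in label_map.names.values() if n != "blood_pool"
    ]
    pmap = parametric_map(image, ref, brain, config.fit, k2p_regions=regions)
    return pmap, int(ref_mask.sum())


def quantify_cohort(
    cohort: Cohort, config: QuantConfig | None = None
) -> dict[str, SubjectQuantification]:
    """Quantify every non-LAB subject of a cohort against the class set of
    their own genotype."""
    config = config or QuantConfig()
    controls = [
        (s.record, s.image) for s in cohort.subjects if s.record.group == "control"
    ]
    class_sets = build_affinity_class_sets(controls, cohort.label_map, config)
    out = {}
    for s in cohort.subjects:
        if s.record.excluded:
            continue
        if s.record.genotype not in class_sets:
            continue
        pmap, n_ref = quantify_subject(
            s.image, cohort.label_map, class_sets[s.record.genotype], config
        )
        out[s.record.id] = SubjectQuantification(s.record, pmap, n_ref)
    return out


def regional_mean_bp(pmap: ParametricMap, label_map: LabelMap) -> dict[str, float]:
    """Mean fitted BP_ND per labelled region."""
    return {
        name: float(np.nanmean(pmap.bp[label_map.mask(name)]))
        for name in label_map.names.values()
    }
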