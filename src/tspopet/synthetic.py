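"""Synthetic dynamic TSPO-PET cohorts with known kinetic ground truth.

The generator emulates the structure the downstream analysis assumes: a
control group plus anoxic and traumatic coma groups (defaults 24/6/11),
regionally heterogeneous binding potential (BP_ND) elevated in
mesocircuit/posteromedial regions for anoxic subjects and in medial
prefrontal cortex for traumatic subjects, HAB/MAB binder genotypes with
lower MAB binding, and CRS-R outcomes linked negatively to pallidal/putaminal
/PCC binding.

Voxel kinetics follow the simplified reference tissue model: every tissue
region's curve is generated by ``srtm_forward`` from a common one-tissue
reference curve driven by a Feng-type arterial input function; a blood-pool
region carries the (scaled) input function itself. All rate constants are
per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._numerics import FINE_DT_MIN, expconv, fine_grid, frame_average
from .core import TAC, DynamicImage, FrameSchedule, LabelMap, build_frame_schedule

# The 60-min acquisition protocol: 32 frames.
DEFAULT_FRAME_SPEC = [(6, 10), (8, 30), (5, 60), (5, 120), (8, 300)]

GROUPS = ("control", "anoxic", "traumatic")
GENOTYPES = ("HAB", "MAB", "LAB")
STATES = ("VS_UWS", "MCS", "EMCS", "deceased")
FAVOURABLE_STATES = frozenset({"MCS", "EMCS"})

#: Hypothesis VOIs (13) + precentral-gyrus control region, as sampled by the
#: VOI analysis.
HYPOTHESIS_VOIS = (
    "brainstem",
    "thalamus",
    "caudate",
    "globus_pallidus",
    "putamen",
    "corpus_callosum",
    "acc",
    "pcc",
    "mpfc",
    "precuneus",
    "superior_parietal",
    "cuneus",
    "hippocampus",
)
CONTROL_VOI = "precentral"
DEFAULT_VOI_LIST = HYPOTHESIS_VOIS + (CONTROL_VOI,)

#: Regions with elevated binding in anoxic subjects (voxel-wise findings the
#: cohort generator implants) and in traumatic subjects.
ANOXIC_REGIONS = ("thalamus", "globus_pallidus", "putamen", "pcc", "mpfc", "precuneus", "cuneus")
TRAUMATIC_REGIONS = ("mpfc",)
#: Regions whose (true) binding drives the simulated CRS-R outcome.
OUTCOME_REGIONS = ("globus_pallidus", "putamen", "pcc")


class OverlapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """SRTM/SRTM2 parameter set for one tissue compartment.

    R1 = K1/K1' (delivery relative to reference), k2 target efflux, k2a
    apparent efflux, k2p reference efflux (k2' = k2/R1), BP_ND = k2/k2a - 1.
    """

    r1: float
    k2a: float
    k2p: float

    def __post_init__(self):
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2a <= 0:
            raise ValueError("k2a must be positive")
        if self.k2p <= 0:
            raise ValueError("k2' must be positive")
        if self.bp < -1:
            raise ValueError("BP_ND must be >= -1")

    @property
    def k2(self) -> float:
        return self.r1 * self.k2p

    @property
    def bp(self) -> float:
        return self.k2 / self.k2a - 1.0

    @classmethod
    def from_bp(cls, r1: float, bp: float, k2p: float) -> "KineticParams":
        """Construct from (R1, BP_ND, k2'): k2a = R1*k2' / (1 + BP)."""
        return cls(r1=r1, k2a=r1 * k2p / (1.0 + bp), k2p=k2p)


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    group: str
    genotype: str
    crs_r: int
    state: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not 0 <= self.crs_r <= 23:
            raise ValueError("CRS-R must lie in [0, 23]")

    @property
    def outcome(self) -> str:
        return "favourable" if self.state in FAVOURABLE_STATES else "unfavourable"

    @property
    def excluded(self) -> bool:
        """Low-affinity binders are excluded from quantification."""
        return self.genotype == "LAB"


# ---------------------------------------------------------------------------
# Input function and forward models
# ---------------------------------------------------------------------------

#: Feng tri-exponential arterial input parameters (A1 in activity/min, A2/A3
#: in activity units, eigenvalues per minute). Classic values giving a sharp
#: peak near 0.24 min followed by bi-exponential washout.
FENG_DEFAULT = (851.1225, 21.8798, 20.8113, 4.133859, 0.1190996, 0.0104233)


def input_function(t: np.ndarray, params: tuple = FENG_DEFAULT) -> np.ndarray:
    """Feng-type tri-exponential arterial input curve.

    C_p(t) = (A1*t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t};
    zero at t = 0, single early peak, monotone decay afterwards.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    a1, a2, a3, l1, l2, l3 = params
    cp = (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)
    return np.maximum(cp, 0.0)


def reference_fine_curve(
    t: np.ndarray, k1: float = 0.1, k2p: float = 0.05, feng: tuple = FENG_DEFAULT
) -> np.ndarray:
    """One-tissue reference curve C_R(t) = K1 * [C_p (x) e^{-k2' t}](t) on a
    uniform fine grid (t in minutes)."""
    dt = t[1] - t[0]
    return k1 * expconv(input_function(t, feng), dt, k2p)


def simulate_reference_tac(
    schedule: FrameSchedule, k1: float = 0.1, k2p: float = 0.05, dt: float = FINE_DT_MIN
) -> TAC:
    """Frame-averaged reference-region TAC from the one-tissue model."""
    if k1 < 0 or k2p <= 0:
        raise ValueError("K1 must be >= 0 and k2' > 0")
    t = fine_grid(schedule, dt)
    return TAC(frame_average(reference_fine_curve(t, k1, k2p), t, schedule), schedule)


def srtm_forward(
    ref_fine: np.ndarray, t: np.ndarray, params: KineticParams, schedule: FrameSchedule
) -> TAC:
    """Frame-averaged target-tissue curve under the SRTM operational equation

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) [C_R (x) e^{-k2a t}](t).

    With R1 = 1 and BP = 0 the target reproduces the reference exactly.
    """
    dt = t[1] - t[0]
    ct = params.r1 * ref_fine + (params.k2 - params.r1 * params.k2a) * expconv(
        ref_fine, dt, params.k2a
    )
    return TAC(frame_average(ct, t, schedule), schedule)


# ---------------------------------------------------------------------------
# Phantom geometry and construction
# ---------------------------------------------------------------------------

#: Per-region default kinetics: (baseline BP_ND, R1). The cerebellar grey
#: matter is a true non-specific region (BP = 0, R1 = 1) so the SVCA-derived
#: pseudo-reference is valid by construction; white matter has slow, low
#: delivery kinetics; the blood pool carries the input function.
REGION_KINETICS: dict[str, tuple[float, float]] = {
    "brainstem": (0.30, 0.95),
    "thalamus": (1.00, 1.05),
    "caudate": (0.50, 1.00),
    "globus_pallidus": (0.60, 0.95),
    "putamen": (0.55, 1.05),
    "corpus_callosum": (0.35, 0.85),
    "acc": (0.45, 1.00),
    "pcc": (0.50, 1.10),
    "mpfc": (0.40, 1.00),
    "precuneus": (0.45, 0.95),
    "superior_parietal": (0.35, 1.05),
    "cuneus": (0.30, 1.00),
    "hippocampus": (0.50, 0.90),
    "precentral": (0.40, 1.00),
    "cerebellum_gm": (0.00, 1.00),
    "white_matter": (0.10, 0.60),
}

PHANTOM_REGIONS = tuple(REGION_KINETICS) + ("blood_pool",)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + kinetics of one phantom subject."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    region_masks: dict[str, np.ndarray]  # name -> boolean mask, non-overlapping
    params: dict[str, KineticParams]  # tissue regions only
    blood_scale: float = 1.0
    noise_scale: float = 0.0
    #: per-voxel multiplicative kinetic heterogeneity: each voxel's curve is
    #: scaled by exp(N(-sd^2/2, sd)) (mean 1), emulating smooth within-parcel
    #: variation in delivery/binding density. 0 = kinetically homogeneous
    #: regions.
    voxel_scale_sd: float = 0.0
    k1_ref: float = 0.1
    k2p: float = 0.05
    frame_spec: tuple = tuple(DEFAULT_FRAME_SPEC)

    def __post_init__(self):
        missing = set(PHANTOM_REGIONS) - set(self.region_masks)
        if missing:
            raise ValueError(f"phantom is missing regions: {sorted(missing)}")
        total = np.zeros(self.shape, dtype=int)
        for m in self.region_masks.values():
            total += np.asarray(m, dtype=bool).astype(int)
        if (total > 1).any():
            raise OverlapError("phantom regions overlap")


#: larger cuboids for non-elevated cortex and the cerebellar reference; the
#: regions with implanted anoxic effects stay ~10% of the brain, matching a
#: plausible elevated fraction
_BIG_CORTICAL = frozenset({"acc", "superior_parietal", "precentral"})


def _default_region_masks(shape=(36, 36, 16)) -> dict[str, np.ndarray]:
    """Disjoint cuboid regions on a 4x4 cell layout carved out of a white
    matter slab: 125-voxel grey regions, 392-voxel non-elevated cortical
    regions, a 512-voxel cerebellar grey region and a 50-voxel blood pool."""
    masks = {}
    wm = np.zeros(shape, dtype=bool)
    wm[3:33, 3:33, 3:13] = True
    cells = [(4 + 8 * i, 4 + 8 * j) for i in range(4) for j in range(4)]
    order = [n for n in PHANTOM_REGIONS if n != "white_matter"]
    for name, (x0, y0) in zip(order, cells):
        m = np.zeros(shape, dtype=bool)
        if name == "blood_pool":
            m[x0 : x0 + 5, y0 : y0 + 5, 7:9] = True  # 50 voxels
        elif name == "cerebellum_gm":
            m[x0 : x0 + 8, y0 : y0 + 8, 4:12] = True  # 512 voxels
        elif name in _BIG_CORTICAL:
            m[x0 : x0 + 7, y0 : y0 + 7, 4:12] = True  # 392 voxels
        else:
            m[x0 : x0 + 5, y0 : y0 + 5, 5:10] = True  # 125 voxels
        masks[name] = m
        wm &= ~m
    masks["white_matter"] = wm
    return masks


def default_phantom_spec(
    shape=(36, 36, 16),
    voxel_size_mm: float = 4.0,
    bp_overrides: dict[str, float] | None = None,
    r1_overrides: dict[str, float] | None = None,
    noise_scale: float = 0.0,
    voxel_scale_sd: float = 0.0,
    k2p: float = 0.05,
) -> PhantomSpec:
    """The default 36x36x16, 4-mm phantom with per-region default kinetics."""
    bp_overrides = bp_overrides or {}
    r1_overrides = r1_overrides or {}
    params = {}
    for name, (bp, r1) in REGION_KINETICS.items():
        params[name] = KineticParams.from_bp(
            r1=r1_overrides.get(name, r1), bp=bp_overrides.get(name, bp), k2p=k2p
        )
    return PhantomSpec(
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        region_masks=_default_region_masks(shape),
        params=params,
        noise_scale=noise_scale,
        voxel_scale_sd=voxel_scale_sd,
        k2p=k2p,
    )


def _phantom_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size_mm
    return aff


def build_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[DynamicImage, LabelMap, dict[str, KineticParams]]:
    """Render a phantom: each tissue region's noiseless voxel TACs equal the
    SRTM forward model of its parameters; the blood pool carries the scaled
    input function. Gaussian frame-dependent noise is added when
    ``spec.noise_scale > 0`` (seed-reproducible)."""
    schedule = build_frame_schedule(list(spec.frame_spec))
    t = fine_grid(schedule)
    ref_fine = reference_fine_curve(t, spec.k1_ref, spec.k2p)
    values = np.zeros(spec.shape + (schedule.n_frames,))
    labels = np.zeros(spec.shape, dtype=np.int32)
    names = {}
    for i, name in enumerate(PHANTOM_REGIONS, start=1):
        mask = spec.region_masks[name]
        if name == "blood_pool":
            curve = frame_average(spec.blood_scale * input_function(t), t, schedule)
        else:
            curve = srtm_forward(ref_fine, t, spec.params[name], schedule).values
        values[mask] = curve
        labels[mask] = i
        names[i] = name
    rng = np.random.default_rng(seed)
    if spec.voxel_scale_sd > 0:
        sd = spec.voxel_scale_sd
        mult = np.exp(rng.normal(-sd**2 / 2.0, sd, size=spec.shape))
        values = values * mult[..., None]
    image = DynamicImage(values, schedule, _phantom_affine(spec))
    label_map = LabelMap(labels, names, image.affine)
    if spec.noise_scale > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        image = add_noise(image, spec.noise_scale, noise_seed, brain_mask=labels != 0)
    return image, label_map, dict(spec.params)


def add_noise(
    image: DynamicImage,
    scale: float,
    seed: int | None,
    brain_mask: np.ndarray | None = None,
) -> DynamicImage:
    """Additive Gaussian noise with the standard dynamic-PET frame-variance
    proxy: per-frame SD = scale * sqrt(mean brain activity in frame /
    frame duration in minutes). ``scale=0`` is the identity."""
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    if scale == 0:
        return image
    rng = np.random.default_rng(seed)
    if brain_mask is None:
        brain_mask = np.ones(image.shape, dtype=bool)
    mean_act = image.values[brain_mask].mean(axis=0)
    sd = scale * np.sqrt(np.maximum(mean_act, 0.0) / (image.schedule.durations / 60.0))
    noise = rng.standard_normal(image.values.shape) * sd
    return DynamicImage(image.values + noise, image.schedule, image.affine)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Implanted group effects and outcome link of the simulated cohort."""

    anoxic_bp_increment: tuple[float, float] = (0.5, 1.0)
    traumatic_bp_increment: tuple[float, float] = (0.5, 1.0)
    #: multiplicative lognormal jitter (sigma) on every region BP per subject
    subject_bp_jitter_sd: float = 0.05
    #: additive Gaussian jitter on per-region R1, clipped to [0.8, 1.2]
    subject_r1_jitter_sd: float = 0.03
    #: MAB binding relative to HAB
    mab_bp_scale: float = 0.8
    lab_fraction: float = 0.0
    #: CRS-R ~ 23 * logistic(-(driver - centre)/width) + N(0, noise), rounded
    crsr_centre: float = 0.9
    crsr_width: float = 0.25
    crsr_noise_sd: float = 2.0

    @classmethod
    def null(cls) -> "EffectSpec":
        """No implanted group effects (groups exchangeable)."""
        return cls(anoxic_bp_increment=(0.0, 0.0), traumatic_bp_increment=(0.0, 0.0))


#: Default per-frame noise scale and within-region kinetic heterogeneity of
#: the full dynamic simulation: a high-count acquisition (late-frame voxel
#: coefficient of variation ~2.5%) with modest (3%) within-parcel variation
#: in delivery/binding density. See docs/methods.md for the rationale and
#: the sensitivity of the pseudo-reference extraction to these choices.
DEFAULT_NOISE_SCALE = 0.3
DEFAULT_VOXEL_SCALE_SD = 0.03


@dataclass(frozen=True)
class SubjectData:
    record: SubjectRecord
    image: DynamicImage
    true_params: dict[str, KineticParams]


@dataclass(frozen=True)
class Cohort:
    subjects: list[SubjectData]
    label_map: LabelMap

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for region, p in s.true_params.items():
                rows.append(
                    {"id": s.record.id, "region": region, "r1": p.r1,
                     "k2a": p.k2a, "bp": p.bp}
                )
        return pd.DataFrame(rows)

    def subjects_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"id": r.id, "group": r.group, "genotype": r.genotype,
                 "crs_r": r.crs_r, "state": r.state, "outcome": r.outcome}
                for r in self.records
            ]
        )


def _draw_subject(
    idx: int, group: str, effects: EffectSpec, rng: np.random.Generator, k2p: float
) -> tuple[SubjectRecord, dict[str, float], dict[str, float]]:
    """Draw one subject's record and per-region true (BP, R1)."""
    p_lab = effects.lab_fraction
    genotype = rng.choice(GENOTYPES, p=[(1 - p_lab) / 2, (1 - p_lab) / 2, p_lab])
    geno_scale = {"HAB": 1.0, "MAB": effects.mab_bp_scale, "LAB": 0.3}[genotype]

    bps, r1s = {}, {}
    for region, (bp0, r10) in REGION_KINETICS.items():
        bp = bp0
        if group == "anoxic" and region in ANOXIC_REGIONS:
            bp += rng.uniform(*effects.anoxic_bp_increment)
        elif group == "traumatic" and region in TRAUMATIC_REGIONS:
            bp += rng.uniform(*effects.traumatic_bp_increment)
        bp *= geno_scale
        if region != "cerebellum_gm":  # the reference region stays exact
            bp *= np.exp(rng.normal(0.0, effects.subject_bp_jitter_sd))
            r10 = float(np.clip(rng.normal(r10, effects.subject_r1_jitter_sd), 0.8, 1.2)) \
                if region != "white_matter" else r10
        bps[region], r1s[region] = float(bp), float(r10)

    if group == "control":
        crs_r, state = 23, "EMCS"
    else:
        driver = float(np.mean([bps[r] for r in OUTCOME_REGIONS]))
        crs_float = 23.0 / (1.0 + np.exp((driver - effects.crsr_centre) / effects.crsr_width))
        crs_r = int(np.clip(round(crs_float + rng.normal(0, effects.crsr_noise_sd)), 0, 23))
        if crs_r < 8:
            state = "deceased" if rng.random() < 0.3 else "VS_UWS"
        elif crs_r < 16:
            state = "MCS"
        else:
            state = "EMCS"
    record = SubjectRecord(
        id=f"{group[:3]}{idx:03d}", group=group, genotype=str(genotype),
        crs_r=crs_r, state=state,
    )
    return record, bps, r1s


def _subject_param_sets(
    n_controls: int, n_anoxic: int, n_traumatic: int, effects: EffectSpec,
    rng: np.random.Generator, k2p: float,
):
    out = []
    idx = 0
    for group, n in zip(GROUPS, (n_controls, n_anoxic, n_traumatic)):
        for _ in range(n):
            out.append(_draw_subject(idx, group, effects, rng, k2p))
            idx += 1
    return out


def simulate_cohort(
    n_controls: int = 24,
    n_anoxic: int = 6,
    n_traumatic: int = 11,
    effect_spec: EffectSpec | None = None,
    seed: int | None = None,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    voxel_scale_sd: float = DEFAULT_VOXEL_SCALE_SD,
    shape=(36, 36, 16),
    k2p: float = 0.05,
) -> Cohort:
    """Simulate a full dynamic-PET cohort (default: the 24/6/11 study
    composition). Pure function of its arguments and the seed."""
    if min(n_controls, n_anoxic, n_traumatic) < 0:
        raise ValueError("group sizes must be >= 0")
    effects = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    drawn = _subject_param_sets(n_controls, n_anoxic, n_traumatic, effects, rng, k2p)
    subjects = []
    label_map = None
    for record, bps, r1s in drawn:
        spec = default_phantom_spec(
            shape=shape, bp_overrides=bps, r1_overrides=r1s,
            noise_scale=noise_scale, voxel_scale_sd=voxel_scale_sd, k2p=k2p,
        )
        noise_seed = int(rng.integers(0, 2**31 - 1))
        image, label_map, params = build_phantom(spec, seed=noise_seed)
        subjects.append(SubjectData(record, image, params))
    if label_map is None:
        _, label_map, _ = build_phantom(default_phantom_spec(shape=shape, k2p=k2p))
    return Cohort(subjects, label_map)


# ---------------------------------------------------------------------------
# BP-map level cohort (for replicate-heavy statistical suites)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BpCohort:
    records: list[SubjectRecord]
    bp_maps: list[np.ndarray]  # one 3D BP map per subject
    label_map: LabelMap
    true_bp: list[dict[str, float]]  # per subject, region -> true BP


def simulate_bp_cohort(
    n_controls: int = 24,
    n_anoxic: int = 6,
    n_traumatic: int = 11,
    effect_spec: EffectSpec | None = None,
    seed: int | None = None,
    bp_noise_sd: float = 0.2,
    shape=(36, 36, 16),
) -> BpCohort:
    """Simulate subjects at the binding-potential-map level: each subject's
    BP map is their true regional BP plus i.i.d. voxel noise emulating
    kinetic-fit error. Shares the group/genotype/outcome machinery of
    ``simulate_cohort`` and is the workhorse for replicate-heavy statistical
    calibration (null FDR, detection power), where rendering and fitting full
    4D images per replicate would be prohibitive.
    """
    effects = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    drawn = _subject_param_sets(n_controls, n_anoxic, n_traumatic, effects, rng, 0.05)
    masks = _default_region_masks(shape)
    labels = np.zeros(shape, dtype=np.int32)
    names = {}
    for i, name in enumerate(PHANTOM_REGIONS, start=1):
        labels[masks[name]] = i
        names[i] = name
    label_map = LabelMap(labels, names)
    brain = labels != 0
    records, bp_maps, true_bp = [], [], []
    for record, bps, _r1s in drawn:
        m = np.zeros(shape)
        for name in REGION_KINETICS:
            m[masks[name]] = bps[name]
        m[masks["blood_pool"]] = 0.0
        m[brain] += rng.normal(0.0, bp_noise_sd, size=int(brain.sum()))
        records.append(record)
        bp_maps.append(m)
        true_bp.append(bps)
    return BpCohort(records, bp_maps, label_map, true_bp)
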