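"""Synthetic stroke-brain phantom with known ground truth.

Generates everything the downstream stages consume — T1w/T2w anatomy, a
GM/WM/CSF segmentation, a left-hemisphere lesion with a graded damage
profile, an interleaved control/label pCASL series with an M0 calibration
volume, and a per-frame rigid-motion trace — on a common grid whose world
``x = 0`` plane is the midsagittal plane.

Design of the anatomy
---------------------
The brain is an ellipsoid; grey matter is its outer shell, white matter the
interior, and CSF fills two paramedian lateral-ventricle ellipsoids.  The
lesion is a sphere confined to the left hemisphere with damage rising
linearly from 0.1 at the rim to 1.0 at the core.  Inside the lesion the
T2w/T1w ratio interpolates linearly between the intact-GM ratio and the CSF
ratio as damage goes 0.1 -> 1.0, so the ratio-based damage score is exactly
invertible in the noiseless case.  Lesion CBF declines linearly with damage
(an optional step increase at damage 0.6 emulates a grey-matter transition
mid-scale).

The ASL difference signal is built by inverting the single-compartment
quantification model voxel by voxel (including the slice-dependent
post-labeling delay), so with zero noise the perfusion stage recovers the
true CBF to numerical precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Mask, Volume
from .perfusion import (
    AcquisitionParams,
    MotionTrace,
    PerfusionSeries,
    QuantificationConstants,
    deltam_per_unit_cbf,
)

TISSUE_LABELS = {"background": 0, "GM": 1, "WM": 2, "CSF": 3}


class PhantomSpecError(ValueError):
    """The phantom specification is geometrically or physically invalid."""


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    Intensities are in arbitrary scanner units; CBF in mL/100g/min; all
    geometry in world mm.  The defaults give a 64^3 grid at 2 mm isotropic
    (a desk-scale stand-in for 1 mm acquisitions) with 40 control/label
    pairs, tissue CBF GM 60 / WM 20 / CSF 0, and a lesion whose CBF falls
    from 40 at the least-damaged rim by 20 mL/100g/min per unit damage.
    """

    shape: tuple = (64, 64, 64)
    spacing: tuple = (2.0, 2.0, 2.0)

    # per-tissue image intensities (T2w/T1w ratios: GM 0.8, WM 0.6, CSF 3.0)
    t1w_intensity: dict = field(
        default_factory=lambda: {"GM": 900.0, "WM": 1100.0, "CSF": 400.0, "background": 40.0}
    )
    t2w_intensity: dict = field(
        default_factory=lambda: {"GM": 720.0, "WM": 660.0, "CSF": 1200.0, "background": 40.0}
    )
    proton_density: dict = field(
        default_factory=lambda: {"GM": 850.0, "WM": 700.0, "CSF": 1000.0, "background": 100.0}
    )
    true_cbf: dict = field(
        default_factory=lambda: {"GM": 60.0, "WM": 20.0, "CSF": 0.0, "background": 0.0}
    )

    # anatomy geometry
    brain_semiaxes: tuple = (50.0, 56.0, 46.0)
    gm_shell_fraction: float = 0.85
    ventricle_offset_x: float = 14.0
    ventricle_center_y: float = 6.0
    ventricle_semiaxes: tuple = (7.0, 26.0, 9.0)

    # lesion model
    lesion_center: tuple = (-32.0, 8.0, 2.0)
    lesion_radius: float = 24.0
    damage_rim: float = 0.1
    cavity_fraction: float = 0.5
    lesion_cbf_rim: float = 40.0
    lesion_cbf_slope: float = 20.0
    gm_jump: float = 0.0

    # noise (additive Gaussian SD per image type)
    noise_sd_asl: float = 5.0
    noise_sd_anat: float = 8.0
    noise_sd_m0: float = 0.0

    # acquisition
    n_pairs: int = 40
    control_first: bool = True
    params: AcquisitionParams = field(default_factory=AcquisitionParams)
    constants: QuantificationConstants = field(default_factory=QuantificationConstants)

    # motion model: smooth random walk plus injected large excursions
    walk_sd_translation: float = 0.03
    walk_sd_rotation: float = 0.15
    n_excursion_frames: int = 4
    excursion_frames: tuple | None = None
    excursion_translation: float = 1.2
    excursion_rotation: float = 6.0

    # demographics
    age: float = 55.0
    sex: str = "M"
    months_since_stroke: float = 48.0
    wab_aq: float = 65.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise PhantomSpecError("at least one control/label pair is required")
        if any(v < 0 for k, v in self.true_cbf.items()):
            raise PhantomSpecError("tissue CBF values must be >= 0")
        if abs(self.true_cbf.get("CSF", 0.0)) > 1e-12:
            raise PhantomSpecError("CSF CBF must be 0")
        cx = self.lesion_center[0]
        if cx == 0:
            raise PhantomSpecError("lesion centre must be off the midline")
        if abs(cx) < self.lesion_radius:
            raise PhantomSpecError(
                f"lesion of radius {self.lesion_radius} mm at x={cx} mm crosses "
                "the midline; it must fit in one hemisphere"
            )
        if not (0 < self.damage_rim < 1):
            raise PhantomSpecError("damage at the rim must be in (0, 1)")
        if not (0 <= self.cavity_fraction < 1):
            raise PhantomSpecError("cavity_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Voxelwise truth for parameter-recovery checks.

    tissue_labels: 0 background, 1 GM, 2 WM, 3 CSF (partition of the grid);
    damage: continuous true damage, nonzero only inside the lesion;
    cbf: true perfusion map; corrupted_frames: frames carrying injected
    motion excursions.
    """

    tissue_labels: np.ndarray
    damage: Volume
    cbf: Volume
    corrupted_frames: tuple


@dataclass
class Phantom:
    """One synthetic subject: images, masks, series, trace, truth, manifest."""

    spec: PhantomSpec
    t1w: Volume
    t2w: Volume
    tissues: dict
    brain: Mask
    lesion: Mask
    series: PerfusionSeries
    trace: MotionTrace
    truth: GroundTruth
    manifest: dict


def _ellipsoid_norm(x, y, z, center, semiaxes):
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)


def _centered_affine(shape, spacing) -> np.ndarray:
    """Diagonal affine placing the grid centre at world (0,0,0).

    Voxel centres fall at half-integer multiples of the spacing for
    even-sized axes, so no voxel centre lies exactly on the midline plane.
    """
    affine = np.eye(4)
    for i in range(3):
        affine[i, i] = spacing[i]
        affine[i, 3] = -(shape[i] - 1) / 2.0 * spacing[i]
    return affine


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate one synthetic subject; deterministic given ``spec.seed``."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    affine = _centered_affine(spec.shape, spec.spacing)
    ref = Volume(np.zeros(spec.shape), affine)
    x, y, z = ref.world_grids()

    # --- anatomy ---------------------------------------------------------
    en = _ellipsoid_norm(x, y, z, (0.0, 0.0, 0.0), spec.brain_semiaxes)
    brain = en <= 1.0
    gm = brain & (en > spec.gm_shell_fraction)
    vent_l = _ellipsoid_norm(
        x, y, z, (-spec.ventricle_offset_x, spec.ventricle_center_y, 0.0), spec.ventricle_semiaxes
    )
    vent_r = _ellipsoid_norm(
        x, y, z, (spec.ventricle_offset_x, spec.ventricle_center_y, 0.0), spec.ventricle_semiaxes
    )
    csf = brain & ~gm & ((vent_l <= 1.0) | (vent_r <= 1.0))
    wm = brain & ~gm & ~csf

    labels = np.zeros(spec.shape, dtype=np.int8)
    labels[gm] = TISSUE_LABELS["GM"]
    labels[wm] = TISSUE_LABELS["WM"]
    labels[csf] = TISSUE_LABELS["CSF"]

    # --- lesion and graded damage ---------------------------------------
    r = np.sqrt(
        (x - spec.lesion_center[0]) ** 2
        + (y - spec.lesion_center[1]) ** 2
        + (z - spec.lesion_center[2]) ** 2
    )
    side = x < 0 if spec.lesion_center[0] < 0 else x > 0
    lesion = (r <= spec.lesion_radius) & brain & side
    if not lesion.any():
        raise PhantomSpecError("lesion mask is empty; move it inside the brain")
    # damage saturates at 1.0 inside the necrotic core (r <= cavity_fraction*R)
    # and ramps linearly down to the rim value at the lesion edge
    damage = np.zeros(spec.shape)
    rim = spec.damage_rim
    ramp = np.clip(
        (1.0 - r[lesion] / spec.lesion_radius) / max(1.0 - spec.cavity_fraction, 1e-9),
        0.0,
        1.0,
    )
    damage[lesion] = rim + (1.0 - rim) * ramp

    # --- intensity images ------------------------------------------------
    def fill(table: dict) -> np.ndarray:
        out = np.full(spec.shape, table["background"], dtype=float)
        for name in ("GM", "WM", "CSF"):
            out[labels == TISSUE_LABELS[name]] = table[name]
        return out

    t1w = fill(spec.t1w_intensity)
    t2w = fill(spec.t2w_intensity)
    gm_ratio = spec.t2w_intensity["GM"] / spec.t1w_intensity["GM"]
    csf_ratio = spec.t2w_intensity["CSF"] / spec.t1w_intensity["CSF"]
    # inside the lesion the T2w/T1w ratio tracks damage linearly from the
    # GM ratio (damage = rim) to the CSF ratio (damage = 1)
    ratio_lesion = gm_ratio + (csf_ratio - gm_ratio) * (damage[lesion] - rim) / (1.0 - rim)
    t1w[lesion] = spec.t1w_intensity["GM"]
    t2w[lesion] = ratio_lesion * spec.t1w_intensity["GM"]
    if spec.noise_sd_anat > 0:
        t1w = t1w + rng.normal(0.0, spec.noise_sd_anat, spec.shape)
        t2w = t2w + rng.normal(0.0, spec.noise_sd_anat, spec.shape)

    # --- true CBF --------------------------------------------------------
    cbf = fill(spec.true_cbf)
    lesion_cbf = spec.lesion_cbf_rim - spec.lesion_cbf_slope * (damage[lesion] - rim)
    if spec.gm_jump:
        lesion_cbf = lesion_cbf + spec.gm_jump * (damage[lesion] >= 0.6)
    cbf[lesion] = np.clip(lesion_cbf, 0.0, None)

    # --- pCASL series ----------------------------------------------------
    pd_map = fill(spec.proton_density)
    deltam = cbf * deltam_per_unit_cbf(pd_map, spec.params, spec.constants)
    n_frames = 2 * spec.n_pairs
    frames = np.empty(spec.shape + (n_frames,), dtype=float)
    roles = []
    for f in range(n_frames):
        is_control = (f % 2 == 0) == spec.control_first
        base = pd_map if is_control else pd_map - deltam
        noise = rng.normal(0.0, spec.noise_sd_asl, spec.shape) if spec.noise_sd_asl > 0 else 0.0
        frames[..., f] = base + noise
        roles.append("control" if is_control else "label")

    m0_data = pd_map.copy()
    if spec.noise_sd_m0 > 0:
        m0_data = m0_data + rng.normal(0.0, spec.noise_sd_m0, spec.shape)
    m0 = Volume(m0_data, affine)
    series = PerfusionSeries(frames, affine, tuple(roles), m0, spec.params)

    # --- motion trace ----------------------------------------------------
    # mean-reverting (AR(1)) wobble: realistic sub-threshold head motion that
    # does not drift unboundedly over the run
    def ar1_walk(sd: float) -> np.ndarray:
        steps = rng.normal(0.0, sd, (n_frames, 3))
        out = np.zeros((n_frames, 3))
        for f in range(1, n_frames):
            out[f] = 0.9 * out[f - 1] + steps[f]
        return out

    trans = ar1_walk(spec.walk_sd_translation)
    rot = ar1_walk(spec.walk_sd_rotation)
    if spec.excursion_frames is not None:
        exc = tuple(int(f) for f in spec.excursion_frames)
    elif spec.n_excursion_frames > 0:
        # frame 0 is the motion reference, so never corrupt it
        exc = tuple(
            int(f)
            for f in sorted(
                rng.choice(np.arange(1, n_frames), spec.n_excursion_frames, replace=False)
            )
        )
    else:
        exc = ()
    for k, f in enumerate(exc):
        if f >= n_frames:
            raise PhantomSpecError(f"excursion frame {f} outside the series")
        if k % 2 == 0:
            trans[f] = (spec.excursion_translation, 0.0, 0.0)
        else:
            rot[f] = (0.0, spec.excursion_rotation, 0.0)
    trace = MotionTrace(trans, rot)

    masks = {
        "GM": Mask(gm, affine, "GM"),
        "WM": Mask(wm, affine, "WM"),
        "CSF": Mask(csf, affine, "CSF"),
    }
    brain_mask = Mask(brain, affine, "brain")
    lesion_mask = Mask(lesion, affine, "lesion")
    truth = GroundTruth(
        tissue_labels=labels,
        damage=Volume(damage, affine),
        cbf=Volume(cbf, affine),
        corrupted_frames=exc,
    )

    voxvol = ref.voxel_volume
    manifest = {
        "seed": spec.seed,
        "shape": list(spec.shape),
        "spacing_mm": list(spec.spacing),
        "lesion_center_mm": list(spec.lesion_center),
        "lesion_radius_mm": spec.lesion_radius,
        "lesion_volume_mm3": lesion_mask.n_voxels * voxvol,
        "lesion_volume_ml": lesion_mask.n_voxels * voxvol / 1000.0,
        "lesion_cbf_rim": spec.lesion_cbf_rim,
        "lesion_cbf_slope": spec.lesion_cbf_slope,
        "gm_jump": spec.gm_jump,
        "true_cbf": dict(spec.true_cbf),
        "noise_sd_asl": spec.noise_sd_asl,
        "noise_sd_anat": spec.noise_sd_anat,
        "n_pairs": spec.n_pairs,
        "corrupted_frames": list(exc),
        "age": spec.age,
        "sex": spec.sex,
        "months_since_stroke": spec.months_since_stroke,
        "wab_aq": spec.wab_aq,
    }

    return Phantom(
        spec=spec,
        t1w=Volume(t1w, affine),
        t2w=Volume(t2w, affine),
        tissues=masks,
        brain=brain_mask,
        lesion=lesion_mask,
        series=series,
        trace=trace,
        truth=truth,
        manifest=manifest,
    )


#: per-parameter (low, high) ranges emulating a heterogeneous chronic-stroke
#: cohort: lesion location/size vary across the left MCA territory, ages span
#: 24-81 years, time since stroke 9-121 months, WAB-AQ 27.4-80.6.
DEFAULT_COHORT_VARIATION: dict = {
    "lesion_center_x": (-38.0, -28.0),
    "lesion_center_y": (-12.0, 22.0),
    "lesion_center_z": (-8.0, 10.0),
    "lesion_radius": (18.0, 26.0),
    "lesion_cbf_rim": (32.0, 46.0),
    "lesion_cbf_slope": (20.0, 20.0),
    "age": (24.0, 81.0),
    "months_since_stroke": (9.0, 121.0),
    "wab_aq": (27.4, 80.6),
}


@dataclass
class Cohort:
    """A generated multi-subject dataset plus its demographics table."""

    subjects: list
    demographics: pd.DataFrame
    manifest: dict


def make_cohort(
    n_subjects: int = 14,
    base_spec: PhantomSpec | None = None,
    variation: dict | None = None,
    effects: dict | None = None,
    female_fraction: float = 4.0 / 14.0,
    seed: int = 0,
) -> Cohort:
    """Generate ``n_subjects`` phantoms with varied lesions and demographics.

    ``variation`` maps parameter names to (low, high) uniform ranges
    (defaults: :data:`DEFAULT_COHORT_VARIATION`).  ``effects`` optionally
    injects demographic effects on the lesion's rim CBF, as additive
    mL/100g/min per unit of the centred covariate:
    ``{"age": b_age, "months_since_stroke": b_t, "sex": b_sex}`` (sex effect
    is +b for F, -b for M).  Sex counts are fixed (at least two per level)
    and positions shuffled, so factorial models are always estimable.
    """
    if n_subjects < 2:
        raise PhantomSpecError("a cohort needs at least 2 subjects")
    base = base_spec or PhantomSpec()
    var = dict(DEFAULT_COHORT_VARIATION)
    if variation:
        var.update(variation)
    effects = effects or {}
    degenerate = all(lo == hi for lo, hi in var.values())

    rng = np.random.default_rng(seed)
    n_f = min(max(2, round(female_fraction * n_subjects)), n_subjects - 2)
    sexes = np.array(["F"] * n_f + ["M"] * (n_subjects - n_f))
    rng.shuffle(sexes)

    def draw(name):
        lo, hi = var[name]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    subjects, rows, per_subject = [], [], []
    for i in range(n_subjects):
        age = draw("age")
        months = draw("months_since_stroke")
        sex = str(sexes[i])
        rim = draw("lesion_cbf_rim")
        rim += effects.get("age", 0.0) * (age - np.mean(var["age"]))
        rim += effects.get("months_since_stroke", 0.0) * (
            months - np.mean(var["months_since_stroke"])
        )
        rim += effects.get("sex", 0.0) * (1.0 if sex == "F" else -1.0)
        spec = dataclasses.replace(
            base,
            lesion_center=(
                draw("lesion_center_x"),
                draw("lesion_center_y"),
                draw("lesion_center_z"),
            ),
            lesion_radius=draw("lesion_radius"),
            lesion_cbf_rim=max(rim, 5.0),
            lesion_cbf_slope=draw("lesion_cbf_slope"),
            age=age,
            sex=sex,
            months_since_stroke=months,
            wab_aq=draw("wab_aq"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ph = make_phantom(spec)
        subjects.append(ph)
        rows.append(
            {
                "subject": f"P{i + 1:02d}",
                "age": age,
                "sex": sex,
                "months_since_stroke": months,
                "wab_aq": spec.wab_aq,
                "lesion_volume_mm3": ph.manifest["lesion_volume_mm3"],
            }
        )
        per_subject.append(ph.manifest)

    manifest = {
        "n_subjects": n_subjects,
        "seed": seed,
        "variation": {k: list(v) for k, v in var.items()},
        "effects": dict(effects),
        "degenerate_variation": degenerate,
        "subjects": per_subject,
    }
    return Cohort(subjects=subjects, demographics=pd.DataFrame(rows), manifest=manifest)
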