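"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without any
acquisition:

* **Midbrain phantoms** — a brain-shaped ellipsoid filled with a
  white-matter enhancement tier, a CSF compartment, and bilateral
  ellipsoidal VTA and SN nuclei inside a midbrain ellipsoid, with the
  SN tier above the VTA tier (the ordering observed in vivo). The MT
  volume is a constant baseline times the tier map plus Gaussian noise,
  and the non-MT volume is the clean baseline, so the enhancement ratio
  recovers the planted tiers exactly in the noiseless case and the
  enhancement-domain noise SD equals ``noise_sd`` exactly otherwise.

* **Cohorts** — two groups (healthy control HC, mood/anxiety MA) with
  configurable standardized group effects on normalized VTA volume and
  intensity and on reward sensitivity (sigma), a planted correlation
  between VTA intensity and external-condition bias (bivariate normal),
  and symptom scales. Marginal means/SDs follow the published subject
  characteristics table; effect magnitudes default to the detectable
  end of the reported directions (volume +0.8 SD in MA, intensity
  -0.8 SD, sigma -3.2 SD, intensity-bias r = +0.4).

* **Trial sets** — factorial effort x reward designs over the printed
  task ranges (3-70 presses, $0.25-$2.00), with Bernoulli external
  responses from the acceptance sigmoid, truncated-logistic internal
  effort choices, and a work-required flag on a random 30% of trials.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice import TaskDesign, accept_probability, znormalize
from .choice import EFFORT_MIN, EFFORT_MAX, REWARD_MIN, REWARD_MAX, _logistic_cdf
from .errors import GeometryError, ParameterError
from .volume import Mask, VolumeGrid

__all__ = [
    "Ellipsoid",
    "BilateralNuclei",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "CohortSpec",
    "SubjectTruth",
    "make_cohort",
    "cohort_table",
    "make_trials",
]


# --------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def mask(self, shape) -> np.ndarray:
        cx, cy, cz = self.center
        a, b, c = self.semi_axes
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


@dataclass(frozen=True)
class BilateralNuclei:
    """A mirror-symmetric pair of nucleus ellipsoids.

    ``lateral_offset_vox`` is the distance of each center from the
    midline sagittal plane (axis 0); ``center_yz_vox`` the shared
    (y, z) center; semi-axes in voxels.
    """

    lateral_offset_vox: float
    center_yz_vox: tuple[float, float]
    semi_axes_vox: tuple[float, float, float]

    def pair(self, midline_x: float) -> tuple[Ellipsoid, Ellipsoid]:
        y, z = self.center_yz_vox
        left = Ellipsoid((midline_x - self.lateral_offset_vox, y, z), self.semi_axes_vox)
        right = Ellipsoid((midline_x + self.lateral_offset_vox, y, z), self.semi_axes_vox)
        return left, right


_DEFAULT_TIERS = {"csf": 0.85, "wm": 0.95, "vta": 1.08, "sn": 1.12}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity tiers and noise level of a midbrain phantom.

    Defaults: 64x64x48 grid at 0.4 mm isotropic (the acquisition's
    voxel scale), tier means csf 0.85 < wm 0.95 < vta 1.08 < sn 1.12,
    noise_sd 0.01 in enhancement units.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    tier_means: dict = field(default_factory=lambda: dict(_DEFAULT_TIERS))
    noise_sd: float = 0.01
    baseline: float = 1000.0
    vta_geometry: BilateralNuclei = BilateralNuclei(4.0, (27.5, 23.5), (3.0, 4.0, 3.0))
    sn_geometry: BilateralNuclei = BilateralNuclei(10.5, (31.5, 23.5), (3.5, 5.0, 3.0))
    brain_semi_axes: tuple[float, float, float] = (28.0, 28.0, 21.0)
    midbrain: Ellipsoid | None = None
    csf_region: Ellipsoid | None = None
    seed: int = 0

    def validate(self) -> None:
        t = self.tier_means
        if not (t["sn"] > t["vta"] > t["wm"] > t["csf"] > 0):
            raise ParameterError("tier means must satisfy sn > vta > wm > csf > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for g in (self.vta_geometry, self.sn_geometry):
            if min(g.semi_axes_vox) < 1:
                raise ParameterError("nucleus semi-axes must be >= 1 voxel")

    @property
    def midline_x(self) -> float:
        return (self.grid_shape[0] - 1) / 2.0

    @property
    def grid_center(self) -> tuple[float, float, float]:
        return tuple((s - 1) / 2.0 for s in self.grid_shape)

    def resolved_midbrain(self) -> Ellipsoid:
        if self.midbrain is not None:
            return self.midbrain
        cx, cy, cz = self.grid_center
        return Ellipsoid((cx, cy, cz), (14.0, 12.0, 10.0))

    def resolved_csf(self) -> Ellipsoid:
        if self.csf_region is not None:
            return self.csf_region
        cx, cy, cz = self.grid_center
        return Ellipsoid((cx, cy + 15.5, cz), (8.0, 6.0, 12.0))


@dataclass
class GroundTruth:
    """Planted masks, tier map, and exact nucleus volumes."""

    masks: dict
    true_tier_map: VolumeGrid
    true_vta_volume_mm3: float
    true_sn_volume_mm3: float


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid, GroundTruth]:
    """Build paired MT / non-MT volumes and their ground truth.

    The non-MT volume is the constant baseline; the MT volume is
    baseline x tier map plus Gaussian noise of SD
    ``noise_sd x baseline``, so MT / non-MT = tier + N(0, noise_sd).
    Nuclei extending outside the midbrain, or overlapping each other,
    raise :class:`~vtamap.errors.GeometryError`.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size_mm
    mid = spec.midline_x

    cx, cy, cz = spec.grid_center
    brain = Ellipsoid((cx, cy, cz), spec.brain_semi_axes).mask(shape)
    midbrain = spec.resolved_midbrain().mask(shape) & brain
    csf = spec.resolved_csf().mask(shape) & brain & ~midbrain

    def nucleus(geom: BilateralNuclei) -> np.ndarray:
        l, r = geom.pair(mid)
        return l.mask(shape) | r.mask(shape)

    vta = nucleus(spec.vta_geometry)
    sn = nucleus(spec.sn_geometry)
    if (vta & ~midbrain).any() or (sn & ~midbrain).any():
        raise GeometryError("nucleus geometry extends outside the midbrain mask")
    if (vta & sn).any():
        raise GeometryError("VTA and SN geometries overlap")

    t = spec.tier_means
    tier = np.zeros(shape, dtype=np.float64)
    tier[brain] = t["wm"]
    tier[csf] = t["csf"]
    tier[vta] = t["vta"]
    tier[sn] = t["sn"]

    rng = np.random.default_rng(spec.seed)
    non_mt_arr = np.full(shape, spec.baseline, dtype=np.float64)
    mt_arr = spec.baseline * tier
    if spec.noise_sd > 0:
        mt_arr = mt_arr + rng.normal(0.0, spec.noise_sd * spec.baseline, size=shape)

    voxvol = float(np.prod(vs))
    truth = GroundTruth(
        masks={
            "vta": Mask(vta, vs, id="vta_true"),
            "sn": Mask(sn, vs, id="sn_true"),
            "midbrain": Mask(midbrain, vs, id="midbrain"),
            "brain": Mask(brain, vs, id="brain"),
        },
        true_tier_map=VolumeGrid(tier, vs, id="tier_map"),
        true_vta_volume_mm3=float(vta.sum()) * voxvol,
        true_sn_volume_mm3=float(sn.sum()) * voxvol,
    )
    return (
        VolumeGrid(mt_arr, vs, id="mt"),
        VolumeGrid(non_mt_arr, vs, id="non_mt"),
        truth,
    )


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted standardized effects.

    Signed effects are (MA - HC) / SD. Defaults plant the reported
    directions at magnitudes that a cohort of this size can detect:
    larger normalized VTA volume, lower normalized VTA intensity and
    much lower reward sensitivity (sigma) in the MA group, with VTA
    intensity positively correlated with external bias. Setting every
    effect (and ``symptom_effect_scale``) to 0 gives the null
    generator used for type-I-error calibration.
    """

    n_hc: int = 22
    n_ma: int = 21
    effect_volume_d: float = 0.8
    effect_intensity_d: float = -0.8
    effect_sigma_d: float = -3.2
    effect_sn_d: float = 0.0
    r_intensity_bias: float = 0.4
    symptom_effect_scale: float = 1.0
    seed: int = 0

    # marginal anchors (HC mean, common SD)
    intensity_mean: float = 1.08
    intensity_sd: float = 0.010
    volume_mean_mm3: float = 19.2
    volume_sd_mm3: float = 2.5
    sn_intensity_mean: float = 1.12
    sn_intensity_sd: float = 0.010
    bias_external_mean: float = 0.034
    bias_external_sd: float = 0.57
    bias_internal_mean: float = 0.545
    bias_internal_sd: float = 0.46
    sigma_external_mean: float = 0.450
    sigma_external_sd: float = 0.09
    sigma_internal_mean: float = 0.491
    sigma_internal_sd: float = 0.10
    brain_volume_mean_mm3: float = 1_260_000.0
    brain_volume_sd_mm3: float = 100_000.0
    sigma_floor: float = 0.01

    def validate(self) -> None:
        if not abs(self.r_intensity_bias) < 1:
            raise ParameterError("|r_intensity_bias| must be < 1")
        if self.n_hc < 2 or self.n_ma < 2:
            raise ParameterError("each group needs n >= 2")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "CohortSpec":
        """All planted effects zero: the calibration generator."""
        return cls(
            effect_volume_d=0.0,
            effect_intensity_d=0.0,
            effect_sigma_d=0.0,
            effect_sn_d=0.0,
            r_intensity_bias=0.0,
            symptom_effect_scale=0.0,
            seed=seed,
            **kwargs,
        )


# Symptom marginals (HC mean, HC sd, MA mean, MA sd) from the published
# subject characteristics; MA-HC differences scale with symptom_effect_scale.
_SYMPTOM_MARGINALS = {
    "anhedonia_anticipatory": (46.86, 8.22, 40.25, 6.62),
    "anhedonia_consummatory": (37.86, 6.73, 36.63, 9.25),
    "anxiety_total": (22.91, 2.37, 38.57, 10.06),
    "depression": (1.47, 1.32, 11.13, 4.67),
}


@dataclass
class SubjectTruth:
    """Planted per-subject ground truth."""

    subject_id: str
    group: str
    sex: str
    true_bias_internal: float
    true_bias_external: float
    true_sigma_internal: float
    true_sigma_external: float
    true_vta_intensity: float
    true_vta_volume: float
    true_sn_intensity: float
    true_brain_volume_mm3: float
    symptoms: dict = field(default_factory=dict)


def make_cohort(spec: CohortSpec) -> list[SubjectTruth]:
    """Draw a cohort of :class:`SubjectTruth` records.

    VTA intensity and external bias are drawn from a bivariate normal
    with correlation ``r_intensity_bias`` (Gaussian marginals +
    Gaussian copula); all other covariates are independent Gaussians.
    Group effects shift the MA means by effect_d x SD. Sigmas are
    clipped at ``sigma_floor`` to keep them strictly positive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectTruth] = []
    r = spec.r_intensity_bias
    counter = 0
    for group, n in (("HC", spec.n_hc), ("MA", spec.n_ma)):
        shift = 1.0 if group == "MA" else 0.0
        for _ in range(n):
            counter += 1
            z_int = rng.standard_normal()
            z_bias = r * z_int + np.sqrt(1 - r * r) * rng.standard_normal()
            intensity = (
                spec.intensity_mean
                + shift * spec.effect_intensity_d * spec.intensity_sd
                + spec.intensity_sd * z_int
            )
            bias_ext = spec.bias_external_mean + spec.bias_external_sd * z_bias
            volume = (
                spec.volume_mean_mm3
                + shift * spec.effect_volume_d * spec.volume_sd_mm3
                + spec.volume_sd_mm3 * rng.standard_normal()
            )
            sn_int = (
                spec.sn_intensity_mean
                + shift * spec.effect_sn_d * spec.sn_intensity_sd
                + spec.sn_intensity_sd * rng.standard_normal()
            )
            sig_ext = (
                spec.sigma_external_mean
                + shift * spec.effect_sigma_d * spec.sigma_external_sd
                + spec.sigma_external_sd * rng.standard_normal()
            )
            sig_int = (
                spec.sigma_internal_mean
                + shift * spec.effect_sigma_d * spec.sigma_internal_sd
                + spec.sigma_internal_sd * rng.standard_normal()
            )
            symptoms = {}
            for name, (m_hc, sd_hc, m_ma, sd_ma) in _SYMPTOM_MARGINALS.items():
                m = m_hc + shift * spec.symptom_effect_scale * (m_ma - m_hc)
                sd = sd_hc + shift * spec.symptom_effect_scale * (sd_ma - sd_hc)
                symptoms[name] = float(m + sd * rng.standard_normal())
            subjects.append(
                SubjectTruth(
                    subject_id=f"sub-{counter:03d}",
                    group=group,
                    sex="F" if rng.random() < 0.5 else "M",
                    true_bias_internal=float(
                        spec.bias_internal_mean + spec.bias_internal_sd * rng.standard_normal()
                    ),
                    true_bias_external=float(bias_ext),
                    true_sigma_internal=float(max(sig_int, spec.sigma_floor)),
                    true_sigma_external=float(max(sig_ext, spec.sigma_floor)),
                    true_vta_intensity=float(intensity),
                    true_vta_volume=float(max(volume, 1.0)),
                    true_sn_intensity=float(sn_int),
                    true_brain_volume_mm3=float(
                        max(spec.brain_volume_mean_mm3 + spec.brain_volume_sd_mm3 * rng.standard_normal(), 1e5)
                    ),
                    symptoms=symptoms,
                )
            )
    return subjects


def cohort_table(subjects: list[SubjectTruth]) -> pd.DataFrame:
    """Analysis-ready cohort table from planted truths.

    Planted intensity/volume are defined on the brain-normalized scale,
    so they populate the ``*_norm`` columns directly; behavioral
    parameters are z-scored across the cohort within parameter.
    """
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "vta_volume_norm": s.true_vta_volume,
                "vta_intensity_norm": s.true_vta_intensity,
                "sn_intensity": s.true_sn_intensity,
                "bias_external": s.true_bias_external,
                "bias_internal": s.true_bias_internal,
                "sigma_external": s.true_sigma_external,
                "sigma_internal": s.true_sigma_internal,
                "brain_volume_mm3": s.true_brain_volume_mm3,
                **s.symptoms,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("bias_external", "bias_internal", "sigma_external", "sigma_internal"):
        df[col + "_z"] = znormalize(df[col].to_numpy())
    return df


# --------------------------------------------------------------------------
# trials


def make_trials(subject: SubjectTruth, design: TaskDesign, seed: int) -> pd.DataFrame:
    """Simulate one subject's trial set over the factorial design.

    External condition: accept/reject Bernoulli draws from the
    acceptance sigmoid at the subject's true (bias, sigma). Internal
    condition: self-generated effort levels drawn from the truncated
    logistic choice density (inverse-CDF sampling), mapped back to
    button presses. A random 30% of trials (per ``design.work_fraction``)
    carry the work-required flag.
    """
    if subject.true_sigma_external <= 0 or subject.true_sigma_internal <= 0:
        raise ParameterError("subject sigmas must be strictly positive")
    rng = np.random.default_rng(seed)
    e, r = design.grid()
    frames = []
    if "external" in design.conditions:
        p = accept_probability(e, r, subject.true_bias_external, subject.true_sigma_external)
        resp = (rng.random(e.size) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject.subject_id,
                    "condition": "external",
                    "effort_presses": e.astype(int),
                    "reward_usd": r,
                    "response": resp.astype(float),
                }
            )
        )
    if "internal" in design.conditions:
        m = (
            (np.asarray(r) - REWARD_MIN) / (REWARD_MAX - REWARD_MIN)
            - subject.true_bias_internal
        )
        s = subject.true_sigma_internal
        lo = _logistic_cdf((0.0 - m) / s)
        hi = _logistic_cdf((1.0 - m) / s)
        u = lo + (hi - lo) * rng.random(r.size)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        e_norm = m + s * np.log(u / (1 - u))
        e_norm = np.clip(e_norm, 0.0, 1.0)
        chosen = EFFORT_MIN + e_norm * (EFFORT_MAX - EFFORT_MIN)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject.subject_id,
                    "condition": "internal",
                    "effort_presses": e.astype(int),
                    "reward_usd": r,
                    "response": chosen,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    trials["work_required"] = rng.random(len(trials)) < design.work_fraction
    return trials
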