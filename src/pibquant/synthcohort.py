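"""Ground-truth cohort generation and multicentre phantom rendering.

This module fabricates the study material everything downstream consumes:

* a cohort of subjects (controls / MCI / AD) with per-subject *true* regional
  retention ratios drawn from calibrated two-component Gaussian mixtures,
  ApoE genotype, cognition scores coupled linearly to amyloid burden,
  follow-up and conversion outcomes for MCI;
* phantom PET frame series rendered from the truth in template space with
  centre-specific dose scaling, Gaussian point-spread blur,
  signal-proportional noise and axial field-of-view truncation;
* per-subject grey-matter probability maps.

The mixture, cognition and survival calibration constants are the module's
defaults and define the simulated study conditions; they are derived from the
published group summaries (e.g. AD composite 1.85 ± 0.32 with 90 % positive).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .templates import (
    Atlas,
    CEREBELLUM,
    CORTICAL_INFERIOR,
    CORTICAL_MIDDLE,
    CORTICAL_SUPERIOR,
    ROI_NAMES,
    WHITE_MATTER,
)

DIAGNOSES = ("control", "mci", "ad")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class InfeasibleMomentsError(ValueError):
    """Requested mixture moments imply a non-positive component variance."""


def moment_match_mixture(total_mean: float, total_sd: float, weight_pos: float,
                         neg_mean: float, neg_sd: float) -> tuple[float, float]:
    """Solve for the positive component of a two-component normal mixture.

    Given the target total mean/SD, the positive-component weight and the
    negative component's moments, return ``(pos_mean, pos_sd)`` such that the
    mixture reproduces the totals exactly (law of total mean and variance).
    """
    if not 0 < weight_pos <= 1:
        raise ValueError("weight_pos must be in (0, 1]")
    if weight_pos == 1.0:
        return float(total_mean), float(total_sd)
    w, q = weight_pos, 1.0 - weight_pos
    pos_mean = (total_mean - q * neg_mean) / w
    second = total_sd**2 + total_mean**2          # E[X^2]
    pos_second = (second - q * (neg_mean**2 + neg_sd**2)) / w
    pos_var = pos_second - pos_mean**2
    if pos_var <= 0:
        raise InfeasibleMomentsError(
            f"implied positive-component variance {pos_var:.6g} <= 0")
    return float(pos_mean), float(np.sqrt(pos_var))


@dataclass(frozen=True)
class MixtureParams:
    """Two-component retention-ratio mixture for one diagnostic group."""

    weight_pos: float
    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float

    def validate(self) -> None:
        if not 0 <= self.weight_pos <= 1:
            raise ValueError("weight_pos outside [0, 1]")
        if self.neg_sd < 0 or self.pos_sd < 0:
            raise ValueError("negative mixture SD")

    @property
    def mean(self) -> float:
        w = self.weight_pos
        return w * self.pos_mean + (1 - w) * self.neg_mean

    @property
    def var(self) -> float:
        w = self.weight_pos
        second = (w * (self.pos_mean**2 + self.pos_sd**2)
                  + (1 - w) * (self.neg_mean**2 + self.neg_sd**2))
        return second - self.mean**2

    def tail_above(self, cutoff: float) -> float:
        """Mixture probability of a draw strictly above ``cutoff``."""
        from scipy.stats import norm
        w = self.weight_pos
        return (w * norm.sf(cutoff, self.pos_mean, self.pos_sd)
                + (1 - w) * norm.sf(cutoff, self.neg_mean, self.neg_sd))


@dataclass(frozen=True)
class CentreProfile:
    """Acquisition characteristics of one PET centre."""

    name: str
    psf_fwhm: float                      # mm
    noise_sd_fraction: float             # fraction of local signal, per frame
    dose_scale: float                    # global multiplier
    frame_schedule: tuple[tuple[float, float], ...]   # (start, end) minutes
    fov_z_range: tuple[int, int] | None = None  # half-open voxel slab retained

    def validate(self) -> None:
        prev_end = -np.inf
        for start, end in self.frame_schedule:
            if end <= start:
                raise ValueError(f"{self.name}: empty frame ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.name}: overlapping/unordered frames")
            prev_end = end
        if self.noise_sd_fraction < 0 or self.dose_scale <= 0 or self.psf_fwhm < 0:
            raise ValueError(f"{self.name}: invalid noise/dose/psf")


def _frames(start: float, stop: float, width: float = 5.0):
    edges = np.arange(start, stop + 1e-9, width)
    return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))


def default_centre_profiles() -> tuple[CentreProfile, ...]:
    """Five-centre roster. Centre A acquires six 5-min frames 40-70 min;
    the others cover the common 40-60 min window with varying run-in.
    Dose scales follow the relative injected activities; PSF and noise are
    plausible reconstructed-resolution figures, not published values."""
    return (
        CentreProfile("A", psf_fwhm=5.0, noise_sd_fraction=0.06, dose_scale=1.00,
                      frame_schedule=_frames(40, 70)),
        CentreProfile("B", psf_fwhm=5.5, noise_sd_fraction=0.08, dose_scale=0.67,
                      frame_schedule=_frames(35, 65)),
        CentreProfile("C", psf_fwhm=6.0, noise_sd_fraction=0.07, dose_scale=1.07,
                      frame_schedule=_frames(40, 60)),
        CentreProfile("D", psf_fwhm=5.0, noise_sd_fraction=0.06, dose_scale=0.88,
                      frame_schedule=_frames(40, 60)),
        CentreProfile("E", psf_fwhm=6.5, noise_sd_fraction=0.09, dose_scale=1.33,
                      frame_schedule=_frames(40, 65)),
    )


# --- calibration constants (simulated study conditions) ---------------------

#: Published group totals the mixtures are moment-matched to.
GROUP_TOTALS = {"mci": (1.64, 0.35), "ad": (1.85, 0.32)}
CONTROL_CLUSTER = (1.26, 0.07)        # main-cluster normal component
CONTROL_OUTLIER = (1.674, 0.10)       # high component (5/51 of controls)
POSITIVITY = {"control": 5 / 51, "mci": 0.65, "ad": 0.90}
NEG_COMPONENT = {"control": CONTROL_CLUSTER, "mci": CONTROL_CLUSTER,
                 "ad": (1.30, 0.08)}

APOE_CARRIER_PROB = {"control": 10 / 31, "mci": 31 / 45, "ad": 48 / 85}
#: MCI ApoE e4 carriers draw from the positive component with this weight;
#: the non-carrier weight is solved so the marginal positivity is preserved.
APOE_MCI_CARRIER_WEIGHT = 0.80

AGE = {"control": (67.4, 6.3), "mci": (67.5, 8.1), "ad": (69.2, 8.4)}
MALE_PROB = {"control": 22 / 51, "mci": 37 / 72, "ad": 47 / 97}

#: Default per-centre allocation (counts) for group sizes (51, 72, 97).
CENTRE_ALLOCATION = {
    "control": {"B": 15, "C": 14, "D": 6, "E": 16},
    "mci": {"A": 14, "C": 10, "D": 19, "E": 29},
    "ad": {"A": 19, "B": 14, "C": 10, "D": 34, "E": 20},
}

HIPPOCAMPUS_DIST = (1.26, 0.07)   # low, control-like in all groups
WHITE_MATTER_RATIO = 1.8          # nonspecific binding look-alike
SUBCORTICAL_GAIN = 0.7            # caudate/putamen/thalamus vs composite


@dataclass(frozen=True)
class CognitionTest:
    """Linear coupling of one cognition score to the true composite.

    score = target_mean + slope * (composite - group mixture mean) + noise,
    with the noise SD chosen so the group SD matches ``target_sd``.
    """

    slope: dict[str, float]
    target_mean: dict[str, float]
    target_sd: dict[str, float]
    missing_prob: dict[str, float]
    clip: tuple[float, float] | None = None
    integer: bool = False


def default_cognition_model() -> dict[str, CognitionTest]:
    g = DIAGNOSES
    return {
        "mmse": CognitionTest(
            slope=dict(zip(g, (-1.0, -1.0, -1.0))),
            target_mean=dict(zip(g, (29.2, 27.1, 24.0))),
            target_sd=dict(zip(g, (1.1, 2.0, 3.2))),
            missing_prob=dict(zip(g, (1 - 43 / 51, 0.0, 0.0))),
            clip=(0, 30), integer=True),
        "verbal_immediate_z": CognitionTest(
            slope=dict(zip(g, (-1.5, -1.5, -1.5))),
            target_mean=dict(zip(g, (0.6, -1.0, -1.9))),
            target_sd=dict(zip(g, (1.0, 1.7, 1.4))),
            missing_prob=dict(zip(g, (1 - 36 / 51, 1 - 64 / 72, 1 - 90 / 97)))),
        "verbal_delayed_z": CognitionTest(
            slope=dict(zip(g, (-0.5, -2.34, -0.82))),
            target_mean=dict(zip(g, (0.9, -1.2, -2.2))),
            target_sd=dict(zip(g, (0.8, 1.5, 1.2))),
            missing_prob=dict(zip(g, (1 - 38 / 51, 1 - 64 / 72, 1 - 90 / 97)))),
        "nonverbal_delayed_z": CognitionTest(
            slope=dict(zip(g, (-1.5, -1.5, -1.5))),
            target_mean=dict(zip(g, (0.7, -0.8, -1.7))),
            target_sd=dict(zip(g, (1.2, 1.3, 1.0))),
            missing_prob=dict(zip(g, (1 - 28 / 51, 1 - 60 / 72, 1 - 71 / 97)))),
    }


@dataclass(frozen=True)
class FollowupModel:
    mean_months: float = 28.0
    sd_months: float = 15.0
    clip_months: tuple[float, float] = (6.0, 60.0)
    availability_prob: float = 64 / 72   # fraction of MCI with follow-up


@dataclass
class GeneratorConfig:
    """Everything the cohort/phantom generator needs; seed fixes all draws."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 51, "mci": 72, "ad": 97})
    centre_profiles: tuple[CentreProfile, ...] = field(
        default_factory=default_centre_profiles)
    mixture_params: dict[str, MixtureParams] = field(default_factory=dict)
    apoe_carrier_prob: dict[str, float] = field(
        default_factory=lambda: dict(APOE_CARRIER_PROB))
    apoe_mci_carrier_weight: float = APOE_MCI_CARRIER_WEIGHT
    cognition_model: dict[str, CognitionTest] = field(
        default_factory=default_cognition_model)
    followup_model: FollowupModel = field(default_factory=FollowupModel)
    #: monthly conversion hazard for PIB-positive (truth) MCI
    conversion_rate: float = 0.0445
    #: ground-truth positivity threshold gating conversion eligibility
    truth_cutoff: float = 1.41
    centre_allocation: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(a) for g, a in CENTRE_ALLOCATION.items()})
    seed: int = 0

    def __post_init__(self):
        if not self.mixture_params:
            self.mixture_params = default_mixtures()
        self.validate()

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g} must be > 0")
        for mix in self.mixture_params.values():
            mix.validate()
        for p in list(self.apoe_carrier_prob.values()) + [
                self.apoe_mci_carrier_weight,
                self.followup_model.availability_prob]:
            if not 0 <= p <= 1:
                raise ValueError("probability outside [0, 1]")
        for profile in self.centre_profiles:
            profile.validate()
        if self.conversion_rate < 0:
            raise ValueError("conversion_rate must be >= 0")

    def centre(self, name: str) -> CentreProfile:
        for p in self.centre_profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def default_mixtures() -> dict[str, MixtureParams]:
    """Group mixtures: MCI/AD positive components are moment-matched so the
    mixture reproduces the published group totals; the control mixture is the
    main cluster plus the small high-retention component directly."""
    out = {"control": MixtureParams(POSITIVITY["control"],
                                    *CONTROL_CLUSTER, *CONTROL_OUTLIER)}
    for g in ("mci", "ad"):
        neg = NEG_COMPONENT[g]
        pos = moment_match_mixture(*GROUP_TOTALS[g], POSITIVITY[g], *neg)
        out[g] = MixtureParams(POSITIVITY[g], *neg, *pos)
    return out


def solve_noncarrier_weight(marginal: float, carrier_prob: float,
                            carrier_weight: float) -> float:
    """Positive-component weight for non-carriers preserving the marginal."""
    if carrier_prob >= 1.0:
        return carrier_weight
    w = (marginal - carrier_prob * carrier_weight) / (1.0 - carrier_prob)
    if not 0 <= w <= 1:
        raise ValueError("carrier weight incompatible with marginal positivity")
    return w


@dataclass
class SubjectTruth:
    subject_id: str
    diagnosis: str
    centre: str
    age: float
    sex: str
    apoe_e4: bool | None          # None = genotype unavailable
    true_composite: float
    true_regional: dict[str, float]
    mmse: float | None
    verbal_immediate_z: float | None
    verbal_delayed_z: float | None
    nonverbal_delayed_z: float | None
    followup_months: float | None
    converted: bool | None
    conversion_month: float | None


def _allocate_centres(n: int, allocation: dict[str, int]) -> list[str]:
    """Deterministic proportional allocation of n subjects to centres."""
    names = sorted(allocation)
    weights = np.array([allocation[c] for c in names], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n).astype(int)
    # distribute remainder by largest fractional part, ties by name order
    frac = weights * n - counts
    for i in np.argsort(-frac, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for c, k in zip(names, counts):
        out.extend([c] * int(k))
    return out


def _cognition_coefficients(test: CognitionTest, mix: MixtureParams,
                            group: str) -> tuple[float, float, float]:
    """(intercept-at-group-mixture-mean, slope, residual SD)."""
    slope = test.slope[group]
    resid_var = test.target_sd[group] ** 2 - slope**2 * mix.var
    if resid_var < 0:
        raise ValueError(
            f"cognition slope {slope} too steep for target SD in {group}")
    return test.target_mean[group], slope, float(np.sqrt(resid_var))


def sample_cohort(config: GeneratorConfig) -> list[SubjectTruth]:
    """Draw the full ground-truth cohort. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    subjects: list[SubjectTruth] = []
    cortical = CORTICAL_MIDDLE + CORTICAL_SUPERIOR + CORTICAL_INFERIOR

    for group in DIAGNOSES:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        mix = config.mixture_params[group]
        centres = _allocate_centres(n, config.centre_allocation[group])
        carrier_p = config.apoe_carrier_prob[group]
        if group == "mci":
            w_carrier = config.apoe_mci_carrier_weight
            w_noncarrier = solve_noncarrier_weight(
                mix.weight_pos, carrier_p, w_carrier)
        age_mean, age_sd = AGE[group]
        cog_coef = {name: _cognition_coefficients(t, mix, group)
                    for name, t in config.cognition_model.items()}

        for i in range(n):
            apoe = bool(rng.random() < carrier_p)
            if group == "mci":
                w_pos = w_carrier if apoe else w_noncarrier
            else:
                w_pos = mix.weight_pos
            if rng.random() < w_pos:
                composite = rng.normal(mix.pos_mean, mix.pos_sd)
            else:
                composite = rng.normal(mix.neg_mean, mix.neg_sd)
            composite = float(max(composite, 1.0))

            regional = {r: composite for r in cortical}
            for r in ("caudate", "putamen", "thalamus"):
                regional[r] = 1.0 + SUBCORTICAL_GAIN * (composite - 1.0)
            regional["hippocampus"] = float(
                max(rng.normal(*HIPPOCAMPUS_DIST), 1.0))
            regional[CEREBELLUM] = 1.0
            regional[WHITE_MATTER] = WHITE_MATTER_RATIO

            scores: dict[str, float | None] = {}
            for name, test in config.cognition_model.items():
                mean, slope, resid_sd = cog_coef[name]
                val = mean + slope * (composite - mix.mean) + rng.normal(0, resid_sd)
                missing = rng.random() < test.missing_prob[group]
                if test.clip is not None:
                    val = float(np.clip(val, *test.clip))
                if test.integer:
                    val = float(round(val))
                scores[name] = None if missing else float(val)

            followup = converted = conv_month = None
            if group == "mci":
                followed = rng.random() < config.followup_model.availability_prob
                fm = config.followup_model
                months = float(np.clip(rng.normal(fm.mean_months, fm.sd_months),
                                       *fm.clip_months))
                if composite > config.truth_cutoff and config.conversion_rate > 0:
                    latent = float(rng.exponential(1.0 / config.conversion_rate))
                else:
                    latent = np.inf
                if followed:
                    followup = months
                    converted = latent <= months
                    conv_month = latent if converted else None

            subjects.append(SubjectTruth(
                subject_id=f"{group}-{i + 1:03d}",
                diagnosis=group,
                centre=centres[i],
                age=float(np.clip(rng.normal(age_mean, age_sd), 50, 90)),
                sex="M" if rng.random() < MALE_PROB[group] else "F",
                apoe_e4=None if centres[i] == "C" else apoe,
                true_composite=composite,
                true_regional=regional,
                mmse=scores["mmse"],
                verbal_immediate_z=scores["verbal_immediate_z"],
                verbal_delayed_z=scores["verbal_delayed_z"],
                nonverbal_delayed_z=scores["nonverbal_delayed_z"],
                followup_months=followup,
                converted=converted,
                conversion_month=conv_month,
            ))
    return subjects


def cohort_to_frame(subjects: list[SubjectTruth]):
    """Flatten the cohort into a pandas DataFrame (one row per subject)."""
    import pandas as pd
    rows = []
    for s in subjects:
        row = {k: v for k, v in dataclasses.asdict(s).items()
               if k != "true_regional"}
        for region, value in s.true_regional.items():
            row[f"true_{region}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


# --- phantom rendering ------------------------------------------------------


@dataclass
class FrameSeries:
    """A timed stack of 3-D PET frames on the template grid."""

    data: np.ndarray                               # (n_frames, nx, ny, nz)
    schedule: tuple[tuple[float, float], ...]      # minutes
    voxel_mm: float
    fov_z_range: tuple[int, int] | None = None     # half-open slab retained

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_mm] * 3 + [1.0])


def truth_value_map(subject: SubjectTruth, atlas: Atlas) -> np.ndarray:
    """Paint the subject's true ratios into the atlas labels (background 0)."""
    lut = np.zeros(max(atlas.label_names) + 1)
    for label, name in atlas.label_names.items():
        try:
            lut[label] = subject.true_regional[name]
        except KeyError:
            raise ValueError(f"no true ratio assigned for atlas label {name!r}")
    return lut[atlas.labels]


def render_phantom(subject: SubjectTruth, centre: CentreProfile, atlas: Atlas,
                   rng: np.random.Generator | None = None) -> FrameSeries:
    """Render one subject's frame series for one centre.

    Voxel signal = dose_scale x true ratio of the enclosing label, blurred by
    the centre's Gaussian PSF; each frame adds independent zero-mean Gaussian
    noise with SD = noise_sd_fraction x local (blurred) signal; axial slices
    outside the FOV slab are zeroed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    signal = centre.dose_scale * truth_value_map(subject, atlas)
    if centre.psf_fwhm > 0:
        sigma = centre.psf_fwhm * FWHM_TO_SIGMA / atlas.voxel_mm
        # zero padding: outside the head there is no activity
        signal = ndimage.gaussian_filter(signal, sigma, mode="constant")
    n_frames = len(centre.frame_schedule)
    frames = np.empty((n_frames,) + signal.shape)
    noise_sd = centre.noise_sd_fraction * signal
    for i in range(n_frames):
        frames[i] = signal
        if centre.noise_sd_fraction > 0:
            frames[i] = frames[i] + rng.standard_normal(signal.shape) * noise_sd
    if centre.fov_z_range is not None:
        z0, z1 = centre.fov_z_range
        frames[..., :z0] = 0.0
        frames[..., z1:] = 0.0
    return FrameSeries(data=frames, schedule=tuple(centre.frame_schedule),
                       voxel_mm=atlas.voxel_mm, fov_z_range=centre.fov_z_range)


def render_gm_probability_maps(n: int, atlas: Atlas,
                               seed: int | np.random.Generator = 0,
                               amplitude: float = 0.05,
                               smooth_vox: float = 1.5) -> list[np.ndarray]:
    """Per-subject grey-matter probability maps: 0.9 inside GM labels, 0.1
    outside, plus a smooth subject-specific perturbation field, clipped to
    [0, 1]. Deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    base = np.where(atlas.gm_indicator, 0.9, 0.1)
    maps = []
    for _ in range(n):
        if amplitude > 0:
            noise = ndimage.gaussian_filter(
                rng.standard_normal(atlas.shape), smooth_vox)
            noise *= amplitude / noise.std()
        else:
            noise = 0.0
        maps.append(np.clip(base + noise, 0.0, 1.0))
    return maps


# --- IO ---------------------------------------------------------------------


def write_frame_series(series: FrameSeries, path: str | Path) -> None:
    """4-D NIfTI plus a JSON frame-timing sidecar next to it."""
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(series.data, 0, -1), series.affine)
    nib.save(img, path)
    sidecar = {"frame_schedule_min": [list(f) for f in series.schedule],
               "fov_z_range": list(series.fov_z_range)
               if series.fov_z_range else None}
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1))


def read_frame_series(path: str | Path) -> FrameSeries:
    path = Path(path)
    img = nib.load(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    fov = sidecar["fov_z_range"]
    return FrameSeries(
        data=np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0),
        schedule=tuple(tuple(f) for f in sidecar["frame_schedule_min"]),
        voxel_mm=float(img.header.get_zooms()[0]),
        fov_z_range=tuple(fov) if fov else None)


def write_cohort_csv(subjects: list[SubjectTruth], path: str | Path) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False, float_format="%.6f")


# --- YAML config ------------------------------------------------------------


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["centre_profiles"] = [dataclasses.asdict(p) for p in config.centre_profiles]
    d["mixture_params"] = {g: dataclasses.asdict(m)
                           for g, m in config.mixture_params.items()}
    d["cognition_model"] = {k: dataclasses.asdict(t)
                            for k, t in config.cognition_model.items()}
    d["followup_model"] = dataclasses.asdict(config.followup_model)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "centre_profiles" in d:
        d["centre_profiles"] = tuple(
            CentreProfile(**{**p, "frame_schedule": tuple(
                tuple(f) for f in p["frame_schedule"]),
                "fov_z_range": tuple(p["fov_z_range"])
                if p.get("fov_z_range") else None})
            for p in d["centre_profiles"])
    if "mixture_params" in d:
        d["mixture_params"] = {g: MixtureParams(**m)
                               for g, m in d["mixture_params"].items()}
    if "cognition_model" in d:
        d["cognition_model"] = {
            k: CognitionTest(**{**t, "clip": tuple(t["clip"])
                                if t.get("clip") else None})
            for k, t in d["cognition_model"].items()}
    if "followup_model" in d:
        fm = dict(d["followup_model"])
        fm["clip_months"] = tuple(fm["clip_months"])
        d["followup_model"] = FollowupModel(**fm)
    return GeneratorConfig(**d)


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
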