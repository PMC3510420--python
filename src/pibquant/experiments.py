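"""Seeded calibration-recovery experiments.

These drive the package end-to-end under its default study conditions and
measure how well known generator inputs are recovered: the normative cutoff
from simulated control arms, group composite means and positivity rates
recovered through phantom rendering + quantification, and the Kaplan-Meier
median under a known exponential conversion hazard. They are used both by the
test suite and by the reproduction script.

Imaging experiments run on a reduced 32x32x24 grid at 6 mm — the same
normalized geometry as the default template at desk-scale cost.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np

from .maskbuild import RoiSet, build_roi_set
from .normcut import derive_threshold
from .quantify import quantify_subject
from .survival import km_estimate
from .synthcohort import (
    CONTROL_CLUSTER,
    CONTROL_OUTLIER,
    GeneratorConfig,
    MixtureParams,
    render_gm_probability_maps,
    render_phantom,
    sample_cohort,
)
from .templates import Atlas, build_atlas

REDUCED_SHAPE = (32, 32, 24)
REDUCED_VOXEL_MM = 6.0

#: Fixed seed for the population-level mask construction (the masks model a
#: one-off anatomical template, not a per-experiment random quantity).
_MASK_SEED = 20120908


@lru_cache(maxsize=4)
def reduced_grid() -> tuple[Atlas, RoiSet]:
    """Atlas + eroded ROI set on the reduced grid (built once, reused)."""
    atlas = build_atlas(REDUCED_SHAPE, REDUCED_VOXEL_MM)
    maps = render_gm_probability_maps(10, atlas, seed=_MASK_SEED)
    return atlas, build_roi_set(maps, atlas)


def simulate_arm_composites(diagnosis: str, n_subjects: int,
                            seed: int | np.random.SeedSequence,
                            main_cluster_only: bool = False) -> np.ndarray:
    """Render one diagnostic arm end-to-end and return measured composites.

    Subjects are drawn from the default mixture for ``diagnosis`` (negative
    component only when ``main_cluster_only``), allocated to the default
    centre roster, rendered with centre-specific PSF/noise/dose on the
    reduced grid, and quantified with the standard mask pipeline.
    """
    atlas, rois = reduced_grid()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    cfg = GeneratorConfig(group_sizes={diagnosis: n_subjects},
                          seed=int(ss.generate_state(1)[0] % 2**31))
    if main_cluster_only:
        mix = cfg.mixture_params[diagnosis]
        cfg.mixture_params[diagnosis] = dataclasses.replace(mix, weight_pos=0.0)
    subjects = sample_cohort(cfg)
    out = np.empty(len(subjects))
    children = ss.spawn(len(subjects))
    for i, (subject, child) in enumerate(zip(subjects, children)):
        centre = cfg.centre(subject.centre)
        frames = render_phantom(subject, centre, atlas,
                                rng=np.random.default_rng(child))
        rr = quantify_subject(subject.subject_id, subject.centre, frames, rois)
        out[i] = rr.composite
    return out


def recovery_mc(seed: int, n_seeds: int = 200,
                arms: dict[str, tuple[int, bool]] | None = None
                ) -> dict[str, np.ndarray]:
    """Per-seed mean composites and positivity rates for each arm.

    ``arms`` maps an arm name to (diagnosis, n, main_cluster_only); defaults
    to the study's 46 main-cluster controls, 72 MCI and 97 AD. Returns, for
    each arm, arrays of per-seed mean recovered composite and per-seed
    percent classified positive at the 1.41 cutoff.
    """
    if arms is None:
        arms = {"control_cluster": ("control", 46, True),
                "mci": ("mci", 72, False),
                "ad": ("ad", 97, False)}
    out: dict[str, np.ndarray] = {}
    for a, (name, (diagnosis, n, cluster_only)) in enumerate(arms.items()):
        means = np.empty(n_seeds)
        pos_pct = np.empty(n_seeds)
        for r in range(n_seeds):
            comps = simulate_arm_composites(
                diagnosis, n,
                np.random.SeedSequence(seed, spawn_key=(a, r)),
                main_cluster_only=cluster_only)
            means[r] = comps.mean()
            pos_pct[r] = 100.0 * np.mean(comps > 1.41)
        out[f"{name}_mean"] = means
        out[f"{name}_pos_pct"] = pos_pct
    return out


def cutoff_recovery_mc(seed: int, n_reps: int = 1000,
                       n_cluster: int = 46, n_contaminants: int = 5
                       ) -> np.ndarray:
    """Monte-Carlo cutoffs from simulated control arms.

    Each replicate draws ``n_cluster`` values from the default main-cluster
    normal and ``n_contaminants`` from the high component truncated above
    1.5, then runs main-cluster trimming + mean + 1.96 SD.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu, sd = CONTROL_CLUSTER
    omu, osd = CONTROL_OUTLIER
    cutoffs = np.empty(n_reps)
    for i in range(n_reps):
        cluster = rng.normal(mu, sd, n_cluster)
        contaminants = []
        while len(contaminants) < n_contaminants:
            v = rng.normal(omu, osd)
            if v > 1.5:
                contaminants.append(v)
        cutoffs[i] = derive_threshold(
            np.concatenate([cluster, contaminants])).cutoff
    return cutoffs


def km_median_mc(seed: int, n_reps: int = 500, n_subjects: int = 43,
                 monthly_rate: float = np.log(2) / 24.0,
                 censor_mean: float = 28.0, censor_sd: float = 15.0,
                 censor_clip: tuple[float, float] = (6.0, 60.0)
                 ) -> np.ndarray:
    """KM median (months) over seeded replicates of an exponential-conversion
    arm under the study's censoring distribution. Replicates where the KM
    curve never reaches 0.5 give NaN."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    medians = np.empty(n_reps)
    for i in range(n_reps):
        event_t = rng.exponential(1.0 / monthly_rate, n_subjects)
        censor_t = np.clip(rng.normal(censor_mean, censor_sd, n_subjects),
                           *censor_clip)
        observed = np.minimum(event_t, censor_t)
        converted = event_t <= censor_t
        medians[i] = km_estimate(observed, converted).median
    return medians
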