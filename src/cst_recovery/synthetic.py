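"""Synthetic template-space volumes, lesions and patient cohorts.

Real lesion masks and Fugl-Meyer (FMA) records from stroke cohorts are
IRB-restricted, so this module generates stand-ins with the statistical
structure the downstream analysis assumes:

* a bilateral corticospinal-tract (CST) "atlas" as two disjoint tubes, one
  per hemisphere, in a small template grid;
* unilateral lesions built as unions of tract-voxel selections targeting an
  exact injury score on the 1/16 grid (plus an off-tract blob for volume
  variability) — block-built rather than morphologically realistic, so the
  intended score is provable;
* patient cohorts with three latent recovery groups (mild/ceiling,
  severe-recoverer, severe-non-recoverer), a strong initial-to-follow-up FMA
  correlation, CST-injury signal confined to the severe groups, and null
  demographic covariates.

FMA scores are truncated, rounded Gaussians conditioned on the latent
group.  Within the severe groups the follow-up score follows a linear model
whose *standardized* slopes on initial FMA and CST injury equal the requested
``initial_effect`` and ``injury_effect``, so parameter-recovery tests have
an exact target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple

import numpy as np
import pandas as pd

from .tract_injury import cst_injury, partition_tract
from .volume import LATERAL_AXIS, LONGITUDINAL_AXIS, VolumeMask

__all__ = [
    "TemplateSpace",
    "SyntheticAtlasSpec",
    "CohortSpec",
    "SyntheticCohort",
    "make_atlas",
    "make_lesion",
    "make_cohort",
]

GROUP_NAMES = ("mild_ceiling", "severe_recoverer", "severe_nonrecoverer")


# ---------------------------------------------------------------------------
# template space and atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSpace:
    """A small stand-in for a standard template grid.

    Axis 0 is lateral (index < ``midline_index`` = left hemisphere, the
    half-open convention assigns the midline plane to the right), axis 2 is
    longitudinal (increasing = superior).
    """

    shape: tuple[int, int, int] = (32, 32, 40)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    midline_index: int = 16

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValueError(f"invalid shape {self.shape}")
        if self.shape[LONGITUDINAL_AXIS] < 16:
            raise ValueError("longitudinal extent must be >= 16 slices to allow 16 subsections")
        if not 0 < self.midline_index < self.shape[LATERAL_AXIS]:
            raise ValueError("midline_index must be strictly inside the volume")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Tube-shaped tract per hemisphere.

    ``centerline_left`` gives the in-plane (lateral, anterior-posterior)
    voxel coordinates of the left tract for each longitudinal slice in
    ``z_range`` (half-open).  The right centerline defaults to the left one
    mirrored across the midline.  ``radius_mm = 0`` degenerates to a single
    voxel per slice.
    """

    centerline_left: np.ndarray  # (n_slices, 2) float voxel coords
    z_range: tuple[int, int]
    radius_mm: float = 3.0
    centerline_right: np.ndarray | None = None

    @classmethod
    def default(cls, space: TemplateSpace, radius_mm: float = 3.0) -> "SyntheticAtlasSpec":
        """A gently curving tract spanning most of the longitudinal extent."""
        nz = space.shape[LONGITUDINAL_AXIS]
        z_range = (2, nz - 2)
        zs = np.arange(*z_range)
        x = space.midline_index / 2 + 1.5 * np.sin(np.linspace(0, np.pi, len(zs)))
        y = space.shape[1] / 2 + 2.0 * np.cos(np.linspace(0, np.pi / 2, len(zs)))
        return cls(
            centerline_left=np.column_stack([x, y]),
            z_range=z_range,
            radius_mm=radius_mm,
        )

    def mirrored_right(self, space: TemplateSpace) -> np.ndarray:
        if self.centerline_right is not None:
            return np.asarray(self.centerline_right, dtype=float)
        right = np.asarray(self.centerline_left, dtype=float).copy()
        # half-open reflection: voxel i <-> 2*midline - 1 - i
        right[:, 0] = 2 * space.midline_index - 1 - right[:, 0]
        return right


def _tube_mask(
    space: TemplateSpace,
    centerline: np.ndarray,
    z_range: tuple[int, int],
    radius_mm: float,
) -> np.ndarray:
    nx, ny, _ = space.shape
    vx, vy, _ = space.voxel_size
    data = np.zeros(space.shape, dtype=bool)
    xs = np.arange(nx)[:, None]
    ys = np.arange(ny)[None, :]
    for i, z in enumerate(range(*z_range)):
        cx, cy = centerline[i]
        if radius_mm == 0:
            data[int(round(cx)), int(round(cy)), z] = True
        else:
            d2 = ((xs - cx) * vx) ** 2 + ((ys - cy) * vy) ** 2
            data[:, :, z] = d2 <= radius_mm**2 + 1e-9
    return data


def make_atlas(
    space: TemplateSpace, spec: SyntheticAtlasSpec | None = None
) -> tuple[VolumeMask, VolumeMask]:
    """Build the bilateral tract atlas: (left mask, right mask).

    The two hemispheric masks are disjoint and each nonempty on at least 16
    longitudinal slices.  A spec whose tube crosses the midline is rejected.
    """
    if spec is None:
        spec = SyntheticAtlasSpec.default(space)
    z0, z1 = spec.z_range
    nz = space.shape[LONGITUDINAL_AXIS]
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"z_range {spec.z_range} outside longitudinal extent {nz}")
    if z1 - z0 < 16:
        raise ValueError("tract must span >= 16 longitudinal slices")
    centre_l = np.asarray(spec.centerline_left, dtype=float)
    if centre_l.shape != (z1 - z0, 2):
        raise ValueError("centerline_left must have one (x, y) pair per slice in z_range")
    centre_r = spec.mirrored_right(space)

    left = _tube_mask(space, centre_l, spec.z_range, spec.radius_mm)
    right = _tube_mask(space, centre_r, spec.z_range, spec.radius_mm)

    m = space.midline_index
    if left[m:, :, :].any():
        raise ValueError("left tract crosses the midline into the right hemisphere")
    if right[:m, :, :].any():
        raise ValueError("right tract crosses the midline into the left hemisphere")

    kwargs = dict(voxel_size=space.voxel_size, longitudinal_axis=LONGITUDINAL_AXIS)
    return VolumeMask(left, **kwargs), VolumeMask(right, **kwargs)


# ---------------------------------------------------------------------------
# lesions with exact injury scores
# ---------------------------------------------------------------------------

def make_lesion(
    space: TemplateSpace,
    side: str,
    target_injury: float,
    atlas: tuple[VolumeMask, VolumeMask],
    seed: int,
    threshold: float = 0.05,
    n_subsections: int = 16,
    spill: bool | None = None,
) -> VolumeMask:
    """Build a unilateral lesion whose scored CST injury is exactly ``target_injury``.

    ``target_injury`` must lie on the k/16 grid.  k subsections are chosen
    at random; each receives lesion voxels covering at least ``threshold``
    of its tract voxels, while unselected subsections stay strictly below
    threshold.  With ``spill=True`` every unselected subsection receives a
    *nonzero* sub-threshold overlap, which is impossible for subsections
    with fewer than ``1/threshold`` tract voxels (an error names the first
    such subsection); the default injects spill only where possible.  A
    small off-tract blob on the lesion side adds volume variability without
    touching the score.
    """
    k = round(target_injury * n_subsections)
    if not 0 <= k <= n_subsections or abs(k / n_subsections - target_injury) > 1e-9:
        raise ValueError(
            f"target_injury {target_injury} is not on the 1/{n_subsections} grid"
        )
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    tract = atlas[0] if side == "left" else atlas[1]
    partition = partition_tract(tract, n=n_subsections)
    rng = np.random.default_rng(seed)

    if spill:
        for i, m in enumerate(partition.voxel_counts):
            if math.ceil(threshold * m) - 1 < 1:
                raise ValueError(
                    f"subsection {i} has only {m} tract voxels; any nonzero "
                    f"overlap already reaches the {threshold:.0%} threshold"
                )

    selected = set(rng.choice(n_subsections, size=k, replace=False).tolist())
    data = np.zeros(space.shape, dtype=bool)
    axis = tract.longitudinal_axis
    coords = np.column_stack(np.nonzero(tract.data))
    zcol = coords[:, axis]
    for i, ((a, b), m) in enumerate(zip(partition.slice_ranges, partition.voxel_counts)):
        sub = coords[(zcol >= a) & (zcol < b)]
        if i in selected:
            need = math.ceil(threshold * m)
            take = int(rng.integers(need, m + 1))
        else:
            cap = math.ceil(threshold * m) - 1
            if cap >= 1 and (spill or (spill is None and rng.random() < 0.5)):
                take = int(rng.integers(1, cap + 1))
            else:
                take = 0
        if take:
            picked = sub[rng.choice(len(sub), size=take, replace=False)]
            data[picked[:, 0], picked[:, 1], picked[:, 2]] = True

    _add_offtract_blob(data, space, side, atlas, rng)

    lesion = VolumeMask(data, voxel_size=space.voxel_size, longitudinal_axis=axis)
    return lesion


def _add_offtract_blob(
    data: np.ndarray,
    space: TemplateSpace,
    side: str,
    atlas: tuple[VolumeMask, VolumeMask],
    rng: np.random.Generator,
) -> None:
    """Add a random rectangular blob on ``side``, disjoint from both tracts."""
    nx, ny, nz = space.shape
    m = space.midline_index
    x_lo, x_hi = (0, m) if side == "left" else (m, nx)
    size = rng.integers(2, 6, size=3)
    x0 = int(rng.integers(x_lo, max(x_lo + 1, x_hi - size[0])))
    y0 = int(rng.integers(0, max(1, ny - size[1])))
    z0 = int(rng.integers(0, max(1, nz - size[2])))
    blob = np.zeros_like(data)
    blob[x0 : min(x0 + size[0], x_hi), y0 : y0 + size[1], z0 : z0 + size[2]] = True
    blob &= ~(atlas[0].data | atlas[1].data)
    if not blob.any():
        # fall back to a guaranteed off-tract corner voxel on the lesion side
        cx = 0 if side == "left" else nx - 1
        if atlas[0].data[cx, 0, 0] or atlas[1].data[cx, 0, 0]:
            raise RuntimeError("no off-tract voxel available for lesion blob")
        blob[cx, 0, 0] = True
    data |= blob


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for a synthetic stroke cohort.

    ``cluster_mix`` gives the proportions of the three latent groups
    (mild/ceiling, severe-recoverer, severe-non-recoverer).  Within the
    severe groups the follow-up FMA-UE follows a linear model whose
    standardized slopes on initial FMA-UE and CST injury are
    ``initial_effect`` and ``injury_effect``; ``noise_sd`` is the residual
    SD in FMA points.  Lower-extremity scores are generated in parallel
    with CST injury decoupled by default (``injury_effect_le = 0``),
    mirroring the null the analysis is expected to find there.
    """

    n_patients: int = 67
    cluster_mix: tuple[float, float, float] = (28 / 67, 19.5 / 67, 19.5 / 67)
    injury_effect: float = -0.35
    initial_effect: float = 0.45
    noise_sd: float = 3.0
    seed: int = 0
    # lower-extremity generation (parallel structure, null injury signal)
    injury_effect_le: float = 0.0
    initial_effect_le: float = 0.60
    noise_sd_le: float = 2.5
    # probability of a complete (16/16) CST injury, excluded downstream
    complete_injury_rate: float = 0.03
    # probability a patient lacks any qualifying follow-up assessment
    missing_followup_rate: float = 0.0
    # probability of a third, late FMA assessment
    extra_assessment_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10 for stable downstream regressions")
        if len(self.cluster_mix) != 3 or any(p < 0 for p in self.cluster_mix):
            raise ValueError("cluster_mix must be three nonnegative proportions")
        if abs(sum(self.cluster_mix) - 1.0) > 1e-6:
            raise ValueError("cluster_mix proportions must sum to 1")
        for name in ("injury_effect", "initial_effect", "injury_effect_le", "initial_effect_le"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must be a standardized slope in (-1, 1)")
        if self.injury_effect**2 + self.initial_effect**2 >= 0.95:
            raise ValueError("combined squared effects must leave residual variance")


# group-conditional score models.  Severe initial scores are clipped,
# rounded Gaussians (mean, sd, low, high).  Mild/ceiling initial scores
# are a two-part uniform mixture (p_ceiling at or above the ceiling cut,
# the rest spread evenly down to the severity boundary) so that the
# ceiling filter removes the intended share and the observed mild minimum
# sits at the generating boundary.  (center, separation) parametrize the
# severe follow-up means: recoverers separation/2 above the center,
# non-recoverers separation/2 below.  Mild/ceiling patients recover ~70%
# of their remaining headroom (proportional recovery) independent of CST
# injury.
_UE_SEVERE_INITIAL = (11.0, 5.0, 0, 34)
_UE_MILD_INITIAL = (0.5, 60, 66, 35, 59)  # p_ceiling, ceil_lo, ceil_hi, lo, hi
_UE_SEVERE_FOLLOW = (34.0, 24.0)  # center, recoverer/non-recoverer separation
_UE_MILD_NOISE = 3.0

_LE_SEVERE_INITIAL = (7.0, 4.0, 0, 13)
_LE_MILD_INITIAL = (0.78, 28, 34, 14, 27)
_LE_SEVERE_FOLLOW = (17.0, 14.0)
_LE_MILD_NOISE = 2.0

#: moments of the analysed injury distribution (uniform on {0..15}/16;
#: complete 16/16 injuries are excluded before any regression)
_INJURY_MEAN = 7.5 / 16
_INJURY_SD = math.sqrt((1240 / 16) / 256 - (7.5 / 16) ** 2)


class SyntheticCohort(NamedTuple):
    patients: pd.DataFrame
    assessments: pd.DataFrame
    masks: dict[str, VolumeMask] | None


def _clipped_round_normal(rng, mean, sd, low, high, size):
    return np.clip(np.round(rng.normal(mean, sd, size)), low, high).astype(int)


def _mild_initial(rng, params, size):
    p_ceiling, ceil_lo, ceil_hi, lo, hi = params
    at_ceiling = rng.random(size) < p_ceiling
    out = np.empty(size, dtype=int)
    out[at_ceiling] = rng.integers(ceil_lo, ceil_hi + 1, size=int(at_ceiling.sum()))
    out[~at_ceiling] = rng.integers(lo, hi + 1, size=int((~at_ceiling).sum()))
    return out


def _severe_followup(
    rng: np.random.Generator,
    initial: np.ndarray,
    injury: np.ndarray,
    is_recoverer: np.ndarray,
    follow_params: tuple[float, float],
    p_recoverer: float,
    init_params: tuple[float, float],
    initial_effect: float,
    injury_effect: float,
    noise_sd: float,
    high: int,
) -> np.ndarray:
    """Severe-group follow-up with exact population standardized slopes.

    ``follow = center +/- separation/2 (by latent group)
    + s_f * (initial_effect * z_initial + injury_effect * z_injury) + noise``
    with the scale ``s_f`` chosen so that the *total* severe-stratum
    follow-up SD equals ``s_f``; the population standardized regression
    slopes on initial FMA and injury then equal the requested effects, group
    membership being independent of both predictors.
    """
    center, separation = follow_params
    m_i, s_i = init_params
    resid_share = 1.0 - initial_effect**2 - injury_effect**2
    var_offset = p_recoverer * (1 - p_recoverer) * separation**2
    s_f = math.sqrt((noise_sd**2 + var_offset) / resid_share)
    z_i = (initial - m_i) / s_i
    z_c = (injury - _INJURY_MEAN) / _INJURY_SD
    offset = np.where(is_recoverer, separation / 2.0, -separation / 2.0)
    latent = center + offset + s_f * (initial_effect * z_i + injury_effect * z_c)
    latent = latent + rng.normal(0.0, noise_sd, size=len(initial))
    return np.clip(np.round(latent), 0, high).astype(int)


def make_cohort(
    spec: CohortSpec,
    space: TemplateSpace | None = None,
    atlas: tuple[VolumeMask, VolumeMask] | None = None,
    with_masks: bool = False,
) -> SyntheticCohort:
    """Generate a patient table (and optionally lesion masks).

    Reproducible under a fixed ``spec.seed``.  The returned patient table
    keeps the latent group label for parameter-recovery tests, and the
    assessments table reproduces the initial/follow-up scores at their
    dated visits so the follow-up-selection filter can be exercised
    end-to-end.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    groups = rng.choice(3, size=n, p=np.asarray(spec.cluster_mix) / sum(spec.cluster_mix))

    # demographics — independent of outcome by design (null covariates)
    age = _clipped_round_normal(rng, 67.82, 15.04, 18, 95, n)
    sex = np.where(rng.random(n) < 30 / 67, "F", "M")
    location = np.where(rng.random(n) < 31 / 67, "subcortical", "cortical")
    side = np.where(rng.random(n) < 30 / 67, "left", "right")

    # CST injury on the 1/16 grid, identical distribution in every group so
    # that group membership never confounds the injury signal
    injured_count = rng.integers(0, 16, size=n)
    injured_count[rng.random(n) < spec.complete_injury_rate] = 16
    injury = injured_count / 16.0

    mild = groups == 0
    rec = groups == 1
    nonrec = groups == 2
    severe = ~mild

    init_ue = np.empty(n, dtype=int)
    init_le = np.empty(n, dtype=int)
    init_ue[mild] = _mild_initial(rng, _UE_MILD_INITIAL, mild.sum())
    init_ue[severe] = _clipped_round_normal(rng, *_UE_SEVERE_INITIAL, severe.sum())
    init_le[mild] = _mild_initial(rng, _LE_MILD_INITIAL, mild.sum())
    init_le[severe] = _clipped_round_normal(rng, *_LE_SEVERE_INITIAL, severe.sum())

    follow_ue = np.empty(n, dtype=int)
    follow_le = np.empty(n, dtype=int)
    # mild/ceiling: proportional recovery of ~70% of the remaining headroom
    follow_ue[mild] = np.clip(
        np.round(init_ue[mild] + 0.7 * (66 - init_ue[mild]) + rng.normal(0, _UE_MILD_NOISE, mild.sum())),
        init_ue[mild], 66,
    ).astype(int)
    follow_le[mild] = np.clip(
        np.round(init_le[mild] + 0.7 * (34 - init_le[mild]) + rng.normal(0, _LE_MILD_NOISE, mild.sum())),
        init_le[mild], 34,
    ).astype(int)

    p_rec = spec.cluster_mix[1] / (spec.cluster_mix[1] + spec.cluster_mix[2])
    follow_ue[severe] = _severe_followup(
        rng, init_ue[severe].astype(float), injury[severe], rec[severe],
        _UE_SEVERE_FOLLOW, p_rec,
        _UE_SEVERE_INITIAL[:2], spec.initial_effect, spec.injury_effect, spec.noise_sd, 66,
    )
    follow_le[severe] = _severe_followup(
        rng, init_le[severe].astype(float), injury[severe], rec[severe],
        _LE_SEVERE_FOLLOW, p_rec,
        _LE_SEVERE_INITIAL[:2], spec.initial_effect_le, spec.injury_effect_le, spec.noise_sd_le, 34,
    )

    # lesion volume: independent log-normal (a null covariate for the screen)
    volume = np.exp(rng.normal(9.6, 0.9, size=n))

    # visit schedule
    onset = np.array(
        [date(2016, 1, 1) + timedelta(days=int(d)) for d in rng.integers(0, 365, size=n)]
    )
    mri_day = np.clip(np.round(rng.normal(2.8, 2.0, n)), 0, 14).astype(int)
    initial_day = np.clip(np.round(rng.normal(11.4, 8.3, n)), 1, 45).astype(int)
    followup_day = 60 + np.clip(np.round(rng.exponential(15.0, n)), 0, 80).astype(int)
    has_follow = rng.random(n) >= spec.missing_followup_rate
    has_extra = rng.random(n) < spec.extra_assessment_rate
    extra_day = rng.integers(150, 241, size=n)

    ids = [f"P{i:04d}" for i in range(n)]
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": sex,
            "lesion_location": location,
            "lesion_side": side,
            "onset_date": onset,
            "mri_date": [o + timedelta(days=int(d)) for o, d in zip(onset, mri_day)],
            "latent_group": [GROUP_NAMES[g] for g in groups],
            "cst_injured_count": injured_count,
            "cst_injury": injury,
            "lesion_volume_mm3": volume,
            "initial_day": initial_day,
            "followup_day": followup_day,
            "initial_fma_ue": init_ue,
            "followup_fma_ue": follow_ue,
            "initial_fma_le": init_le,
            "followup_fma_le": follow_le,
            "has_followup": has_follow,
        }
    )

    rows = []
    for i in range(n):
        rows.append(
            {
                "patient_id": ids[i],
                "days_from_onset": int(initial_day[i]),
                "date": onset[i] + timedelta(days=int(initial_day[i])),
                "fma_ue": int(init_ue[i]),
                "fma_le": int(init_le[i]),
            }
        )
        if has_follow[i]:
            rows.append(
                {
                    "patient_id": ids[i],
                    "days_from_onset": int(followup_day[i]),
                    "date": onset[i] + timedelta(days=int(followup_day[i])),
                    "fma_ue": int(follow_ue[i]),
                    "fma_le": int(follow_le[i]),
                }
            )
            if has_extra[i]:
                drift_ue = int(np.clip(follow_ue[i] + round(rng.normal(1, 2)), 0, 66))
                drift_le = int(np.clip(follow_le[i] + round(rng.normal(0.5, 1.5)), 0, 34))
                rows.append(
                    {
                        "patient_id": ids[i],
                        "days_from_onset": int(extra_day[i]),
                        "date": onset[i] + timedelta(days=int(extra_day[i])),
                        "fma_ue": drift_ue,
                        "fma_le": drift_le,
                    }
                )
    assessments = pd.DataFrame(rows)

    masks = None
    if with_masks:
        if space is None:
            space = TemplateSpace()
        if atlas is None:
            atlas = make_atlas(space)
        masks = {}
        for i in range(n):
            lesion = make_lesion(
                space,
                side[i],
                injured_count[i] / 16.0,
                atlas,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            masks[ids[i]] = lesion
            score = cst_injury(lesion, atlas[0] if side[i] == "left" else atlas[1])
            assert score.injured_count == injured_count[i]
            patients.loc[i, "lesion_volume_mm3"] = lesion.count() * lesion.voxel_volume_mm3

    return SyntheticCohort(patients=patients, assessments=assessments, masks=masks)
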