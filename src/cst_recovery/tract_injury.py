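"""Corticospinal-tract injury scoring by the 16-subsection overlap rule.

The tract (one hemisphere of the CST atlas) is divided into ``n`` (default
16) longitudinal subsections over its occupied inferior-superior extent.  A
subsection counts as injured when at least 5% of its tract voxels fall
inside the lesion; the injury score is the injured count divided by ``n``,
so scores live on the grid {0, 1/16, ..., 1}.  A score of 1 (complete tract
involvement) is grounds for excluding the patient downstream.

Subsection boundaries are equal-as-possible longitudinal slice spans; when
the extent does not divide evenly the leftover slices are given to the most
superior subsections, one each.  Slice ranges are half-open and 0-based.
The 5% criterion is taken over the subsection's *tract* voxels, not the
whole slab, and the comparison is inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VolumeMask

__all__ = [
    "SubsectionPartition",
    "InjuryScore",
    "partition_tract",
    "subsection_overlap",
    "cst_injury",
    "score_bilateral",
]

#: Guard for the inclusive >= threshold comparison: overlap fractions are
#: exact multiples of 1/m for a subsection of m tract voxels, so a 1e-12
#: slack can never flip a genuinely sub-threshold fraction.
_THRESHOLD_EPS = 1e-12


@dataclass(frozen=True)
class SubsectionPartition:
    """Longitudinal partition of a tract into subsections.

    ``slice_ranges`` are half-open ``(start, stop)`` slice indices on the
    longitudinal axis, disjoint, ordered inferior to superior, and jointly
    covering exactly the tract's occupied extent.  ``voxel_counts`` holds the
    number of tract voxels in each subsection (all >= 1).
    """

    n_subsections: int
    longitudinal_axis: int
    slice_ranges: tuple[tuple[int, int], ...]
    voxel_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.slice_ranges) != self.n_subsections:
            raise ValueError("one slice range per subsection required")
        prev_stop = None
        for i, (a, b) in enumerate(self.slice_ranges):
            if b <= a:
                raise ValueError(f"subsection {i} has empty slice range ({a}, {b})")
            if prev_stop is not None and a != prev_stop:
                raise ValueError("slice ranges must be contiguous and ordered")
            prev_stop = b
        if any(c < 1 for c in self.voxel_counts):
            raise ValueError("every subsection must contain at least one tract voxel")

    @property
    def total_voxels(self) -> int:
        return int(sum(self.voxel_counts))


@dataclass(frozen=True)
class InjuryScore:
    """Per-hemisphere CST injury on the 1/n grid.

    ``value`` is ``injured_count / n_subsections``; the non-lesion hemisphere
    of a unilateral lesion always scores 0.
    """

    injured_count: int
    n_subsections: int
    fractions: tuple[float, ...]
    side: str | None = None
    lesion_volume_mm3: float | None = field(default=None, compare=False)

    @property
    def value(self) -> float:
        return self.injured_count / self.n_subsections

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "injured_count": self.injured_count,
            "n_subsections": self.n_subsections,
            "value": self.value,
            "fractions": list(self.fractions),
            "lesion_volume_mm3": self.lesion_volume_mm3,
        }


def partition_tract(tract: VolumeMask, n: int = 16) -> SubsectionPartition:
    """Split a tract mask into ``n`` longitudinal subsections.

    The occupied extent (first to last nonempty longitudinal slice) is cut
    into ``n`` half-open slice ranges of equal-as-possible length; when the
    span is not divisible by ``n`` the remainder slices are assigned to the
    most superior subsections, one extra slice each.  Deterministic.

    Raises
    ------
    ValueError
        If the tract is empty, spans fewer than ``n`` slices, or some
        subsection would contain no tract voxels (an interior gap).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tract.is_empty():
        raise ValueError("cannot partition an empty tract")
    axis = tract.longitudinal_axis
    profile = tract.data.sum(axis=tuple(i for i in range(3) if i != axis))
    occupied = np.nonzero(profile)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    span = hi - lo + 1
    if span < n:
        raise ValueError(f"tract spans {span} longitudinal slices; need >= {n}")

    base, extra = divmod(span, n)
    # first (n - extra) subsections get `base` slices, the `extra` most
    # superior ones get base + 1
    sizes = [base] * (n - extra) + [base + 1] * extra
    ranges = []
    start = lo
    for size in sizes:
        ranges.append((start, start + size))
        start += size
    counts = tuple(int(profile[a:b].sum()) for a, b in ranges)
    for i, c in enumerate(counts):
        if c == 0:
            raise ValueError(f"subsection {i} (slices {ranges[i]}) contains no tract voxels")
    return SubsectionPartition(
        n_subsections=n,
        longitudinal_axis=axis,
        slice_ranges=tuple(ranges),
        voxel_counts=counts,
    )


def subsection_overlap(
    lesion: VolumeMask,
    partition: SubsectionPartition,
    tract: VolumeMask,
) -> np.ndarray:
    """Per-subsection lesion overlap fractions.

    ``fraction[i] = |lesion & tract & slab_i| / |tract & slab_i|``, each in
    [0, 1].  Lesion and tract must share grid shape and voxel geometry.
    """
    lesion.same_grid(tract)
    axis = partition.longitudinal_axis
    both = lesion.data & tract.data
    fractions = np.empty(partition.n_subsections, dtype=float)
    for i, ((a, b), m) in enumerate(zip(partition.slice_ranges, partition.voxel_counts)):
        sl = [slice(None)] * 3
        sl[axis] = slice(a, b)
        fractions[i] = both[tuple(sl)].sum() / m
    return fractions


def cst_injury(
    lesion: VolumeMask,
    tract: VolumeMask,
    threshold: float = 0.05,
    n: int = 16,
    side: str | None = None,
) -> InjuryScore:
    """Score CST injury: fraction of subsections with >= ``threshold`` overlap.

    A subsection is injured when its overlap fraction is at least
    ``threshold`` (inclusive); the score is ``injured / n``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    partition = partition_tract(tract, n=n)
    fractions = subsection_overlap(lesion, partition, tract)
    injured = int(np.sum(fractions + _THRESHOLD_EPS >= threshold))
    return InjuryScore(
        injured_count=injured,
        n_subsections=n,
        fractions=tuple(float(f) for f in fractions),
        side=side,
    )


def score_bilateral(
    lesion: VolumeMask,
    atlas_left: VolumeMask,
    atlas_right: VolumeMask,
    midline_index: int,
    threshold: float = 0.05,
    n: int = 16,
) -> InjuryScore:
    """Score a unilateral lesion against the appropriate atlas hemisphere.

    Determines the lesion side from the midline, scores the ipsilesional
    tract, and attaches lesion volume.  The contralesional hemisphere of a
    unilateral lesion scores 0 by construction and is not reported.

    Raises
    ------
    ValueError
        If the lesion is bilateral (such patients must be excluded upstream).
    """
    from .volume import lesion_side, lesion_volume

    side = lesion_side(lesion, midline_index)
    if side == "bilateral":
        raise ValueError("bilateral lesion: patient must be excluded, no single-side score")
    tract = atlas_left if side == "left" else atlas_right
    score = cst_injury(lesion, tract, threshold=threshold, n=n, side=side)
    return InjuryScore(
        injured_count=score.injured_count,
        n_subsections=score.n_subsections,
        fractions=score.fractions,
        side=side,
        lesion_volume_mm3=lesion_volume(lesion),
    )
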