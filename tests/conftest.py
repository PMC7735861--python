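import numpy as np
import pytest

from cst_recovery import TemplateSpace, make_atlas


@pytest.fixture(scope="session")
def space():
    return TemplateSpace()


@pytest.fixture(scope="session")
def atlas(space):
    return make_atlas(space)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_tract(rng, shape=(6, 6, 20)):
    """Random tract occupying every longitudinal slice (partitionable into 16)."""
    data = rng.random(shape) < 0.3
    for z in range(shape[2]):
        if not data[:, :, z].any():
            data[rng.integers(shape[0]), rng.integers(shape[1]), z] = True
    return data


def brute_force_injury(lesion, tract, n=16, threshold=0.05):
    """Independent triple-loop voxel-count implementation of the injury score.

    Finds the tract's occupied longitudinal extent, carves it into n slabs
    (remainder slices to the most superior slabs), counts lesion-overlapping
    tract voxels per slab with explicit loops, and applies the inclusive
    threshold via integer arithmetic (injured iff overlap * 20 >= count for
    threshold = 0.05, exact rational comparison).
    """
    from fractions import Fraction

    zs = [z for z in range(tract.shape[2]) if tract[:, :, z].any()]
    lo, hi = zs[0], zs[-1]
    span = hi - lo + 1
    base, extra = divmod(span, n)
    sizes = [base] * (n - extra) + [base + 1] * extra
    injured = 0
    fractions = []
    start = lo
    thr = Fraction(threshold).limit_denominator(10**6)
    for size in sizes:
        count = overlap = 0
        for z in range(start, start + size):
            for x in range(tract.shape[0]):
                for y in range(tract.shape[1]):
                    if tract[x, y, z]:
                        count += 1
                        if lesion[x, y, z]:
                            overlap += 1
        fractions.append(Fraction(overlap, count))
        if Fraction(overlap, count) >= thr:
            injured += 1
        start += size
    return injured, fractions
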