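"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mosaicbench.regions import RegionSet


# -- per-base brute-force region oracle ------------------------------------


def mask_of(regions: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base membership mask for one toy chromosome."""
    mask = np.zeros(length, dtype=bool)
    arr = regions.array(chrom)
    for s, e in arr:
        mask[s:min(e, length)] = True
    return mask


def regions_from_mask(chrom: str, mask: np.ndarray) -> RegionSet:
    """Rebuild the canonical RegionSet from a per-base mask."""
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return RegionSet.from_intervals((chrom, int(s), int(e)) for s, e in zip(starts, ends))


def random_region_set(rng: np.random.Generator, chrom: str, length: int) -> RegionSet:
    """A random interval set (possibly overlapping/abutting before merge)."""
    n = int(rng.integers(0, 12))
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(s + 1 + rng.integers(1, length // 3 + 2), length) + 1))
        ivs.append((chrom, s, e))
    return RegionSet.from_intervals(ivs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
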