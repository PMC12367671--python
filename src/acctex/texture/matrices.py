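"""Discretization and texture-matrix construction.

All second-order families operate on a fixed-bin-width discretization of
the VOI intensities. Neighborhoods are defined on the voxel grid at
Chebyshev distance 1 (26-connectivity in 3D); directional families (GLCM,
GLRLM) use the 13 unique direction vectors, with features later averaged
over directions. Gray levels keep their bin values (gaps from unoccupied
bins are preserved, matrices are indexed by the occupied levels only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volumes import VOI, Volume

#: 13 unique 3D direction vectors (the lexicographically positive half of
#: the 26-neighborhood).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DiscretizedRegion:
    """Gray-level indices of a VOI under fixed-bin-width discretization.

    ``levels`` holds the 1-based bin index per voxel (0 outside the mask);
    ``ng`` is the number of *occupied* levels; ``level_values`` the sorted
    occupied bin indices (gaps allowed).
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.level_values = np.unique(self.levels[self.mask])
        self.ng = int(self.level_values.size)
        self.n_voxels = int(self.mask.sum())

    def level_index(self) -> np.ndarray:
        """Map the masked level array onto compact 0-based indices."""
        return np.searchsorted(self.level_values, self.levels)


def discretize(volume: Volume, voi: VOI, bin_width: float = 25.0) -> DiscretizedRegion:
    """Fixed-bin-width gray-level discretization of the VOI intensities.

    ``level(v) = floor((I(v) - min_I) / bin_width) + 1``, so the minimum
    intensity maps to level 1 and a value landing exactly on the top bin
    edge occupies its own (top) bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    voi.check_aligned(volume)
    if not voi.mask.any():
        raise ValueError("cannot discretize an empty VOI")
    vals = volume.data[voi.mask]
    levels = np.zeros(volume.data.shape, dtype=np.int64)
    levels[voi.mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedRegion(levels=levels, mask=voi.mask, bin_width=bin_width)


def _offset_slices(offset):
    """Slices (a, b) such that arr[b] sits at +offset from arr[a]."""
    a, b = [], []
    for o in offset:
        if o >= 0:
            a.append(slice(None, -o if o else None))
            b.append(slice(o, None))
        else:
            a.append(slice(-o, None))
            b.append(slice(None, o))
    return tuple(a), tuple(b)


def glcm_matrix(region: DiscretizedRegion, direction) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction.

    Returns an ``ng x ng`` matrix over the occupied levels; all-zero when
    the direction yields no in-mask voxel pairs.
    """
    ng = region.ng
    idx = region.level_index()
    a, b = _offset_slices(direction)
    valid = region.mask[a] & region.mask[b]
    ia, ib = idx[a][valid], idx[b][valid]
    counts = np.bincount(ia * ng + ib, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # symmetrize: count each pair in both orders
    total = counts.sum()
    return counts / total if total > 0 else counts


def glrlm_matrix(region: DiscretizedRegion, direction) -> np.ndarray:
    """Run-length counts for one direction: rows = occupied levels, cols = length.

    Every in-mask voxel belongs to exactly one maximal run per direction.
    """
    dz, dy, dx = direction
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, 1] = True
    structure[1 + dz, 1 + dy, 1 + dx] = True
    structure[1 - dz, 1 - dy, 1 - dx] = True
    max_len = region.mask.sum() if region.mask.ndim == 0 else max(region.mask.shape)
    rows = []
    for lv in region.level_values:
        binary = region.mask & (region.levels == lv)
        lab, n = ndimage.label(binary, structure=structure)
        row = np.zeros(max_len, dtype=float)
        if n:
            sizes = np.bincount(lab[lab > 0])[1:]
            hist = np.bincount(sizes, minlength=max_len + 1)[1:]
            row[: hist.size] = hist
        rows.append(row)
    mat = np.array(rows)
    used = np.nonzero(mat.any(axis=0))[0]
    last = used[-1] + 1 if used.size else 1
    return mat[:, :last]


def glszm_matrix(region: DiscretizedRegion) -> np.ndarray:
    """Size-zone counts: rows = occupied levels, cols = zone size (26-connected)."""
    max_size = region.n_voxels
    rows = []
    for lv in region.level_values:
        binary = region.mask & (region.levels == lv)
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        row = np.zeros(max_size, dtype=float)
        if n:
            sizes = np.bincount(lab[lab > 0])[1:]
            hist = np.bincount(sizes, minlength=max_size + 1)[1:]
            row[: hist.size] = hist
        rows.append(row)
    mat = np.array(rows)
    used = np.nonzero(mat.any(axis=0))[0]
    last = used[-1] + 1 if used.size else 1
    return mat[:, :last]


def gldm_matrix(region: DiscretizedRegion, alpha: int = 0) -> np.ndarray:
    """Dependence counts: rows = occupied levels, cols = dependence size.

    The dependence of a voxel is the number of its in-mask 26-neighbors
    whose gray-level difference is at most ``alpha``; the matrix column
    index is ``dependence + 1`` (a voxel with no dependent neighbors sits
    in column j = 1), so j-weighted formulas never divide by zero.
    """
    dep = np.zeros(region.mask.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _offset_slices(off)
        both = region.mask[a] & region.mask[b]
        close = np.abs(region.levels[a] - region.levels[b]) <= alpha
        dep[a] += (both & close).astype(np.int64)
    ng = region.ng
    idx = region.level_index()[region.mask]
    d = dep[region.mask]
    n_dep = int(d.max()) + 1
    counts = np.bincount(idx * n_dep + d, minlength=ng * n_dep).astype(float)
    return counts.reshape(ng, n_dep)


def ngtdm_table(region: DiscretizedRegion) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i) for the neighborhood gray-tone differences.

    ``s_i`` sums, over the in-mask voxels of level i, the absolute difference
    between i and the mean level of the voxel's in-mask 26-neighborhood;
    voxels with no in-mask neighbor contribute zero.
    """
    nb_sum = np.zeros(region.mask.shape, dtype=float)
    nb_cnt = np.zeros(region.mask.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _offset_slices(off)
        w = region.mask[a] & region.mask[b]
        nb_sum[a] += np.where(w, region.levels[b], 0)
        nb_cnt[a] += w
    m = region.mask
    diff = np.zeros(region.mask.shape, dtype=float)
    has_nb = m & (nb_cnt > 0)
    diff[has_nb] = np.abs(region.levels[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    idx = region.level_index()[m]
    n_i = np.bincount(idx, minlength=region.ng).astype(float)
    s_i = np.bincount(idx, weights=diff[m], minlength=region.ng)
    p_i = n_i / region.n_voxels
    return n_i, p_i, s_i
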