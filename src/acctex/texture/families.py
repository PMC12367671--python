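"""Feature formulas for the six families (92 features total).

Directional families (GLCM, GLRLM) compute each feature per direction and
average the values over the 13 unique directions; GLSZM/GLDM/NGTDM use a
single matrix. Entropies are base-2 and sum only over positive entries.

Degenerate conventions (all documented and tested): a single gray level
gives Correlation = 1, MCC = 1, Imc1 = Imc2 = 0, InverseVariance = 0,
NGTDM Contrast/Busyness/Strength = 0 and Coarseness capped at 1e6; GLCM
directions with no voxel pairs are dropped from the direction average.
"""

from __future__ import annotations

import numpy as np

from ..volumes import VOI, Volume
from .matrices import (
    DIRECTIONS_13,
    DiscretizedRegion,
    discretize,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
)

_COARSENESS_CAP = 1e6


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# First order


def first_order_features(volume: Volume, voi: VOI, bin_width: float = 25.0) -> dict[str, float]:
    """The 18 first-order statistics on the raw (undiscretized) VOI intensities.

    Entropy and Uniformity are the only members computed on the discretized
    histogram. Skewness and Kurtosis use population moments; zero-variance
    regions give Skewness = 0 and Kurtosis = 0 by convention.
    """
    x = volume.data[voi.mask].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    region = discretize(volume, voi, bin_width)
    hist = np.bincount(region.level_index()[voi.mask]).astype(float)
    p = hist / n
    energy = float(np.sum(x**2))
    return {
        "firstorder_10Percentile": p10,
        "firstorder_90Percentile": p90,
        "firstorder_Energy": energy,
        "firstorder_Entropy": _entropy(p),
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "firstorder_Median": float(np.median(x)),
        "firstorder_Minimum": float(x.min()),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_RobustMeanAbsoluteDeviation": (
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
        ),
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "firstorder_TotalEnergy": volume.voxel_volume_mm3 * energy,
        "firstorder_Uniformity": float(np.sum(p**2)),
        "firstorder_Variance": m2,
    }


# ---------------------------------------------------------------------------
# GLCM


def _glcm_single(p: np.ndarray, v: np.ndarray, ng: int) -> dict[str, float]:
    I, J = np.meshgrid(v.astype(float), v.astype(float), indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(v * px))
    uy = float(np.sum(v * py))
    sigx = float(np.sqrt(np.sum(px * (v - ux) ** 2)))
    sigy = float(np.sqrt(np.sum(py * (v - uy) ** 2)))
    absdiff = np.abs(I - J)
    # difference distribution p_{x-y} grouped by |i-j|
    dvals = np.unique(absdiff)
    pd = np.array([p[absdiff == k].sum() for k in dvals])
    diff_avg = float(np.sum(p * absdiff))
    # sum distribution p_{x+y}
    s = I + J
    svals = np.unique(s)
    ps = np.array([p[s == k].sum() for k in svals])

    hx, hy = _entropy(px), _entropy(py)
    hxy = _entropy(p)
    pos = p > 0
    marg = np.outer(px, py)
    hxy1 = float(-np.sum(p[pos] * np.log2(marg[pos])))
    pos_m = marg > 0
    hxy2 = float(-np.sum(marg[pos_m] * np.log2(marg[pos_m])))

    if sigx > 0 and sigy > 0:
        correlation = (float(np.sum(p * I * J)) - ux * uy) / (sigx * sigy)
    else:
        correlation = 1.0
    div = max(hx, hy)
    imc1 = (hxy - hxy1) / div if div > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px_i py_k)
    nz = px > 0
    if nz.sum() > 1:
        psub = p[np.ix_(nz, nz)]
        pxs, pys = px[nz], py[nz]
        q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    offdiag = absdiff > 0
    return {
        "glcm_Autocorrelation": float(np.sum(p * I * J)),
        "glcm_ClusterProminence": float(np.sum(p * (I + J - ux - uy) ** 4)),
        "glcm_ClusterShade": float(np.sum(p * (I + J - ux - uy) ** 3)),
        "glcm_ClusterTendency": float(np.sum(p * (I + J - ux - uy) ** 2)),
        "glcm_Contrast": float(np.sum(p * (I - J) ** 2)),
        "glcm_Correlation": float(correlation),
        "glcm_DifferenceAverage": diff_avg,
        "glcm_DifferenceEntropy": _entropy(pd),
        "glcm_DifferenceVariance": float(np.sum(pd * (dvals - diff_avg) ** 2)),
        "glcm_Id": float(np.sum(p / (1.0 + absdiff))),
        "glcm_Idm": float(np.sum(p / (1.0 + absdiff**2))),
        "glcm_Idmn": float(np.sum(p / (1.0 + absdiff**2 / ng**2))),
        "glcm_Idn": float(np.sum(p / (1.0 + absdiff / ng))),
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": float(np.sum(p[offdiag] / absdiff[offdiag] ** 2)),
        "glcm_JointAverage": ux,
        "glcm_JointEnergy": float(np.sum(p**2)),
        "glcm_JointEntropy": hxy,
        "glcm_MCC": mcc,
        "glcm_MaximumProbability": float(p.max()),
        "glcm_SumEntropy": _entropy(ps),
        "glcm_SumSquares": float(np.sum(p * (I - ux) ** 2)),
    }


def glcm_features(region: DiscretizedRegion) -> dict[str, float]:
    """23 co-occurrence features, averaged over the 13 directions."""
    per_dir = []
    for d in DIRECTIONS_13:
        p = glcm_matrix(region, d)
        if p.sum() > 0:
            per_dir.append(_glcm_single(p, region.level_values, region.ng))
    if not per_dir:
        # no voxel pair in any direction (e.g. scattered single voxels)
        return dict.fromkeys(_glcm_single(np.array([[1.0]]), np.array([1]), 1), np.nan)
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM / GLSZM (shared size-distribution formulas)


def _size_family(P: np.ndarray, v: np.ndarray, n_voxels: int, prefix: str, small: str,
                 large: str, col: str) -> dict[str, float]:
    """Shared formulas for run-length and size-zone matrices.

    ``P`` is a count matrix (rows = occupied gray levels with values ``v``,
    columns = run length / zone size starting at 1).
    """
    nr = P.sum()
    p = P / nr
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    V = v.astype(float)[:, None]
    Jm = j[None, :]
    pg = p.sum(axis=1)  # gray-level marginal
    pj = p.sum(axis=0)  # size marginal
    mu_g = float(np.sum(pg * v))
    mu_j = float(np.sum(pj * j))
    return {
        f"{prefix}_GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / nr),
        f"{prefix}_GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        f"{prefix}_GrayLevelVariance": float(np.sum(pg * (v - mu_g) ** 2)),
        f"{prefix}_HighGrayLevel{col}Emphasis": float(np.sum(p * V**2)),
        f"{prefix}_{large}Emphasis": float(np.sum(p * Jm**2)),
        f"{prefix}_{large}HighGrayLevelEmphasis": float(np.sum(p * V**2 * Jm**2)),
        f"{prefix}_{large}LowGrayLevelEmphasis": float(np.sum(p * Jm**2 / V**2)),
        f"{prefix}_LowGrayLevel{col}Emphasis": float(np.sum(p / V**2)),
        f"{prefix}_{'RunEntropy' if prefix == 'glrlm' else 'ZoneEntropy'}": _entropy(p.ravel()),
        f"{prefix}_{'RunLengthNonUniformity' if prefix == 'glrlm' else 'SizeZoneNonUniformity'}":
            float(np.sum(P.sum(axis=0) ** 2) / nr),
        f"{prefix}_{'RunLengthNonUniformityNormalized' if prefix == 'glrlm' else 'SizeZoneNonUniformityNormalized'}":
            float(np.sum(pj**2)),
        f"{prefix}_{'RunPercentage' if prefix == 'glrlm' else 'ZonePercentage'}":
            float(nr / n_voxels),
        f"{prefix}_{'RunVariance' if prefix == 'glrlm' else 'ZoneVariance'}":
            float(np.sum(pj * (j - mu_j) ** 2)),
        f"{prefix}_{small}Emphasis": float(np.sum(p / Jm**2)),
        f"{prefix}_{small}HighGrayLevelEmphasis": float(np.sum(p * V**2 / Jm**2)),
        f"{prefix}_{small}LowGrayLevelEmphasis": float(np.sum(p / (V**2 * Jm**2))),
    }


def glrlm_features(region: DiscretizedRegion) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    per_dir = [
        _size_family(
            glrlm_matrix(region, d), region.level_values, region.n_voxels,
            "glrlm", "ShortRun", "LongRun", "Run",
        )
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glszm_features(region: DiscretizedRegion) -> dict[str, float]:
    """16 size-zone features from the single 26-connected zone matrix."""
    return _size_family(
        glszm_matrix(region), region.level_values, region.n_voxels,
        "glszm", "SmallArea", "LargeArea", "Zone",
    )


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(region: DiscretizedRegion, alpha: int = 0) -> dict[str, float]:
    """14 dependence features; column index j = dependence count + 1."""
    P = gldm_matrix(region, alpha=alpha)
    nz = P.sum()
    p = P / nz
    v = region.level_values.astype(float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    V, Jm = v[:, None], j[None, :]
    pg, pj = p.sum(axis=1), p.sum(axis=0)
    mu_g, mu_j = float(np.sum(pg * v)), float(np.sum(pj * j))
    return {
        "gldm_DependenceEntropy": _entropy(p.ravel()),
        "gldm_DependenceNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "gldm_DependenceNonUniformityNormalized": float(np.sum(pj**2)),
        "gldm_DependenceVariance": float(np.sum(pj * (j - mu_j) ** 2)),
        "gldm_GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "gldm_GrayLevelVariance": float(np.sum(pg * (v - mu_g) ** 2)),
        "gldm_HighGrayLevelEmphasis": float(np.sum(p * V**2)),
        "gldm_LargeDependenceEmphasis": float(np.sum(p * Jm**2)),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * V**2 * Jm**2)),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * Jm**2 / V**2)),
        "gldm_LowGrayLevelEmphasis": float(np.sum(p / V**2)),
        "gldm_SmallDependenceEmphasis": float(np.sum(p / Jm**2)),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * V**2 / Jm**2)),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (V**2 * Jm**2))),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(region: DiscretizedRegion) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    n_i, p_i, s_i = ngtdm_table(region)
    v = region.level_values.astype(float)
    nv = region.n_voxels
    occ = p_i > 0
    vp, pp, sp = v[occ], p_i[occ], s_i[occ]
    ngp = int(occ.sum())
    sum_ps = float(np.sum(pp * sp))

    coarseness = 1.0 / sum_ps if sum_ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    if ngp > 1:
        pi_, pj_ = pp[:, None], pp[None, :]
        vi_, vj_ = vp[:, None], vp[None, :]
        contrast = float(
            np.sum(pi_ * pj_ * (vi_ - vj_) ** 2) / (ngp * (ngp - 1)) * np.sum(sp) / nv
        )
        busy_den = float(np.sum(np.abs(vi_ * pi_ - vj_ * pj_)))
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si_, sj_ = sp[:, None], sp[None, :]
        complexity = float(
            np.sum(np.abs(vi_ - vj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)) / nv
        )
        strength_num = float(np.sum((pi_ + pj_) * (vi_ - vj_) ** 2))
        strength = strength_num / np.sum(sp) if np.sum(sp) > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_Busyness": busyness,
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }
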